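"""Stage orchestration: chains the analysis stages over one artifact
directory, as a pure function of (inputs, config, seed).

Stages, in order: ``simulate`` (or load input tables), ``normalize``,
``richness``, ``cluster``, ``bioenv_pca``, ``depth_stats``, ``brt``,
``project``.  A config may list any prefix/subset of the stage order;
later stages require the artifacts of earlier ones.  Every stage writes
its outputs as TSV/JSON under its own subdirectory, and a ``log.json``
records the seed and resolved parameters of every stage run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance, community, depth_stats, simulate
from .brt import BRTConfig, evaluate, fit_brt, partial_dependence, relative_influence
from .projection import DEFAULT_INCREMENTS, project_clades
from .tables import read_counts, read_env, write_env, write_matrix

STAGE_ORDER = ("simulate", "normalize", "richness", "cluster",
               "bioenv_pca", "depth_stats", "brt", "project")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _scenario_config(config: dict) -> simulate.ScenarioConfig:
    params = dict(config.get("scenario", {}))
    params.setdefault("seed", config.get("seed", 0))
    niche = params.pop("niche_spec", None)
    if isinstance(niche, dict) and niche and isinstance(next(iter(niche.values())), dict):
        params["niche_spec"] = {c: simulate.NicheSpec(**v) for c, v in niche.items()}
    elif niche is not None:
        params["niche_spec"] = niche
    env_spec = params.pop("env_spec", None)
    if isinstance(env_spec, dict) and env_spec and isinstance(next(iter(env_spec.values())), dict):
        params["env_spec"] = {v: simulate.EnvVarSpec(**s) for v, s in env_spec.items()}
    elif env_spec is not None:
        params["env_spec"] = env_spec
    for key in ("n_clades_per_family", "library_size_range", "size_fractions"):
        if key in params and isinstance(params[key], list):
            params[key] = tuple(params[key])
    return simulate.ScenarioConfig(**params)


def run_pipeline(config: dict, out_dir: Path | str) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(STAGE_ORDER))
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in stages]
    seed = int(config.get("seed", 0))
    log = {"seed": seed, "stages": stages, "params": {}}
    ctx: dict = {}

    for stage in stages:
        try:
            _STAGES[stage](config, ctx, out, log)
        except Exception as exc:  # noqa: BLE001 - rethrown with stage name
            raise PipelineError(stage, exc) from exc
    (out / "log.json").write_text(json.dumps(log, indent=1, sort_keys=True,
                                             default=str))
    return out


# --------------------------------------------------------------------------
# stages


def _stage_simulate(config, ctx, out, log):
    scen = _scenario_config(config)
    data_dir = out / "data"
    simulate.write_scenario(scen, data_dir)
    ctx["env"] = read_env(data_dir / "env.tsv")
    ctx["mrna_raw"] = read_counts(data_dir, "mrna", "raw_reads")
    ctx["dna_raw"] = read_counts(data_dir, "dna", "raw_reads")
    ctx["ko"] = pd.read_csv(data_dir / "ko.tsv", sep="\t", index_col=0)
    log["params"]["simulate"] = {
        "n_stations": scen.n_stations, "seed": scen.seed,
        "dispersion": scen.dispersion}


def _load_inputs(config, ctx):
    if "env" in ctx:
        return
    in_dir = Path(config["input_dir"])
    ctx["env"] = read_env(in_dir / "env.tsv")
    ctx["mrna_raw"] = read_counts(in_dir, "mrna", "raw_reads")
    ctx["dna_raw"] = read_counts(in_dir, "dna", "raw_reads")
    ko_path = in_dir / "ko.tsv"
    ctx["ko"] = (pd.read_csv(ko_path, sep="\t", index_col=0)
                 if ko_path.exists() else None)


def _stage_normalize(config, ctx, out, log):
    _load_inputs(config, ctx)
    stage_dir = out / "abundance"
    stage_dir.mkdir(exist_ok=True)
    mrna = abundance.normalize_occurrence(ctx["mrna_raw"], "mrna_occurrence")
    dna = abundance.normalize_occurrence(ctx["dna_raw"], "dna_occurrence")
    ctx["mrna"], ctx["dna"] = mrna, dna
    write_matrix(mrna.values, stage_dir / "occurrence_mrna.tsv", "clade")
    write_matrix(dna.values, stage_dir / "occurrence_dna.tsv", "clade")
    pa = abundance.derive_presence(mrna)
    ctx["presence"] = pa
    write_matrix(pa.values, stage_dir / "presence.tsv", "clade")
    corr, ratios = abundance.mrna_dna_comparison(mrna, dna)
    corr.to_csv(stage_dir / "mrna_dna_correlation.tsv", sep="\t", index=False)
    write_matrix(ratios, stage_dir / "mrna_dna_ratio.tsv", "clade")
    fc = pd.DataFrame({f: abundance.fold_change_over_median(mrna, f)
                       for f in mrna.families})
    fc.to_csv(stage_dir / "foldchange.tsv", sep="\t", index_label="sample")
    log["params"]["normalize"] = {"rule": "reads/kb/diatom_total"}


def _stage_richness(config, ctx, out, log):
    stage_dir = out / "abundance"
    stage_dir.mkdir(exist_ok=True)
    stats = abundance.richness(ctx["presence"], ctx["mrna"].clade_meta)
    ctx["richness"] = stats
    stats.richness.to_csv(stage_dir / "richness.tsv", sep="\t", index_label="site")
    stats.per_depth.to_csv(stage_dir / "richness_correlation.tsv", sep="\t")
    stats.depth_contrast.to_csv(stage_dir / "richness_depth_ttest.tsv", sep="\t")
    ratios, test = abundance.family_ratio(ctx["mrna"])
    ratios.to_csv(stage_dir / "ratios.tsv", sep="\t", index_label="site")
    (stage_dir / "ratio_ttest.json").write_text(json.dumps(test, default=float))
    log["params"]["richness"] = {"families": ctx["mrna"].families}


def _stage_cluster(config, ctx, out, log):
    stage_dir = out / "community"
    stage_dir.mkdir(exist_ok=True)
    params = config.get("cluster", {})
    k_lo, k_hi = params.get("k_range", [2, 10])
    ctx["clusters"] = {}
    ctx["distances"] = {}
    for fam in ctx["mrna"].families:
        pa_fam = ctx["presence"].family_subset(ctx["mrna"].clade_meta, fam)
        d = community.zero_adjusted_dissimilarity(pa_fam, "sorensen_pa")
        k_max = min(k_hi, len(d.values) - 1)
        sol = community.select_k(d, range(k_lo, k_max + 1))
        ctx["distances"][fam] = d
        ctx["clusters"][fam] = sol
        write_matrix(d.values, stage_dir / f"distances_{fam}.tsv", "site")
        sol.labels.to_csv(stage_dir / f"clusters_{fam}.tsv", sep="\t",
                          index_label="site")
        sol.silhouette.to_csv(stage_dir / f"silhouette_{fam}.tsv", sep="\t")
    log["params"]["cluster"] = {"k_range": [k_lo, k_hi],
                               "metric": "sorensen_pa", "linkage": "ward"}


def _stage_bioenv_pca(config, ctx, out, log):
    stage_dir = out / "community"
    stage_dir.mkdir(exist_ok=True)
    env = ctx["env"]
    ctx["bioenv"] = {}
    for fam, d in ctx["distances"].items():
        subset, rho, profile = community.bioenv_select(env, d)
        ctx["bioenv"][fam] = subset
        profile.to_csv(stage_dir / f"bioenv_{fam}.tsv", sep="\t")
        pca = community.env_pca(env, subset, ctx["clusters"][fam])
        coords = pca.coordinates.copy()
        if pca.clusters is not None:
            coords["cluster"] = pca.clusters
        coords.to_csv(stage_dir / f"pca_coords_{fam}.tsv", sep="\t",
                      index_label="site")
        pca.loadings.to_csv(stage_dir / f"pca_loadings_{fam}.tsv", sep="\t",
                            index_label="variable")
        log["params"].setdefault("bioenv_pca", {})[fam] = {
            "subset": subset, "rho": rho}


def _stage_depth_stats(config, ctx, out, log):
    stage_dir = out / "depth"
    stage_dir.mkdir(exist_ok=True)
    env, mrna = ctx["env"], ctx["mrna"]
    dist, screens = depth_stats.vertical_switch(mrna, env)
    dist.to_csv(stage_dir / "vertical_switch.tsv", sep="\t")
    screens.to_csv(stage_dir / "vertical_switch_screen.tsv", sep="\t", index=False)
    fc = pd.DataFrame({f: abundance.fold_change_over_median(mrna, f)
                       for f in mrna.families})
    meta = mrna.sample_meta
    sites = [f"{st}|{d}" for st, d in zip(meta["station"], meta["depth"])]
    fc_site = fc.groupby(sites).mean()
    screen = depth_stats.env_correlation_screen(
        fc_site, env.reindex(fc_site.index), method="spearman")
    screen.to_csv(stage_dir / "env_screen.tsv", sep="\t", index=False)
    if ctx.get("ko") is not None:
        mats = depth_stats.cross_kingdom_screen(mrna, ctx["ko"])
        for depth, mat in mats.items():
            write_matrix(mat, stage_dir / f"crosskingdom_{depth.lower()}.tsv",
                         "clade")
    log["params"]["depth_stats"] = {"screen": "spearman+fdr_bh"}


def _stage_brt(config, ctx, out, log):
    stage_dir = out / "brt"
    stage_dir.mkdir(exist_ok=True)
    params = dict(config.get("brt", {}))
    clades = params.pop("clades", None) or list(ctx["presence"].values.index)
    loss_params = {k: v for k, v in params.items()
                   if k in {f.name for f in dataclasses.fields(BRTConfig)}}
    env = ctx["env"]
    pa = ctx["presence"].values
    frac = ctx["mrna"].subset_fraction("20-180")
    site_of = [f"{st}|{d}" for st, d in zip(frac.sample_meta["station"],
                                            frac.sample_meta["depth"])]
    abun = frac.values.T.set_axis(site_of).groupby(level=0).sum().T

    seed0 = int(config.get("seed", 0))
    ctx["brt_models"] = {}
    eval_rows = []
    for i, clade in enumerate(clades):
        for kind, loss in (("presence", "bernoulli"), ("abundance", "laplace")):
            cfg = BRTConfig(loss=loss, seed=seed0 + 13 * i + (7 if loss == "laplace" else 0),
                            **loss_params)
            if kind == "presence":
                y = pa.loc[clade].reindex(env.index).astype(float)
                if y.nunique() < 2:
                    continue
            else:
                y = abun.loc[clade].reindex(env.index).astype(float)
            model = fit_brt(env[list(env.columns)], y, cfg)
            if kind == "presence":
                ctx["brt_models"][clade] = model
            infl = relative_influence(model)
            infl.to_csv(stage_dir / f"influence_{clade}_{kind}.tsv", sep="\t")
            model.cv_profile.to_csv(stage_dir / f"cv_profile_{clade}_{kind}.tsv",
                                    sep="\t", index=False)
            (stage_dir / f"model_{clade}_{kind}.json").write_text(model.to_json())
            metrics = evaluate(model, env, y)
            metrics.pop("quartile_classes", None)
            eval_rows.append({"clade": clade, "kind": kind, **metrics})
            if infl.sum() > 0:
                curve = partial_dependence(model, env, infl.index[0])
                curve.to_csv(stage_dir / f"curve_{clade}_{kind}.tsv", sep="\t")
    pd.DataFrame(eval_rows).to_csv(stage_dir / "eval.tsv", sep="\t", index=False)
    log["params"]["brt"] = {"clades": list(clades), **loss_params}


def _stage_project(config, ctx, out, log):
    stage_dir = out / "projection"
    stage_dir.mkdir(exist_ok=True)
    params = config.get("project", {})
    increments = tuple(params.get("increments", DEFAULT_INCREMENTS))
    models = ctx.get("brt_models", {})
    if not models:
        raise ValueError("no presence models fitted; run the brt stage first")
    table, thresholds = project_clades(models, ctx["presence"].values,
                                       ctx["env"], increments)
    table.to_csv(stage_dir / "projection.tsv", sep="\t")
    thresholds.to_csv(stage_dir / "thresholds.tsv", sep="\t")
    log["params"]["project"] = {"increments": list(increments)}


_STAGES = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "richness": _stage_richness,
    "cluster": _stage_cluster,
    "bioenv_pca": _stage_bioenv_pca,
    "depth_stats": _stage_depth_stats,
    "brt": _stage_brt,
    "project": _stage_project,
}
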