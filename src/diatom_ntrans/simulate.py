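"""Synthetic Tara-like scenario generator with planted, recoverable structure.

Generates clade x sample read-count tables (metatranscriptome and
metagenome layers), a site x variable environmental table, and a
prokaryotic KO abundance table, for a sampling design of ``n_stations``
stations at up to two depths (surface everywhere, DCM at a configurable
subset) and four plankton size fractions.

The environmental gradients come from a Gaussian copula over a latent
"latitude" axis: each continuous variable loads on the shared axis and
is then mapped onto its marginal range (linearly or log-linearly), so
variables are correlated the way oceanographic gradients are —
temperature and light up-axis, macronutrients down-axis — while planted
latent correlations stay below the modeling cap of |r| < 0.6.

Clade expected abundance follows a planted niche response (logistic
increasing/decreasing, Gaussian unimodal, or flat generalist) to one
named environmental variable, scaled by a per-clade gene copy intensity
and the sample's library size; observed counts are negative-binomial
around that mean (Poisson in the infinite-dispersion limit).  Every
random draw flows from the single scenario seed through named
sub-streams, so regeneration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .tables import (
    CONTINUOUS_PREDICTORS,
    SIZE_FRACTIONS,
    CladeAbundanceTable,
    sample_key,
    site_key,
    validate_env,
    write_counts,
    write_env,
)


class ConfigError(ValueError):
    """Scenario configuration is internally inconsistent."""


@dataclasses.dataclass(frozen=True)
class EnvVarSpec:
    """Marginal range and copula loading of one continuous variable.

    ``loading`` is the correlation of the variable's latent Gaussian
    with the shared latitude axis; the planted latent correlation
    between two variables is the product of their loadings.  ``dcm_shift``
    is added on the latent scale for DCM rows (DCM is colder, darker and
    more nutrient-rich than the surface).
    """

    low: float
    high: float
    loading: float
    log_scale: bool = False
    dcm_shift: float = 0.0


@dataclasses.dataclass(frozen=True)
class NicheSpec:
    """Planted response of one clade to one environmental variable.

    kind: 'logistic_up' | 'logistic_down' | 'gaussian' | 'flat'.
    ``center`` and ``width`` are on the variable's generating scale
    (log-units for log-scale variables).  Flat niches ignore all three.
    """

    kind: str
    variable: str | None = None
    center: float = 0.0
    width: float = 1.0

    def response(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "flat":
            return np.ones_like(np.asarray(x, dtype=float))
        z = (np.asarray(x, dtype=float) - self.center) / self.width
        if self.kind == "logistic_up":
            return 1.0 / (1.0 + np.exp(-z))
        if self.kind == "logistic_down":
            return 1.0 / (1.0 + np.exp(z))
        if self.kind == "gaussian":
            return np.exp(-0.5 * z * z)
        raise ConfigError(f"unknown niche kind {self.kind!r}")

    @property
    def monotone_sign(self) -> int:
        """+1/-1 for monotone niches, 0 for gaussian/flat."""
        return {"logistic_up": 1, "logistic_down": -1}.get(self.kind, 0)


# Default marginal ranges and loadings.  Loadings keep every planted
# pairwise latent correlation at or below 0.68*0.65 = 0.44, well under
# the 0.6 selection cap used for the real predictors.
DEFAULT_ENV_SPEC: dict[str, EnvVarSpec] = {
    "chlorophyll_a": EnvVarSpec(0.02, 8.0, -0.30, log_scale=True, dcm_shift=0.5),
    "iron": EnvVarSpec(0.005, 2.0, 0.25, log_scale=True),
    "par": EnvVarSpec(5.0, 60.0, 0.55, dcm_shift=-1.2),
    "nh4": EnvVarSpec(0.01, 2.0, -0.25, log_scale=True, dcm_shift=0.3),
    "no2_no3": EnvVarSpec(0.02, 30.0, -0.65, log_scale=True, dcm_shift=0.8),
    "no3": EnvVarSpec(0.02, 28.0, -0.60, log_scale=True, dcm_shift=0.8),
    "temperature": EnvVarSpec(-1.8, 30.0, 0.68, dcm_shift=-0.7),
    "nitracline_depth": EnvVarSpec(5.0, 180.0, 0.45),
}


def _default_niches(families: dict[str, int], env_spec: dict[str, EnvVarSpec]) -> dict[str, NicheSpec]:
    """One planted niche per clade, cycling drivers and response kinds.

    Centers sit at the middle of the driver's generating-scale range and
    widths at one sixth of it, so responses vary over the sampled
    gradient instead of saturating.
    """
    drivers = ["temperature", "no3", "par", "nitracline_depth", "no2_no3", "chlorophyll_a"]
    kinds = ["logistic_up", "logistic_down", "gaussian", "logistic_up", "logistic_down", "flat"]
    niches: dict[str, NicheSpec] = {}
    i = 0
    for family, n_clades in families.items():
        for c in range(n_clades):
            kind = kinds[i % len(kinds)]
            var = drivers[i % len(drivers)]
            spec = env_spec[var]
            lo, hi = spec.low, spec.high
            if spec.log_scale:
                lo, hi = math.log(lo), math.log(hi)
            niches[clade_name(family, c)] = NicheSpec(
                kind=kind, variable=None if kind == "flat" else var,
                center=0.5 * (lo + hi), width=(hi - lo) / 6.0,
            )
            i += 1
    return niches


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII"]


def clade_name(family: str, index: int) -> str:
    return f"{family}_{_ROMAN[index]}"


@dataclasses.dataclass
class ScenarioConfig:
    """Full specification of a synthetic scenario.

    Defaults reproduce the global-ocean sampling design this pipeline is
    built for: 65 stations, surface everywhere and a DCM sample at 42 of
    65 stations, four size fractions, 11 AMT1 and 12 NRT2 clades.
    """

    n_stations: int = 65
    dcm_fraction: float = 42 / 65
    size_fractions: tuple[str, ...] = SIZE_FRACTIONS
    n_clades_per_family: tuple[int, int] = (11, 12)
    env_spec: dict[str, EnvVarSpec] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ENV_SPEC))
    niche_spec: dict[str, NicheSpec] | None = None
    copy_number_spec: dict[str, float] | None = None
    dispersion: float = 1.0            # NB size; inf => Poisson
    library_size_range: tuple[int, int] = (200_000, 2_000_000)
    expression_scale: float = 1e-6     # expected transporter reads per
                                       # diatom read per kb at full niche
                                       # response; keeps detection sparse
    dna_scale: float = 5e-7
    dna_env_exponent: float = 0.25     # DNA layer's (weak) niche dependence
    correlation_cap: float = 0.6
    n_kos: int = 15
    ko_specs: dict[str, str] | None = None   # KO -> env var or clade name
    ko_noise_sd: float = 0.5
    presence_min_expected: float = 1.0
    seed: int = 0

    @property
    def families(self) -> dict[str, int]:
        return {"AMT1": self.n_clades_per_family[0], "NRT2": self.n_clades_per_family[1]}

    @property
    def clades(self) -> list[str]:
        return [clade_name(f, i) for f, n in self.families.items() for i in range(n)]

    def resolved_niches(self) -> dict[str, NicheSpec]:
        if self.niche_spec is None:
            return _default_niches(self.families, self.env_spec)
        return self.niche_spec

    def resolved_copy_numbers(self) -> dict[str, float]:
        if self.copy_number_spec is not None:
            return self.copy_number_spec
        # geometric spread of gene copy intensity across clades, 0.5..2
        clades = self.clades
        vals = np.geomspace(0.5, 2.0, num=len(clades))
        return dict(zip(clades, vals.tolist()))

    def validate(self) -> "ScenarioConfig":
        if self.n_stations < 1:
            raise ConfigError("n_stations must be >= 1")
        if not 0.0 <= self.dcm_fraction <= 1.0:
            raise ConfigError("dcm_fraction must be in [0, 1]")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0 (use inf for Poisson)")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ConfigError("library_size_range must be positive and ordered")
        for v, spec in self.env_spec.items():
            if not -1.0 < spec.loading < 1.0:
                raise ConfigError(f"env_spec[{v}]: loading must be in (-1, 1)")
            if spec.high <= spec.low:
                raise ConfigError(f"env_spec[{v}]: empty range")
            if spec.log_scale and spec.low <= 0:
                raise ConfigError(f"env_spec[{v}]: log scale needs a positive range")
        cap = self.correlation_cap
        names = list(self.env_spec)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                planted = abs(self.env_spec[a].loading * self.env_spec[b].loading)
                if planted >= cap:
                    raise ConfigError(
                        f"planted correlation |r|={planted:.2f} between {a} and {b} "
                        f"exceeds the cap {cap}")
        for clade, niche in self.resolved_niches().items():
            if niche.kind != "flat" and niche.variable not in self.env_spec:
                raise ConfigError(
                    f"niche for {clade} references unknown variable {niche.variable!r}")
        return self


@dataclasses.dataclass
class ScenarioTruth:
    """Ground truth recorded at generation time, for recovery tests."""

    env: pd.DataFrame                      # realized site x variable table
    expected_mrna: pd.DataFrame            # clade x sample expected counts
    niche: dict[str, NicheSpec]            # the generating response per clade
    copy_number: dict[str, float]
    presence: pd.DataFrame                 # clade x site true presence (0/1)
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "niche": {c: dataclasses.asdict(n) for c, n in self.niche.items()},
            "copy_number": self.copy_number,
            "presence": {c: self.presence.loc[c].astype(int).to_dict()
                         for c in self.presence.index},
        }, indent=1, sort_keys=True)


def _rngs(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Independent named sub-streams all derived from one scenario seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _sites(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Station/depth grid: SRF everywhere, DCM at the first stations of a
    seeded shuffle so the DCM subset is latitude-independent."""
    stations = [f"ST{i + 1:03d}" for i in range(config.n_stations)]
    n_dcm = int(round(config.dcm_fraction * config.n_stations))
    order = rng.permutation(config.n_stations)
    dcm_set = {stations[i] for i in order[:n_dcm]}
    rows = [(st, "SRF") for st in stations]
    rows += [(st, "DCM") for st in stations if st in dcm_set]
    return pd.DataFrame(rows, columns=["station", "depth"])


def generate_env(config: ScenarioConfig) -> pd.DataFrame:
    """Generate the site x variable environmental table.

    Returns one row per station x depth with the nine standard
    predictors.  Realized pairwise |Pearson r| between continuous
    predictors is checked against ``config.correlation_cap`` whenever
    there are enough sites for the check to be meaningful (>= 25).
    """
    config.validate()
    rngs = _rngs(config.seed, "sites", "env")
    grid = _sites(config, rngs["sites"])
    rng = rngs["env"]

    stations = [f"ST{i + 1:03d}" for i in range(config.n_stations)]
    z = dict(zip(stations, rng.normal(size=config.n_stations)))  # latent latitude

    cols: dict[str, np.ndarray] = {}
    for var in CONTINUOUS_PREDICTORS:
        spec = config.env_spec[var]
        eps = rng.normal(size=len(grid))
        lat = np.array([z[st] for st in grid["station"]])
        g = spec.loading * lat + math.sqrt(1.0 - spec.loading ** 2) * eps
        g = g + np.where(grid["depth"].to_numpy() == "DCM", spec.dcm_shift, 0.0)
        u = stats.norm.cdf(g)
        if spec.log_scale:
            vals = np.exp(math.log(spec.low) + (math.log(spec.high) - math.log(spec.low)) * u)
        else:
            vals = spec.low + (spec.high - spec.low) * u
        cols[var] = vals
    cols["sampling_depth"] = (grid["depth"] == "DCM").astype(int).to_numpy()

    index = [site_key(st, d) for st, d in zip(grid["station"], grid["depth"])]
    env = pd.DataFrame(cols, index=pd.Index(index, name="site"))
    env.insert(0, "station", grid["station"].to_numpy())
    env.insert(1, "depth", grid["depth"].to_numpy())
    env = env.drop(columns=["station", "depth"])

    if len(env) >= 25:
        corr = env[list(CONTINUOUS_PREDICTORS)].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        worst = corr.max()
        if worst >= config.correlation_cap:
            # at small n an exceedance is sampling noise around the planted
            # (sub-cap) correlations, so only designs large enough for the
            # cap to be a stable property hard-fail
            msg = (f"realized predictor correlation {worst:.2f} exceeds the "
                   f"cap {config.correlation_cap}")
            if len(env) >= 100:
                raise ConfigError(msg + "; lower the copula loadings")
            warnings.warn(msg + f" (n={len(env)}: sampling noise)")
    return validate_env(env)


def _niche_input(env: pd.DataFrame, var: str, spec: EnvVarSpec) -> np.ndarray:
    x = env[var].to_numpy(dtype=float)
    return np.log(x) if spec.log_scale else x


def _expected_site_response(config: ScenarioConfig, env: pd.DataFrame) -> pd.DataFrame:
    """Clade x site matrix of niche responses in [0, 1]."""
    niches = config.resolved_niches()
    out = {}
    for clade, niche in niches.items():
        if niche.kind == "flat" or niche.variable is None:
            out[clade] = np.ones(len(env))
        else:
            x = _niche_input(env, niche.variable, config.env_spec[niche.variable])
            out[clade] = niche.response(x)
    return pd.DataFrame(out, index=env.index).T


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.maximum(mu, 0.0)
    if math.isinf(dispersion):
        return rng.poisson(mu)
    # NB with mean mu and variance mu + mu^2/k
    k = dispersion
    p = k / (k + mu)
    return rng.negative_binomial(k, p)


def generate_counts(
    config: ScenarioConfig, env: pd.DataFrame
) -> tuple[CladeAbundanceTable, CladeAbundanceTable, ScenarioTruth]:
    """Draw the mRNA and DNA count layers around the planted niches.

    Expected mRNA count for clade c in sample s is
    ``library_size(s) * expression_scale * copy_number(c) *
    niche_c(env(site(s))) * w(c, fraction(s))`` where ``w`` is the
    clade's size-fraction profile (Dirichlet-drawn, times the number of
    fractions so a clade evenly spread keeps weight 1 per fraction).
    The DNA layer replaces the niche response with its
    ``dna_env_exponent`` power — gene copies track the niche much more
    weakly than transcription does.
    """
    config.validate()
    sites = env.index.tolist()
    grid = _sites(config, _rngs(config.seed, "sites")["sites"])
    expected_sites = [site_key(st, d) for st, d in zip(grid["station"], grid["depth"])]
    if expected_sites != sites:
        raise ConfigError("env table does not match the config's sampling grid")

    rngs = _rngs(config.seed, "sites", "env", "counts")
    rng = rngs["counts"]

    clades = config.clades
    niches = config.resolved_niches()
    copy_num = config.resolved_copy_numbers()
    response = _expected_site_response(config, env)  # clade x site

    fracs = list(config.size_fractions)
    n_f = len(fracs)
    # per-clade size-fraction profile; mean 1 per fraction
    frac_w = pd.DataFrame(
        rng.dirichlet(np.full(n_f, 5.0), size=len(clades)) * n_f,
        index=clades, columns=fracs)

    samples = [sample_key(*sk.split("|"), f) for sk in sites for f in fracs]
    site_of = {s: "|".join(s.split("|")[:2]) for s in samples}
    frac_of = {s: s.split("|")[2] for s in samples}

    lo, hi = config.library_size_range
    totals = {
        "mrna": rng.integers(lo, hi + 1, size=len(samples)),
        "dna": rng.integers(lo, hi + 1, size=len(samples)),
    }

    def build_layer(layer: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        tot = totals[layer]
        mu = np.zeros((len(clades), len(samples)))
        for ci, c in enumerate(clades):
            resp = response.loc[c]
            for si, s in enumerate(samples):
                r = resp[site_of[s]]
                w = frac_w.at[c, frac_of[s]]
                if layer == "mrna":
                    mu[ci, si] = tot[si] * config.expression_scale * copy_num[c] * r * w
                else:
                    mu[ci, si] = (tot[si] * config.dna_scale * copy_num[c]
                                  * r ** config.dna_env_exponent * w)
        counts = _draw_counts(rng, mu, config.dispersion)
        values = pd.DataFrame(counts, index=clades, columns=samples)
        meta = pd.DataFrame({
            "station": [s.split("|")[0] for s in samples],
            "depth": [s.split("|")[1] for s in samples],
            "fraction": [frac_of[s] for s in samples],
            "diatom_total": tot,
        }, index=pd.Index(samples, name="sample"))
        return pd.DataFrame(mu, index=clades, columns=samples), (values, meta)

    mu_mrna, (mrna_values, mrna_meta) = build_layer("mrna")
    _, (dna_values, dna_meta) = build_layer("dna")

    clade_meta = pd.DataFrame({
        "family": [c.split("_")[0] for c in clades],
        "clade_id": [c.split("_")[1] for c in clades],
        "kb_covered": np.round(rng.uniform(0.5, 3.0, size=len(clades)), 3),
    }, index=pd.Index(clades, name="clade"))

    mrna = CladeAbundanceTable(mrna_values, "raw_reads", clade_meta, mrna_meta).validate()
    dna = CladeAbundanceTable(dna_values, "raw_reads", clade_meta, dna_meta).validate()

    # true presence: expected site-level mRNA reads (summed over fractions)
    site_expected = mu_mrna.T.groupby([site_of[s] for s in mu_mrna.columns]).sum().T
    site_expected = site_expected[sites]
    presence = (site_expected > config.presence_min_expected).astype(int)

    truth = ScenarioTruth(
        env=env, expected_mrna=mu_mrna, niche=niches,
        copy_number=copy_num, presence=presence, seed=config.seed)
    return mrna, dna, truth


def generate_ko_table(config: ScenarioConfig, env: pd.DataFrame) -> pd.DataFrame:
    """KO x site table of prokaryotic nitrogen-metabolism gene abundances.

    KOs listed in ``config.ko_specs`` share a driver with the diatom
    clades: a value naming an environmental variable gives the KO a
    logistic-increasing response to it; a value naming a clade copies
    that clade's niche-response surface (so the planted diatom-KO
    correlation is exact up to noise).  Remaining KOs are pure lognormal
    noise.  Multiplicative lognormal noise with sd ``ko_noise_sd``
    applies to every KO; set it to 0 for noise-free surfaces.
    """
    config.validate()
    rngs = _rngs(config.seed, "sites", "env", "counts", "ko")
    rng = rngs["ko"]
    response = _expected_site_response(config, env)
    ko_specs = config.ko_specs or {}
    names = list(ko_specs)
    names += [f"K{90000 + i}" for i in range(len(names), config.n_kos)]

    rows = {}
    for name in names:
        target = ko_specs.get(name)
        if target is None:
            base = np.ones(len(env))
        elif target in config.env_spec:
            x = _niche_input(env, target, config.env_spec[target])
            lo, hi = x.min(), x.max()
            width = (hi - lo) / 6.0 if hi > lo else 1.0
            base = 1.0 / (1.0 + np.exp(-(x - 0.5 * (lo + hi)) / width))
        elif target in response.index:
            base = response.loc[target].to_numpy()
        else:
            raise ConfigError(f"ko_specs[{name}]: unknown target {target!r}")
        noise = (np.exp(rng.normal(0.0, config.ko_noise_sd, size=len(env)))
                 if config.ko_noise_sd > 0 else 1.0)
        rows[name] = base * noise
    return pd.DataFrame(rows, index=env.index).T


def generate_scenario(config: ScenarioConfig):
    """Convenience wrapper: env + both count layers + KO table + truth."""
    env = generate_env(config)
    mrna, dna, truth = generate_counts(config, env)
    ko = generate_ko_table(config, env)
    return env, mrna, dna, ko, truth


def write_scenario(config: ScenarioConfig, out_dir: Path | str) -> None:
    """Materialize a scenario as the pipeline's TSV inputs + truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    env, mrna, dna, ko, truth = generate_scenario(config)
    write_env(env, out / "env.tsv")
    write_counts(mrna, out, "mrna")
    write_counts(dna, out, "dna")
    ko.to_csv(out / "ko.tsv", sep="\t", index_label="ko")
    (out / "truth.json").write_text(truth.to_json())
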