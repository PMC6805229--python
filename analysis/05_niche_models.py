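"""Boosted-regression-tree niche models for selected clades.

For each selected clade, fits a Bernoulli model of site-level presence
and a Laplace model of 20-180 um transcript occurrence on the nine
environmental predictors (slow learning rate, tree complexity 5, 50%
bag fraction, tree number chosen by k-fold cross-validation), then
reports relative influences, validation metrics and the top predictor's
response curve, and simplifies the presence model by backward predictor
elimination.
"""

from pathlib import Path

import pandas as pd

from diatom_ntrans import abundance
from diatom_ntrans.brt import (
    BRTConfig, evaluate, fit_brt, partial_dependence, relative_influence,
    simplify,
)
from diatom_ntrans.tables import read_counts, read_env

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "brt"
OUT.mkdir(parents=True, exist_ok=True)

CLADES = ["AMT1_I", "AMT1_II", "NRT2_I", "NRT2_II"]
SEED = 20

env = read_env(ROOT / "data" / "env.tsv")
occ = abundance.normalize_occurrence(
    read_counts(ROOT / "data", "mrna", "raw_reads"), "mrna_occurrence")
pa = abundance.derive_presence(occ)
frac = occ.subset_fraction("20-180")
sites = [f"{st}|{d}" for st, d in
         zip(frac.sample_meta["station"], frac.sample_meta["depth"])]
abun = frac.values.T.set_axis(sites).groupby(level=0).sum().T

rows = []
for i, clade in enumerate(CLADES):
    for kind, loss in (("presence", "bernoulli"), ("abundance", "laplace")):
        y = (pa.values if kind == "presence" else abun).loc[clade] \
            .reindex(env.index).astype(float)
        if kind == "presence" and y.nunique() < 2:
            print(f"{clade}: single presence class, skipped")
            continue
        cfg = BRTConfig(loss=loss, learning_rate=0.005, tree_complexity=5,
                        bag_fraction=0.5, n_folds=10, tree_block=50,
                        max_trees=1500, patience_blocks=4,
                        seed=SEED + 31 * i + (11 if loss == "laplace" else 0))
        model = fit_brt(env, y, cfg)
        infl = relative_influence(model)
        infl.to_csv(OUT / f"influence_{clade}_{kind}.tsv", sep="\t")
        model.cv_profile.to_csv(OUT / f"cv_profile_{clade}_{kind}.tsv",
                                sep="\t", index=False)
        (OUT / f"model_{clade}_{kind}.json").write_text(model.to_json())
        metrics = evaluate(model, env, y)
        metrics.pop("quartile_classes", None)
        rows.append({"clade": clade, "kind": kind, "n_trees": model.n_trees,
                     "top_variable": infl.index[0],
                     "top_influence_pct": infl.iloc[0], **metrics})
        curve = partial_dependence(model, env, infl.index[0])
        curve.to_csv(OUT / f"curve_{clade}_{kind}.tsv", sep="\t")
        stat = (f"CV AUC = {metrics['auc']:.2f}" if loss == "bernoulli"
                else f"quartile r = {metrics['r']:.2f}, p = {metrics['p']:.2g}")
        print(f"{clade} {kind}: {model.n_trees} trees; top predictor "
              f"{infl.index[0]} ({infl.iloc[0]:.0f}%); {stat}; "
              f"{'passes' if metrics['passes'] else 'fails'} the significance cut")
        if kind == "presence":
            reduced, dropped = simplify(model, env, y, cfg)
            print(f"  simplification dropped {len(dropped)} predictors "
                  f"({', '.join(dropped) if dropped else 'none'})")

pd.DataFrame(rows).to_csv(OUT / "eval.tsv", sep="\t", index=False)
print(f"outputs under {OUT}")
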