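"""Surface-vs-DCM contrasts and cross-kingdom correlation screens.

Per dual-depth station: the zero-adjusted Bray-Curtis turnover between
surface and DCM transcript profiles, Spearman-screened (BH-adjusted)
against the environment; family fold-changes screened against all
environmental variables; diatom clade x prokaryotic KO Pearson matrices
per depth; and an example Fisher 2x2 proportion comparison of the kind
used for predicted subcellular localization classes.
"""

import json
from pathlib import Path

import pandas as pd

from diatom_ntrans import abundance, depth_stats
from diatom_ntrans.tables import read_counts, read_env, write_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "depth"
OUT.mkdir(parents=True, exist_ok=True)

env = read_env(ROOT / "data" / "env.tsv")
occ = abundance.normalize_occurrence(
    read_counts(ROOT / "data", "mrna", "raw_reads"), "mrna_occurrence")
ko = pd.read_csv(ROOT / "data" / "ko.tsv", sep="\t", index_col=0)

dist, screens = depth_stats.vertical_switch(occ, env)
dist.to_csv(OUT / "vertical_switch.tsv", sep="\t")
screens.to_csv(OUT / "vertical_switch_screen.tsv", sep="\t", index=False)
print(f"vertical turnover across {len(dist)} dual-depth stations: "
      f"mean zero-adjusted Bray-Curtis = {dist.mean():.3f}")
sig = screens[screens.significant]
print(f"  environmental correlates flagged (|rho|>0.3, BH p<0.05): "
      f"{len(sig)} of {len(screens)} pairs")

fc = pd.DataFrame({f: abundance.fold_change_over_median(occ, f)
                   for f in occ.families})
meta = occ.sample_meta
sites = [f"{st}|{d}" for st, d in zip(meta['station'], meta['depth'])]
fc_site = fc.groupby(sites).mean()
screen = depth_stats.env_correlation_screen(fc_site, env.reindex(fc_site.index))
screen.to_csv(OUT / "env_screen.tsv", sep="\t", index=False)
print(f"family fold-change screen: "
      f"{int(screen.significant.sum())} significant pairs")

mats = depth_stats.cross_kingdom_screen(occ, ko)
for depth, mat in mats.items():
    write_matrix(mat, OUT / f"crosskingdom_{depth.lower()}.tsv", "clade")
    print(f"cross-kingdom ({depth}): {int(mat.notna().sum().sum())} "
          f"unmasked clade-KO correlations of {mat.size} (p < 0.05, unadjusted)")

# proportion comparison of the localization-prediction kind:
# 27/109 vs 14/107 predicted in the class of interest
orr, p = depth_stats.fisher_2x2(27, 82, 14, 93)
(OUT / "fisher.json").write_text(json.dumps(
    {"table": [[27, 82], [14, 93]], "odds_ratio": orr, "p_two_sided": p}))
print(f"Fisher 2x2 (27/109 vs 14/107): conditional OR = {orr:.2f}, "
      f"two-sided p = {p:.3f}")
print(f"outputs under {OUT}")
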