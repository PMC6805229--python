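"""Normalize counts to occurrences and summarize richness structure.

Computes per-sample occurrences (reads/kb/diatom-total), site-level
presence-absence, per-family richness with the cross-family Pearson
relation per depth, the surface-vs-DCM richness t-tests, the mRNA:DNA
comparison, and the AMT1:NRT2 transcript-ratio depth contrast.
"""

import json
from pathlib import Path

import pandas as pd

from diatom_ntrans import abundance
from diatom_ntrans.tables import read_counts, read_env, write_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "abundance"
OUT.mkdir(parents=True, exist_ok=True)

env = read_env(ROOT / "data" / "env.tsv")
mrna_raw = read_counts(ROOT / "data", "mrna", "raw_reads")
dna_raw = read_counts(ROOT / "data", "dna", "raw_reads")

occ = abundance.normalize_occurrence(mrna_raw, "mrna_occurrence")
dna = abundance.normalize_occurrence(dna_raw, "dna_occurrence")
pa = abundance.derive_presence(occ)
write_matrix(occ.values, OUT / "occurrence_mrna.tsv", "clade")
write_matrix(pa.values, OUT / "presence.tsv", "clade")

rich = abundance.richness(pa, occ.clade_meta)
rich.richness.to_csv(OUT / "richness.tsv", sep="\t", index_label="site")
rich.per_depth.to_csv(OUT / "richness_correlation.tsv", sep="\t")
print("cross-family richness relation (NRT2 on AMT1):")
print(rich.per_depth.round(3))
for fam, row in rich.depth_contrast.iterrows():
    print(f"  {fam}: SRF richness > DCM, one-tail paired t = {row['t']:.2f}, "
          f"p = {row['p']:.3g} (n = {int(row['n'])} stations)")

corr, ratios = abundance.mrna_dna_comparison(occ, dna)
corr.to_csv(OUT / "mrna_dna_correlation.tsv", sep="\t", index=False)
overall = corr[corr["fraction"] == "all"].set_index("family")["r"]
print(f"mRNA vs DNA occurrence (all fractions): "
      + ", ".join(f"{f} r = {r:.2f}" for f, r in overall.items()))

ratio_df, test = abundance.family_ratio(occ)
ratio_df.to_csv(OUT / "ratios.tsv", sep="\t", index_label="site")
(OUT / "ratio_ttest.json").write_text(json.dumps(test, default=float))
print(f"AMT1:NRT2 ratio, SRF lower than DCM: one-tail p = {test['p']:.3g} "
      f"(n = {test['n']} dual-depth stations)")

fc = pd.DataFrame({f: abundance.fold_change_over_median(occ, f)
                   for f in occ.families})
fc.to_csv(OUT / "foldchange.tsv", sep="\t", index_label="sample")
print(f"outputs under {OUT}")
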