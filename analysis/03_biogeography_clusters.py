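"""Cluster stations by clade presence-absence and relate the clusters
to the environment.

For each gene family: zero-adjusted Sørensen dissimilarities between
sites, Ward clustering with the cut level chosen by mean silhouette
width, BIOENV selection of the environmental subset best rank-correlated
with the community structure, and a PCA of that subset with cluster
labels attached.
"""

from pathlib import Path

from diatom_ntrans import abundance, community
from diatom_ntrans.tables import read_counts, read_env, write_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "community"
OUT.mkdir(parents=True, exist_ok=True)

env = read_env(ROOT / "data" / "env.tsv")
occ = abundance.normalize_occurrence(
    read_counts(ROOT / "data", "mrna", "raw_reads"), "mrna_occurrence")
pa = abundance.derive_presence(occ)

for fam in occ.families:
    pa_fam = pa.family_subset(occ.clade_meta, fam)
    d = community.zero_adjusted_dissimilarity(pa_fam, "sorensen_pa")
    sol = community.select_k(d, range(2, 11))
    write_matrix(d.values, OUT / f"distances_{fam}.tsv", "site")
    sol.labels.to_csv(OUT / f"clusters_{fam}.tsv", sep="\t", index_label="site")
    sol.silhouette.to_csv(OUT / f"silhouette_{fam}.tsv", sep="\t")
    print(f"{fam}: silhouette optimum k = {sol.k} "
          f"(width {sol.silhouette.loc[sol.k]:.3f}) over "
          f"{len(sol.labels)} sites")

    subset, rho, profile = community.bioenv_select(env, d)
    profile.to_csv(OUT / f"bioenv_{fam}.tsv", sep="\t")
    print(f"{fam}: BIOENV subset {subset} (Spearman rho = {rho:.3f})")

    pca = community.env_pca(env, subset, sol)
    coords = pca.coordinates.copy()
    coords["cluster"] = pca.clusters
    coords.to_csv(OUT / f"pca_coords_{fam}.tsv", sep="\t", index_label="site")
    pca.loadings.to_csv(OUT / f"pca_loadings_{fam}.tsv", sep="\t",
                        index_label="variable")
    print(f"{fam}: PC1/PC2 explain "
          f"{pca.variance_explained.iloc[0]:.1f}% / "
          f"{pca.variance_explained.iloc[1]:.1f}% of the subset variance")
print(f"outputs under {OUT}")
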