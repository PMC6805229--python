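"""Normalization, presence-absence, richness and family-level summaries.

Occurrence is the length- and depth-normalized abundance used
throughout: reads mapped to a clade per kb of covered gene sequence,
divided by the total number of diatom-mapped reads in the sample.  A
clade is *present* at a site (station x depth) when its mRNA occurrence
is positive in at least one of the size fractions sampled there.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CladeAbundanceTable, site_key


@dataclasses.dataclass
class PresenceAbsenceMatrix:
    """Clade x site binary matrix with a note on the aggregation rule."""

    values: pd.DataFrame               # clade x site, entries in {0, 1}
    site_meta: pd.DataFrame            # per-site station, depth
    provenance: str

    def family_subset(self, clade_meta: pd.DataFrame, family: str) -> pd.DataFrame:
        mask = clade_meta["family"] == family
        return self.values.loc[mask.index[mask]]


@dataclasses.dataclass
class RichnessStats:
    """Per-site clade richness by family plus cross-family association."""

    richness: pd.DataFrame             # site x family counts (+ station, depth)
    per_depth: pd.DataFrame            # depth x (r, p, slope, intercept, n)
    depth_contrast: pd.DataFrame       # family x (t, p, n) one-tail SRF > DCM


def normalize_occurrence(
    raw: CladeAbundanceTable, out_layer: str = "mrna_occurrence"
) -> CladeAbundanceTable:
    """Reads / kb covered / total diatom-mapped reads, per clade and sample.

    Zero read cells map to zero occurrence regardless of coverage; a
    nonzero count with zero covered length has an undefined read density
    and raises.
    """
    if raw.layer != "raw_reads":
        raise ValueError(f"expected raw_reads layer, got {raw.layer}")
    raw.validate()
    reads = raw.values.to_numpy(dtype=float)
    kb = raw.clade_meta["kb_covered"].to_numpy(dtype=float)[:, None]
    bad = (reads > 0) & (kb <= 0)
    if bad.any():
        clade = raw.values.index[np.where(bad)[0][0]]
        raise ValueError(f"clade {clade}: nonzero reads with kb_covered = 0")
    totals = raw.sample_meta["diatom_total"].to_numpy(dtype=float)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        occ = np.where(reads > 0, reads / np.where(kb > 0, kb, np.nan) / totals, 0.0)
    values = pd.DataFrame(occ, index=raw.values.index, columns=raw.values.columns)
    return raw.with_values(values, out_layer)


def derive_presence(mrna: CladeAbundanceTable) -> PresenceAbsenceMatrix:
    """Present at a site iff abundance > 0 in any available size fraction."""
    meta = mrna.sample_meta
    sites = [site_key(st, d) for st, d in zip(meta["station"], meta["depth"])]
    grouped = (mrna.values > 0).T.groupby(sites).any().T
    # keep first-appearance site order rather than lexicographic
    order = list(dict.fromkeys(sites))
    values = grouped[order].astype(int)
    site_meta = pd.DataFrame(
        {"station": [s.split("|")[0] for s in order],
         "depth": [s.split("|")[1] for s in order]},
        index=pd.Index(order, name="site"))
    n_frac = pd.Series(sites).value_counts()
    provenance = (
        "present iff abundance > 0 in >=1 size fraction at the site; "
        f"fractions per site ranged {n_frac.min()}-{n_frac.max()}")
    return PresenceAbsenceMatrix(values, site_meta, provenance)


def richness(
    pa: PresenceAbsenceMatrix, clade_meta: pd.DataFrame,
    families: tuple[str, str] = ("AMT1", "NRT2"),
) -> RichnessStats:
    """Per-site clade counts and their cross-family association.

    Richness of the two families is compared by Pearson correlation
    separately at each depth, together with the least-squares line of
    the second family's richness on the first's.  A paired one-tail
    t-test per family asks whether surface richness exceeds DCM richness
    at stations sampled at both depths.
    """
    fam_a, fam_b = families
    counts = {}
    for fam in families:
        rows = clade_meta.index[clade_meta["family"] == fam]
        counts[fam] = pa.values.loc[rows].sum(axis=0)
    rich = pd.DataFrame(counts)
    rich.insert(0, "station", pa.site_meta["station"])
    rich.insert(1, "depth", pa.site_meta["depth"])

    per_depth_rows = []
    for depth, sub in rich.groupby("depth"):
        x, y = sub[fam_a].to_numpy(float), sub[fam_b].to_numpy(float)
        if len(sub) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            per_depth_rows.append((depth, np.nan, np.nan, np.nan, np.nan, len(sub)))
            continue
        r, p = stats.pearsonr(x, y)
        slope, intercept = np.polyfit(x, y, 1)
        per_depth_rows.append((depth, r, p, slope, intercept, len(sub)))
    per_depth = pd.DataFrame(
        per_depth_rows, columns=["depth", "r", "p", "slope", "intercept", "n"]
    ).set_index("depth")

    # paired one-tail: SRF richness > DCM richness, per family
    wide = rich.pivot_table(index="station", columns="depth", values=list(families))
    contrast_rows = []
    for fam in families:
        if ("SRF" not in rich["depth"].values) or ("DCM" not in rich["depth"].values):
            contrast_rows.append((fam, np.nan, np.nan, 0))
            continue
        sub = wide[fam].dropna(subset=["SRF", "DCM"])
        t, p = _paired_onetail(sub["SRF"].to_numpy(), sub["DCM"].to_numpy(), "greater")
        contrast_rows.append((fam, t, p, len(sub)))
    depth_contrast = pd.DataFrame(
        contrast_rows, columns=["family", "t", "p", "n"]).set_index("family")
    return RichnessStats(rich, per_depth, depth_contrast)


def _paired_onetail(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    """Paired one-tail t-test with documented degenerate-variance handling.

    If every pairwise difference is identical: zero difference gives
    t = 0, p = 0.5; a constant nonzero difference is treated as
    infinitely strong evidence (p -> 0 in the alternative's direction,
    1 against it).
    """
    d = np.asarray(a, float) - np.asarray(b, float)
    if len(d) < 2:
        return np.nan, np.nan
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 0.5
        favored = d[0] > 0 if alternative == "greater" else d[0] < 0
        return (np.inf if d[0] > 0 else -np.inf), (0.0 if favored else 1.0)
    res = stats.ttest_rel(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def mrna_dna_comparison(
    mrna: CladeAbundanceTable, dna: CladeAbundanceTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transcript vs gene-copy occurrence, per family and per clade.

    Returns ``(correlations, ratios)``: per-family Pearson r between
    summed mRNA and summed DNA occurrence over the shared samples —
    overall and within each size fraction — and the per-clade,
    per-sample mRNA:DNA ratio (NaN-masked where DNA occurrence is 0).
    """
    shared = mrna.values.columns.intersection(dna.values.columns)
    if len(shared) == 0:
        raise ValueError("no overlapping samples between mRNA and DNA layers")
    m, d = mrna.values[shared], dna.values[shared]
    meta = mrna.sample_meta.loc[shared]

    rows = []
    for fam in mrna.families:
        fam_rows = mrna.clade_meta.index[mrna.clade_meta["family"] == fam]
        ms, ds = m.loc[fam_rows].sum(axis=0), d.loc[fam_rows].sum(axis=0)
        groups = [("all", np.ones(len(shared), bool))]
        groups += [(f, (meta["fraction"] == f).to_numpy())
                   for f in meta["fraction"].unique()]
        for label, mask in groups:
            x, y = ms[mask].to_numpy(float), ds[mask].to_numpy(float)
            if mask.sum() < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((fam, label, np.nan, np.nan, int(mask.sum())))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((fam, label, r, p, int(mask.sum())))
    correlations = pd.DataFrame(rows, columns=["family", "fraction", "r", "p", "n"])

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = m / d.where(d > 0)
    return correlations, ratios


def fold_change_over_median(mrna: CladeAbundanceTable, family: str) -> pd.Series:
    """Per-sample family abundance as fold-change over its global median.

    The family's summed occurrence per sample is divided by the median
    of that sum across all samples; a zero median leaves every
    fold-change undefined (NaN).
    """
    rows = mrna.clade_meta.index[mrna.clade_meta["family"] == family]
    sums = mrna.values.loc[rows].sum(axis=0)
    med = float(np.median(sums))
    if med == 0:
        return pd.Series(np.nan, index=sums.index, name=f"{family}_foldchange")
    return (sums / med).rename(f"{family}_foldchange")


def family_ratio(
    mrna: CladeAbundanceTable, families: tuple[str, str] = ("AMT1", "NRT2")
) -> tuple[pd.DataFrame, dict]:
    """Site-level AMT1:NRT2 transcript ratio and its depth contrast.

    Summed transcripts of each family are aggregated over clades and
    size fractions per station x depth; the ratio is masked where the
    denominator family's sum is zero.  A paired one-tail t-test over
    stations sampled at both depths asks whether the surface ratio is
    *lower* than the DCM ratio.
    """
    fam_a, fam_b = families
    meta = mrna.sample_meta
    sites = [site_key(st, d) for st, d in zip(meta["station"], meta["depth"])]
    sums = {}
    for fam in families:
        rows = mrna.clade_meta.index[mrna.clade_meta["family"] == fam]
        per_sample = mrna.values.loc[rows].sum(axis=0)
        sums[fam] = per_sample.groupby(sites).sum()
    df = pd.DataFrame(sums)
    df["station"] = [s.split("|")[0] for s in df.index]
    df["depth"] = [s.split("|")[1] for s in df.index]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ratio"] = df[fam_a] / df[fam_b].where(df[fam_b] > 0)
    n_masked = int(df["ratio"].isna().sum())

    wide = df.pivot_table(index="station", columns="depth", values="ratio")
    test: dict = {"t": np.nan, "p": np.nan, "n": 0, "n_masked_sites": n_masked}
    if "SRF" in wide.columns and "DCM" in wide.columns:
        paired = wide.dropna(subset=["SRF", "DCM"])
        if len(paired) >= 2:
            t, p = _paired_onetail(
                paired["SRF"].to_numpy(), paired["DCM"].to_numpy(), "less")
            test.update(t=t, p=p, n=len(paired))
    return df, test
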