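"""Surface-vs-DCM contrasts and correlation screens.

Houses the environmental Spearman screens with Benjamini-Hochberg FDR
control, the per-station vertical community turnover (zero-adjusted
Bray-Curtis between a station's surface and DCM transcript profiles),
the diatom-prokaryote Pearson correlation matrices, and the 2x2
Fisher's exact comparison of predicted-localization proportions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio
from statsmodels.stats.multitest import multipletests

from .community import zero_adjusted_dissimilarity
from .tables import CladeAbundanceTable, site_key


def env_correlation_screen(
    responses: pd.DataFrame,
    env: pd.DataFrame,
    method: str = "spearman",
    coeff_threshold: float = 0.30,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate every response with every environmental variable.

    ``responses`` is sample/site x response; rows are aligned with
    ``env`` on their shared index.  Raw p-values are
    Benjamini-Hochberg-adjusted across the whole screen, and a pair is
    flagged significant when adjusted p < ``alpha`` AND
    |coefficient| > ``coeff_threshold`` (the dual criterion used for
    transcript-environment screens).  Pairs with fewer than 4 paired
    observations or a constant member are reported unflagged with a
    reason code.
    """
    corr_fn = {"spearman": stats.spearmanr, "pearson": stats.pearsonr}[method]
    shared = responses.index.intersection(env.index)
    rows = []
    for resp in responses.columns:
        for var in env.columns:
            x = responses.loc[shared, resp].to_numpy(dtype=float)
            y = env.loc[shared, var].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            reason = ""
            if ok.sum() < 4:
                reason = "insufficient_n"
            elif np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                reason = "constant"
            if reason:
                rows.append((resp, var, np.nan, np.nan, int(ok.sum()), reason))
                continue
            r, p = corr_fn(x[ok], y[ok])
            rows.append((resp, var, float(r), float(p), int(ok.sum()), ""))
    screen = pd.DataFrame(
        rows, columns=["response", "variable", "coefficient", "p_raw", "n", "reason"])
    screen["p_adj"] = np.nan
    tested = screen["p_raw"].notna()
    if tested.any():
        screen.loc[tested, "p_adj"] = multipletests(
            screen.loc[tested, "p_raw"], method="fdr_bh")[1]
    screen["significant"] = (
        (screen["p_adj"] < alpha)
        & (screen["coefficient"].abs() > coeff_threshold)
    ).fillna(False)
    screen.attrs["method"] = method
    screen.attrs["adjustment"] = "fdr_bh"
    return screen


def vertical_switch(
    mrna: CladeAbundanceTable, env: pd.DataFrame, dummy: float | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-station vertical community turnover and its drivers.

    For every station sampled at both depths, the zero-adjusted
    Bray-Curtis distance between its surface and DCM clade-transcript
    vectors (clade occurrences summed over size fractions) is computed;
    the distance is then Spearman-screened (BH-adjusted) against each
    environmental variable taken at each depth.
    """
    meta = mrna.sample_meta
    sites = [site_key(st, d) for st, d in zip(meta["station"], meta["depth"])]
    site_sum = mrna.values.T.groupby(sites).sum().T  # clade x site

    stations = meta["station"].unique()
    dual = [st for st in stations
            if site_key(st, "SRF") in site_sum.columns
            and site_key(st, "DCM") in site_sum.columns]
    if not dual:
        raise ValueError("no station was sampled at both depths")

    cols = ([site_key(st, "SRF") for st in dual]
            + [site_key(st, "DCM") for st in dual])
    d = zero_adjusted_dissimilarity(site_sum[cols], "braycurtis_abund", dummy)
    dist = pd.Series(
        [d.values.at[site_key(st, "SRF"), site_key(st, "DCM")] for st in dual],
        index=pd.Index(dual, name="station"), name="srf_dcm_distance")

    blocks = []
    for depth in ("SRF", "DCM"):
        keys = [site_key(st, depth) for st in dual]
        env_depth = env.reindex(keys)
        env_depth.index = dual
        screen = env_correlation_screen(dist.to_frame(), env_depth,
                                        method="spearman")
        screen["depth"] = depth
        blocks.append(screen)
    screens = pd.concat(blocks, ignore_index=True)
    # re-adjust across both depths jointly (one screen, one family of tests)
    tested = screens["p_raw"].notna()
    if tested.any():
        screens.loc[tested, "p_adj"] = multipletests(
            screens.loc[tested, "p_raw"], method="fdr_bh")[1]
    screens["significant"] = (
        (screens["p_adj"] < 0.05) & (screens["coefficient"].abs() > 0.30)
    ).fillna(False)
    return dist, screens


def cross_kingdom_screen(
    clade_mrna: CladeAbundanceTable,
    ko: pd.DataFrame,
    fraction: str = "20-180",
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Diatom clade x prokaryotic KO Pearson matrices, per depth.

    Clade transcript occurrences are taken from the stated diatom size
    fraction; KO abundances come from the prokaryotic fraction and are
    keyed by site.  Entries are Pearson r where p < ``alpha`` and NaN
    (masked) otherwise — deliberately unadjusted, so ~alpha of
    independent pairs stay unmasked by chance.  Depths with fewer than
    4 shared samples are skipped with a warning.
    """
    sub = clade_mrna.subset_fraction(fraction)
    meta = sub.sample_meta
    out: dict[str, pd.DataFrame] = {}
    for depth in ("SRF", "DCM"):
        mask = meta["depth"] == depth
        cols = sub.values.columns[mask]
        sites = [site_key(st, depth) for st in meta.loc[mask, "station"]]
        shared = [(c, s) for c, s in zip(cols, sites) if s in ko.columns]
        if len(shared) < 4:
            warnings.warn(f"{depth}: fewer than 4 shared samples, skipped")
            continue
        ccols = [c for c, _ in shared]
        kcols = [s for _, s in shared]
        cmat = sub.values[ccols].to_numpy(dtype=float)
        kmat = ko[kcols].to_numpy(dtype=float)
        r = np.full((cmat.shape[0], kmat.shape[0]), np.nan)
        for i in range(cmat.shape[0]):
            x = cmat[i]
            if np.ptp(x) == 0:
                continue
            for j in range(kmat.shape[0]):
                y = kmat[j]
                if np.ptp(y) == 0:
                    continue
                rr, pp = stats.pearsonr(x, y)
                if pp < alpha:
                    r[i, j] = rr
        out[depth] = pd.DataFrame(r, index=sub.values.index, columns=ko.index)
    return out


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns the conditional maximum-likelihood odds ratio and the exact
    two-sided p-value (minimum-likelihood summation over the
    hypergeometric null).  A zero row or column margin makes every
    table equally likely under the null: p = 1 by convention, odds
    ratio NaN.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be nonnegative integers")
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, 1.0
    res = stats.fisher_exact(table, alternative="two-sided")
    orr = odds_ratio(table, kind="conditional")
    return float(orr.statistic), float(res.pvalue)


def fisher_2x2_one_sided(a: int, b: int, c: int, d: int,
                         alternative: str = "greater") -> tuple[float, float]:
    """One-sided variant (sidedness of such proportion comparisons is a
    user choice; the two-sided minimum-likelihood rule is the default)."""
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, 1.0
    res = stats.fisher_exact(table, alternative=alternative)
    orr = odds_ratio(table, kind="conditional")
    return float(orr.statistic), float(res.pvalue)
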