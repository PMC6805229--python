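"""Normalization arithmetic, presence rule, richness and family ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diatom_ntrans import abundance
from diatom_ntrans.abundance import (
    PresenceAbsenceMatrix,
    _paired_onetail,
    derive_presence,
    family_ratio,
    fold_change_over_median,
    mrna_dna_comparison,
    normalize_occurrence,
    richness,
)
from diatom_ntrans.tables import CladeAbundanceTable


def make_table(values, kb, totals, fractions=None, stations=None, depths=None,
               families=None):
    values = pd.DataFrame(values, dtype=float)
    n_clades, n_samples = values.shape
    clades = [f"AMT1_{i}" if (families or ["AMT1"] * n_clades)[i] == "AMT1"
              else f"NRT2_{i}" for i in range(n_clades)]
    values.index = pd.Index(clades, name="clade")
    fractions = fractions or ["0.8-5"] * n_samples
    stations = stations or [f"ST{i:03d}" for i in range(n_samples)]
    depths = depths or ["SRF"] * n_samples
    samples = [f"{st}|{d}|{f}" for st, d, f in zip(stations, depths, fractions)]
    values.columns = samples
    clade_meta = pd.DataFrame(
        {"family": families or ["AMT1"] * n_clades,
         "clade_id": [str(i) for i in range(n_clades)],
         "kb_covered": kb}, index=values.index)
    sample_meta = pd.DataFrame(
        {"station": stations, "depth": depths, "fraction": fractions,
         "diatom_total": totals}, index=pd.Index(samples, name="sample"))
    return CladeAbundanceTable(values, "raw_reads", clade_meta, sample_meta)


class TestNormalize:
    def test_stated_formula(self):
        t = make_table([[100]], kb=[2.0], totals=[1_000_000])
        occ = normalize_occurrence(t)
        assert occ.values.iloc[0, 0] == pytest.approx(5e-5)

    def test_zero_reads_zero_occurrence_even_with_zero_kb(self):
        t = make_table([[0, 0], [0, 4]], kb=[0.0, 2.0], totals=[10, 10])
        occ = normalize_occurrence(t)
        assert (occ.values.iloc[0] == [0.0, 0.0]).all()
        assert occ.values.iloc[1, 0] == 0.0
        assert occ.values.iloc[1, 1] == pytest.approx(4 / 2.0 / 10)

    def test_nonzero_reads_with_zero_kb_is_error(self):
        t = make_table([[5]], kb=[0.0], totals=[10])
        with pytest.raises(ValueError, match="kb_covered"):
            normalize_occurrence(t)

    def test_exact_scale_relations(self):
        """Occurrence is linear in reads and inversely proportional to kb
        and totals — exactly, by power-of-two scaling."""
        rng = np.random.default_rng(0)
        reads = rng.integers(0, 50, size=(3, 4))
        t1 = make_table(reads, kb=[1.0, 2.0, 0.5], totals=[100, 200, 400, 800])
        o1 = normalize_occurrence(t1).values.to_numpy()
        t2 = make_table(reads * 2, kb=[1.0, 2.0, 0.5], totals=[100, 200, 400, 800])
        assert np.array_equal(normalize_occurrence(t2).values.to_numpy(), o1 * 2)
        t3 = make_table(reads, kb=[1.0, 2.0, 0.5],
                        totals=[200, 400, 800, 1600])
        assert np.array_equal(normalize_occurrence(t3).values.to_numpy(), o1 / 2)
        t4 = make_table(reads, kb=[2.0, 4.0, 1.0], totals=[100, 200, 400, 800])
        assert np.array_equal(normalize_occurrence(t4).values.to_numpy(), o1 / 2)

    def test_wrong_layer_rejected(self):
        t = make_table([[1]], kb=[1.0], totals=[10])
        occ = normalize_occurrence(t)
        with pytest.raises(ValueError, match="raw_reads"):
            normalize_occurrence(occ)


class TestPresence:
    def test_rule_any_fraction_positive(self):
        t = make_table(
            [[0, 0, 3, 0], [0, 0, 0, 0]],
            kb=[1, 1], totals=[10, 10, 10, 10],
            fractions=["0.8-5", "5-20", "20-180", "180-2000"],
            stations=["ST1"] * 4)
        pa = derive_presence(normalize_occurrence(t))
        assert pa.values.iloc[0, 0] == 1   # one fraction of four
        assert pa.values.iloc[1, 0] == 0   # zero everywhere

    def test_single_available_fraction(self):
        t = make_table([[2]], kb=[1], totals=[10], stations=["ST1"])
        pa = derive_presence(normalize_occurrence(t))
        assert pa.values.iloc[0, 0] == 1

    def test_presence_identical_before_and_after_normalization(self, small_scenario):
        _, mrna, _, _, _ = small_scenario
        pa_raw = derive_presence(mrna)
        pa_norm = derive_presence(normalize_occurrence(mrna))
        pd.testing.assert_frame_equal(pa_raw.values, pa_norm.values)

    def test_richness_invariant_to_positive_rescaling(self, occurrence_tables):
        occ = occurrence_tables[0]
        scaled = occ.with_values(occ.values * 17.3, occ.layer)
        pd.testing.assert_frame_equal(derive_presence(occ).values,
                                      derive_presence(scaled).values)


def _pa(values, stations, depths, families):
    values = pd.DataFrame(np.asarray(values, dtype=int))
    clades = [f"{fam}_{i}" for i, fam in enumerate(families)]
    sites = [f"{st}|{d}" for st, d in zip(stations, depths)]
    values.index = pd.Index(clades, name="clade")
    values.columns = sites
    meta = pd.DataFrame({"station": stations, "depth": depths},
                        index=pd.Index(sites, name="site"))
    clade_meta = pd.DataFrame(
        {"family": families, "clade_id": [str(i) for i in range(len(families))],
         "kb_covered": 1.0}, index=values.index)
    return PresenceAbsenceMatrix(values, meta, "test"), clade_meta


class TestRichness:
    def test_row_of_three_ones(self):
        pa, meta = _pa([[1, 1, 1], [0, 1, 0]],
                       ["A", "B", "C"], ["SRF"] * 3, ["AMT1", "NRT2"])
        rs = richness(pa, meta)
        assert rs.richness["AMT1"].tolist() == [1, 1, 1]
        assert rs.richness["NRT2"].tolist() == [0, 1, 0]

    def test_identical_matrices_give_unit_line(self):
        rng = np.random.default_rng(1)
        block = rng.integers(0, 2, size=(4, 8))
        pa, meta = _pa(np.vstack([block, block]),
                       [f"S{i}" for i in range(8)], ["SRF"] * 8,
                       ["AMT1"] * 4 + ["NRT2"] * 4)
        rs = richness(pa, meta)
        row = rs.per_depth.loc["SRF"]
        assert row["r"] == pytest.approx(1.0)
        assert row["slope"] == pytest.approx(1.0)
        assert row["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_constructed_offset_recovers_slope_and_intercept(self):
        """NRT2 richness = 2 + AMT1 richness exactly -> slope 1, intercept 2."""
        amt1 = np.array([[1, 1, 0, 1, 0],
                         [0, 1, 0, 1, 0],
                         [0, 1, 0, 0, 0]])
        nrt2 = np.zeros((5, 5), dtype=int)
        target = amt1.sum(axis=0) + 2
        for j, r in enumerate(target):
            nrt2[:r, j] = 1
        pa, meta = _pa(np.vstack([amt1, nrt2]),
                       [f"S{i}" for i in range(5)], ["SRF"] * 5,
                       ["AMT1"] * 3 + ["NRT2"] * 5)
        rs = richness(pa, meta)
        row = rs.per_depth.loc["SRF"]
        assert row["slope"] == pytest.approx(1.0)
        assert row["intercept"] == pytest.approx(2.0)

    def test_fewer_than_three_sites_undefined(self):
        pa, meta = _pa([[1, 0], [0, 1]], ["A", "B"], ["SRF"] * 2,
                       ["AMT1", "NRT2"])
        rs = richness(pa, meta)
        assert np.isnan(rs.per_depth.loc["SRF", "r"])


class TestMrnaDna:
    def test_identical_layers(self, occurrence_tables):
        occ = occurrence_tables[0]
        corr, ratios = mrna_dna_comparison(occ, occ)
        assert corr["r"].dropna().to_numpy() == pytest.approx(1.0)
        assert ratios.stack().dropna().to_numpy() == pytest.approx(1.0)

    def test_affine_triple(self, occurrence_tables):
        occ = occurrence_tables[0]
        dna = occ.with_values(occ.values / 3.0, "dna_occurrence")
        corr, ratios = mrna_dna_comparison(occ, dna)
        assert corr["r"].dropna().to_numpy() == pytest.approx(1.0)
        assert ratios.stack().dropna().to_numpy() == pytest.approx(3.0)

    def test_hand_computed_pearson(self):
        m = make_table([[1, 2, 3, 4]], kb=[1], totals=[1, 1, 1, 1],
                       stations=["A", "B", "C", "D"])
        d = make_table([[1, 3, 2, 5]], kb=[1], totals=[1, 1, 1, 1],
                       stations=["A", "B", "C", "D"])
        occ_m = normalize_occurrence(m)
        occ_d = normalize_occurrence(d, "dna_occurrence")
        corr, _ = mrna_dna_comparison(occ_m, occ_d)
        x, y = np.array([1, 2, 3, 4.0]), np.array([1, 3, 2, 5.0])
        expected = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean())**2).sum() * ((y - y.mean())**2).sum()))
        got = corr.loc[(corr["family"] == "AMT1") & (corr["fraction"] == "all"), "r"]
        assert got.iloc[0] == pytest.approx(expected)

    def test_no_overlap_is_error(self):
        a = make_table([[1]], kb=[1], totals=[1], stations=["A"])
        b = make_table([[1]], kb=[1], totals=[1], stations=["B"])
        with pytest.raises(ValueError, match="overlap"):
            mrna_dna_comparison(normalize_occurrence(a),
                                normalize_occurrence(b, "dna_occurrence"))


class TestFoldChange:
    def test_direct_arithmetic(self):
        t = make_table([[1, 2, 3]], kb=[1], totals=[1, 1, 1],
                       stations=["A", "B", "C"])
        occ = normalize_occurrence(t)
        fc = fold_change_over_median(occ, "AMT1")
        assert fc.tolist() == pytest.approx([0.5, 1.0, 1.5])

    def test_permutation_invariance(self):
        t = make_table([[3, 1, 2]], kb=[1], totals=[1, 1, 1],
                       stations=["A", "B", "C"])
        fc = fold_change_over_median(normalize_occurrence(t), "AMT1")
        assert fc["A|SRF|0.8-5"] == pytest.approx(1.5)
        assert fc["B|SRF|0.8-5"] == pytest.approx(0.5)

    def test_zero_median_masked(self):
        t = make_table([[0, 0, 5]], kb=[1], totals=[1, 1, 1],
                       stations=["A", "B", "C"])
        fc = fold_change_over_median(normalize_occurrence(t), "AMT1")
        assert fc.isna().all()


class TestFamilyRatio:
    def _ratio_table(self, srf, dcm):
        n = len(srf)
        stations = [f"S{i}" for i in range(n)] * 2
        depths = ["SRF"] * n + ["DCM"] * n
        amt1 = np.concatenate([srf, dcm])
        values = np.vstack([amt1, np.ones(2 * n)])
        return make_table(values, kb=[1, 1], totals=[1] * 2 * n,
                          stations=stations, depths=depths,
                          families=["AMT1", "NRT2"])

    def test_identical_ratios_null(self):
        t = self._ratio_table(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]))
        _, test = family_ratio(normalize_occurrence(t))
        assert test["t"] == 0.0
        assert test["p"] == 0.5

    def test_degenerate_constant_shift(self):
        t = self._ratio_table(np.array([1.0, 2, 3]), np.array([2.0, 3, 4]))
        _, test = family_ratio(normalize_occurrence(t))
        assert test["p"] == 0.0    # SRF uniformly lower: favored direction

    def test_zero_denominator_masked(self):
        values = np.array([[1.0, 1.0], [0.0, 1.0]])
        t = make_table(values, kb=[1, 1], totals=[1, 1],
                       stations=["A", "B"], families=["AMT1", "NRT2"])
        ratios, test = family_ratio(normalize_occurrence(t))
        assert ratios["ratio"].isna().sum() == 1
        assert test["n_masked_sites"] == 1

    def test_planted_shift_power(self):
        """Paired one-tail test detects a one-unit mean shift (sigma = 1,
        n = 40 stations) at p < 0.001 in >= 95% of seeds."""
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            srf = rng.normal(0.0, 1.0, size=40)
            dcm = srf + 1.0 + rng.normal(0.0, 1.0, size=40)
            _, p = _paired_onetail(srf, dcm, "less")
            if p < 1e-3:
                hits += 1
        assert hits >= 0.95 * n_seeds
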