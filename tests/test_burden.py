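"""Burden metrics, burden regressions, modifier correction, sibling sharing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvgwas.burden import (
    burden_regression,
    compute_burden,
    high_confidence,
    meta_fixed_effects,
    modifier_correction,
    modifier_matrix,
    sex_difference_test,
    sibling_sharing,
)

from conftest import toy_calls


def hc_calls(rows):
    df = toy_calls(rows)
    return high_confidence(df)


class TestComputeBurden:
    def test_mb_additivity(self):
        calls = hc_calls(
            [("s1", "1", 1, 2_000_000, 3, 0.9), ("s1", "2", 1, 500_000, 1, -0.9)]
        )
        out = compute_burden(calls)
        assert out.loc["s1", "mb_dup"] == pytest.approx(2.0, rel=1e-5)
        assert out.loc["s1", "mb_del"] == pytest.approx(0.5, rel=1e-5)
        assert out.loc["s1", "mb_cnv"] == pytest.approx(
            out.loc["s1", "mb_dup"] + out.loc["s1", "mb_del"]
        )

    def test_zero_call_sample_gets_zero_row(self):
        calls = hc_calls([("s1", "1", 1, 1_000_000, 3, 0.9)])
        out = compute_burden(calls, samples=["s1", "s2"])
        assert (out.loc["s2"] == 0).all()

    def test_gene_count_requires_qualifying_feature_overlap(self):
        genes = pd.DataFrame(
            {
                "chrom": ["1"] * 4,
                "start": [100, 2_000, 3_000, 10_000],
                "end": [200, 2_100, 3_100, 10_100],
                "gene": ["g1", "g2", "g3", "g4_intron_only"],
                "feature_class": ["exon", "UTR3", "splice", "intron"],
            }
        )
        calls = hc_calls([("s1", "1", 50, 11_000, 1, -0.9)])
        out = compute_burden(calls, genes=genes)
        # the intron-class feature never qualifies even though it overlaps
        assert out.loc["s1", "genes_del"] == 3
        assert out.loc["s1", "genes_cnv"] == 3

    def test_sex_chromosome_calls_excluded_by_default(self):
        calls = hc_calls([("s1", "X", 1, 1_000_000, 3, 0.9)])
        out = compute_burden(calls, samples=["s1"])
        assert out.loc["s1", "mb_cnv"] == 0.0

    def test_burden_split_sums_exactly(self, rng):
        rows = []
        for i in range(30):
            s = int(rng.integers(1, 5_000_000))
            rows.append(
                (f"s{i % 7}", "1", s, s + int(rng.integers(10_000, 900_000)),
                 3 if rng.random() < 0.5 else 1, 0.9)
            )
        out = compute_burden(hc_calls(rows))
        np.testing.assert_allclose(out["mb_cnv"], out["mb_dup"] + out["mb_del"], rtol=1e-12)


class TestBurdenRegression:
    def test_planted_slope_recovered(self, rng):
        n = 20_000
        burden = pd.Series(rng.exponential(0.3, n), index=[f"s{i}" for i in range(n)])
        y = pd.Series(-0.2 * burden + rng.standard_normal(n), index=burden.index)
        fit = burden_regression(y, burden)
        assert abs(fit["beta"] - (-0.2)) < 3 * fit["se"]

    def test_permuted_burden_is_null(self, rng):
        n = 2_000
        idx = [f"s{i}" for i in range(n)]
        burden = pd.Series(rng.exponential(0.3, n), index=idx)
        y = pd.Series(rng.standard_normal(n), index=idx)
        assert burden_regression(y, burden)["p"] > 1e-3

    def test_constant_burden_rejected(self):
        idx = ["a", "b", "c"]
        with pytest.raises(ValueError):
            burden_regression(
                pd.Series([1.0, 2.0, 3.0], index=idx), pd.Series([1.0, 1.0, 1.0], index=idx)
            )


class TestModifierCorrection:
    def setup_cohort(self, rng, n=4_000, beta=-0.8):
        """Monogenic architecture: one causal deletion region drives the trait."""
        idx = [f"s{i}" for i in range(n)]
        carrier = rng.random(n) < 0.05
        rows = [
            (idx[i], "1", 1_000_000, 2_000_000, 1, -0.9) for i in np.flatnonzero(carrier)
        ]
        calls = hc_calls(rows)
        y = pd.Series(beta * carrier + rng.standard_normal(n), index=idx)
        burden = compute_burden(calls, samples=idx)["mb_cnv"]
        cnvrs = pd.DataFrame({"chrom": ["1"], "start": [1_000_000], "end": [2_000_000]})
        return idx, calls, y, burden, cnvrs, carrier, None

    def test_noncarriers_unchanged(self, rng):
        idx, calls, y, burden, cnvrs, carrier, _ = self.setup_cohort(rng)
        y_corr, b_corr = modifier_correction(y, burden, cnvrs, calls)
        non = np.asarray(~carrier)
        # burden untouched for non-carriers; trait shifts only by the
        # regression intercept refit (identical offset for the G=0 class)
        np.testing.assert_allclose(b_corr[non], burden[non], rtol=1e-12)

    def test_monogenic_signal_nulled(self, rng):
        # the mirror-trait association is entirely driven by one CNVR;
        # removing carrier status and region Mb must kill the burden signal
        idx, calls, y, burden, cnvrs, *_ = self.setup_cohort(rng)
        before = burden_regression(y, burden)
        y_corr, b_corr = modifier_correction(y, burden, cnvrs, calls)
        assert b_corr.max() == 0.0  # every call overlaps the CNVR
        with pytest.raises(ValueError):
            burden_regression(y_corr, b_corr)  # burden now constant: no signal left
        assert before["p"] < 1e-4

    def test_no_cnvrs_is_identity(self, rng):
        idx, calls, y, burden, *_ = self.setup_cohort(rng)
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        y2, b2 = modifier_correction(y, burden, empty, calls)
        pd.testing.assert_series_equal(y2, y)
        pd.testing.assert_series_equal(b2, burden)

    def test_deletion_carrier_coded_minus_one(self):
        calls = hc_calls([("s1", "1", 1_500_000, 1_600_000, 1, -0.9)])
        cnvrs = pd.DataFrame({"chrom": ["1"], "start": [1_000_000], "end": [2_000_000]})
        G = modifier_matrix(cnvrs, calls, ["s1", "s2"])
        assert G.loc["s1", 0] == -1
        assert G.loc["s2", 0] == 0

    def test_type_specific_matrix_zeroes_other_type(self):
        calls = hc_calls(
            [("s1", "1", 1_500_000, 1_600_000, 1, -0.9),
             ("s2", "1", 1_500_000, 1_600_000, 3, 0.9)]
        )
        cnvrs = pd.DataFrame({"chrom": ["1"], "start": [1_000_000], "end": [2_000_000]})
        G_dup = modifier_matrix(cnvrs, calls, ["s1", "s2"], kind="dup")
        assert G_dup.loc["s1", 0] == 0 and G_dup.loc["s2", 0] == 1


class TestSexDifference:
    def test_small_sample_matches_exhaustive_enumeration(self):
        x = np.array([1.2, 3.4, 2.2])
        y = np.array([0.5, 4.1, 2.9, 3.3])
        sexes = pd.Series([0] * 3 + [1] * 4, index=list("abcdefg"))
        burden = pd.Series(np.concatenate([x, y]), index=list("abcdefg"))
        p = sex_difference_test(burden, sexes)
        # exhaustive rank-permutation oracle
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[:3].sum()
        stats_all = [
            sum(c) for c in itertools.combinations(ranks, 3)
        ]
        mean = np.mean(stats_all)
        extreme = np.mean([abs(s - mean) >= abs(obs - mean) - 1e-9 for s in stats_all])
        assert p == pytest.approx(extreme, abs=1e-9)

    def test_location_shift_detected_at_scale(self, rng):
        idx = [f"s{i}" for i in range(2_000)]
        sex = pd.Series(rng.integers(0, 2, 2_000), index=idx)
        burden = pd.Series(rng.exponential(1.0, 2_000) + 0.5 * sex, index=idx)
        assert sex_difference_test(burden, sex) < 1e-6

    def test_empty_group_rejected(self):
        idx = ["a", "b"]
        with pytest.raises(ValueError):
            sex_difference_test(
                pd.Series([1.0, 2.0], index=idx), pd.Series([0, 0], index=idx)
            )


class TestMetaFixedEffects:
    def test_equal_inputs_halve_the_variance(self):
        beta, se, _ = meta_fixed_effects(0.5, 0.1, 0.5, 0.1)
        assert beta == pytest.approx(0.5)
        assert se == pytest.approx(0.1 / np.sqrt(2))

    def test_opposite_betas_cancel(self):
        beta, _, p = meta_fixed_effects(1.0, 0.2, -1.0, 0.2)
        assert beta == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_weights(self):
        beta, se, _ = meta_fixed_effects(1.0, 1.0, 0.0, 0.5)
        assert beta == pytest.approx(0.2)
        assert se == pytest.approx(1 / np.sqrt(5))

    def test_infinite_variance_study_is_ignored(self):
        beta, se, _ = meta_fixed_effects(0.7, 0.1, -5.0, 1e6)
        assert beta == pytest.approx(0.7, abs=1e-6)
        assert se == pytest.approx(0.1, abs=1e-6)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed_effects(1.0, 0.0, 1.0, 0.5)


class TestSiblingSharing:
    def test_identical_calls_share_fully(self):
        idx_calls = toy_calls([("i1", "1", 1_000_000, 2_000_000, 3, 0.9)])
        sib_calls = toy_calls([("b1", "1", 1_000_000, 2_000_000, 3, 0.9)])
        pairs = pd.DataFrame({"index_id": ["i1"], "sibling_id": ["b1"]})
        out = sibling_sharing(pairs, idx_calls, sib_calls, seed=1)
        assert out["mean_shared_fraction"] == 1.0

    def test_overlap_boundary_at_25kb(self):
        pairs = pd.DataFrame({"index_id": ["i1"], "sibling_id": ["b1"]})
        idx_calls = toy_calls([("i1", "1", 1, 100_000, 3, 0.9)])
        # overlap 24,999 bp: not shared
        sib_short = toy_calls([("b1", "1", 75_002, 200_000, 3, 0.9)])
        assert (
            sibling_sharing(pairs, idx_calls, sib_short, seed=1)["mean_shared_fraction"] == 0.0
        )
        # overlap exactly 25,000 bp: shared
        sib_exact = toy_calls([("b1", "1", 75_001, 200_000, 3, 0.9)])
        assert (
            sibling_sharing(pairs, idx_calls, sib_exact, seed=1)["mean_shared_fraction"] == 1.0
        )

    def test_type_mismatch_never_shared(self):
        pairs = pd.DataFrame({"index_id": ["i1"], "sibling_id": ["b1"]})
        idx_calls = toy_calls([("i1", "1", 1, 100_000, 3, 0.9)])
        sib_calls = toy_calls([("b1", "1", 1, 100_000, 1, -0.9)])
        assert (
            sibling_sharing(pairs, idx_calls, sib_calls, seed=1)["mean_shared_fraction"] == 0.0
        )

    def test_low_confidence_calls_ignored(self):
        pairs = pd.DataFrame({"index_id": ["i1"], "sibling_id": ["b1"]})
        idx_calls = toy_calls(
            [("i1", "1", 1, 100_000, 3, 0.9), ("i1", "2", 1, 100_000, 3, 0.3)]
        )
        sib_calls = toy_calls([("b1", "1", 1, 100_000, 3, 0.9)])
        out = sibling_sharing(pairs, idx_calls, sib_calls, seed=1)
        # the low-QS chromosome-2 call does not enter the denominator
        assert out["mean_shared_fraction"] == 1.0
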