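"""CNVR definition, cross-model merging, annotation, region statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cnvgwas.encoding import ModelGenotypes
from cnvgwas.probes import ProbeMap
from cnvgwas.regions import (
    annotate_region,
    binomial_enrichment_test,
    define_cnvr,
    fisher_exact_cmle,
    merge_signals,
    per_copy_direction,
    snp_density_binomial_test,
    welch_t_test,
)


def geno_from_rows(rows, positions, chrom="1"):
    rows = np.asarray(rows, dtype=np.int8)
    probes = ProbeMap(
        pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(rows.shape[0])],
                "chrom": chrom,
                "pos": positions,
            }
        )
    )
    samples = [f"s{j}" for j in range(rows.shape[1])]
    return ModelGenotypes(model="mirror", probes=probes, samples=samples, dosage=rows)


class TestDefineCNVR:
    def test_uncorrelated_lead_gives_zero_length_region(self, rng):
        rows = rng.choice([0, 1, 2], size=(3, 400), p=[0.05, 0.9, 0.05])
        geno = geno_from_rows(rows, [1_000, 2_000, 3_000])
        chrom, start, end = define_cnvr("p1", geno)
        assert (chrom, start, end) == ("1", 2_000, 2_000)

    def test_perfect_block_spans_block_extent(self, rng):
        row = rng.choice([0, 1, 2], size=400, p=[0.05, 0.9, 0.05])
        positions = [100_000 * (i + 1) for i in range(10)]
        geno = geno_from_rows([row] * 10, positions)
        chrom, start, end = define_cnvr("p4", geno)
        assert (start, end) == (100_000, 1_000_000)

    def test_correlated_probe_beyond_3mb_excluded(self, rng):
        row = rng.choice([0, 1, 2], size=400, p=[0.05, 0.9, 0.05])
        geno = geno_from_rows([row, row.copy()], [1_000_000, 4_100_000])
        _, start, end = define_cnvr("p0", geno)
        assert (start, end) == (1_000_000, 1_000_000)

    def test_missing_lead_rejected(self, rng):
        geno = geno_from_rows(rng.choice([0, 1, 2], size=(2, 50)), [100, 200])
        with pytest.raises(ValueError, match="absent"):
            define_cnvr("nope", geno)


def signal(trait, model, start, end, beta, p, chrom="1", lead="pL"):
    return {
        "trait": trait,
        "model": model,
        "chrom": chrom,
        "start": start,
        "end": end,
        "lead_probe": lead,
        "beta": beta,
        "se": 0.1,
        "p": p,
    }


class TestMergeSignals:
    def test_concordant_overlapping_same_trait_merge(self):
        df = pd.DataFrame(
            [
                signal("bmi", "mirror", 100, 500, beta=0.4, p=1e-10),
                signal("bmi", "del-only", 300, 900, beta=-0.5, p=1e-8),
            ]
        )
        out = merge_signals(df)
        assert len(out) == 1
        assert out.loc[0, "start"] == 100 and out.loc[0, "end"] == 900
        assert out.loc[0, "model"] == "mirror"  # smaller p wins
        assert out.loc[0, "models"] == "del-only,mirror"

    def test_different_traits_never_merge(self):
        df = pd.DataFrame(
            [
                signal("bmi", "mirror", 100, 500, beta=0.4, p=1e-10),
                signal("height", "mirror", 100, 500, beta=0.4, p=1e-9),
            ]
        )
        assert len(merge_signals(df)) == 2

    def test_u_shape_pair_is_discordant_under_mirror_reading(self):
        # dup-only beta>0 and del-only beta>0 disagree per copy: no merge
        df = pd.DataFrame(
            [
                signal("grip", "dup-only", 100, 500, beta=0.4, p=1e-10),
                signal("grip", "del-only", 200, 600, beta=0.4, p=1e-9),
            ]
        )
        assert len(merge_signals(df)) == 2

    def test_non_overlapping_intervals_stay_separate(self):
        df = pd.DataFrame(
            [
                signal("bmi", "mirror", 100, 200, beta=0.4, p=1e-10),
                signal("bmi", "mirror", 300, 400, beta=0.4, p=1e-9),
            ]
        )
        assert len(merge_signals(df)) == 2

    def test_merge_is_order_independent(self):
        base = [
            signal("bmi", "mirror", 100, 500, beta=0.4, p=1e-10),
            signal("bmi", "del-only", 300, 900, beta=-0.5, p=1e-8),
            signal("bmi", "dup-only", 850, 1200, beta=0.3, p=1e-7),
            signal("height", "mirror", 100, 500, beta=-0.2, p=1e-6),
        ]
        reference = merge_signals(pd.DataFrame(base))
        for perm in itertools.permutations(range(len(base))):
            out = merge_signals(pd.DataFrame([base[i] for i in perm]))
            pd.testing.assert_frame_equal(out, reference)

    def test_union_boundaries_contain_all_members(self):
        df = pd.DataFrame(
            [
                signal("bmi", "mirror", 100, 500, beta=0.4, p=1e-10),
                signal("bmi", "dup-only", 450, 900, beta=0.5, p=1e-8),
                signal("bmi", "del-only", 880, 1000, beta=-0.3, p=1e-7),
            ]
        )
        out = merge_signals(df)
        assert len(out) == 1
        assert out.loc[0, "start"] <= 100 and out.loc[0, "end"] >= 1000

    def test_per_copy_direction_convention(self):
        assert per_copy_direction("mirror", 0.5) == 1
        assert per_copy_direction("dup-only", -0.2) == -1
        assert per_copy_direction("del-only", -0.2) == 1


class TestAnnotateRegion:
    features = pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "2"],
            "start": [150, 90, 601, 100],
            "end": [300, 99, 700, 300],
            "gene": ["inside", "left", "right_abut", "other_chrom"],
        }
    )

    def test_contained_feature_reported_with_full_length(self):
        out = annotate_region(("1", 100, 600), self.features)
        row = out[out["gene"] == "inside"].iloc[0]
        assert row["overlap_bp"] == 151

    def test_abutting_feature_absent(self):
        out = annotate_region(("1", 100, 600), self.features)
        assert "left" not in set(out["gene"])
        assert "right_abut" not in set(out["gene"])

    def test_single_bp_overlap_reported(self):
        out = annotate_region(("1", 99, 99), self.features)
        assert set(out["gene"]) == {"left"}
        assert out.iloc[0]["overlap_bp"] == 1

    def test_chromosome_mismatch_empty(self):
        assert annotate_region(("7", 1, 10_000), self.features).empty

    def test_matches_brute_force_on_random_intervals(self, rng):
        feats = pd.DataFrame(
            {
                "chrom": "1",
                "start": rng.integers(1, 500, 40),
                "end": 0,
                "gene": [f"g{i}" for i in range(40)],
            }
        )
        feats["end"] = feats["start"] + rng.integers(0, 100, 40)
        region = ("1", 200, 260)
        out = set(annotate_region(region, feats)["gene"])
        brute = {
            f"g{i}"
            for i, (s, e) in enumerate(zip(feats["start"], feats["end"]))
            if min(e, 260) - max(s, 200) + 1 >= 1
        }
        assert out == brute


class TestSNPDensity:
    def test_exact_genome_density_gives_p_one(self):
        regions = pd.DataFrame({"chrom": ["1"], "start": [1], "end": [1000]})
        snps = pd.DataFrame({"chrom": ["1"] * 10, "pos": np.arange(10) * 100 + 1})
        # rate = total/genome chosen so expected successes = observed = 10
        out = snp_density_binomial_test(
            regions, snps, total_snp_signals=10_000, genome_length_bp=1_000_000
        )
        assert out["successes"] == 10
        assert out["p"] == pytest.approx(1.0)
        assert out["fold"] == pytest.approx(1.0)

    def test_zero_successes_matches_binomial_tail(self):
        regions = pd.DataFrame({"chrom": ["1"], "start": [1], "end": [10_000]})
        snps = pd.DataFrame({"chrom": ["2"], "pos": [5]})
        out = snp_density_binomial_test(
            regions, snps, total_snp_signals=1_000, genome_length_bp=1_000_000
        )
        # direct two-sided binomial mass at k=0 (minlike convention)
        expected = stats.binomtest(0, 10_000, 1e-3).pvalue
        assert out["p"] == pytest.approx(expected, rel=1e-12)

    def test_overlapping_regions_counted_once(self):
        regions = pd.DataFrame({"chrom": ["1", "1"], "start": [1, 500], "end": [1000, 1400]})
        snps = pd.DataFrame({"chrom": ["1"], "pos": [700]})
        out = snp_density_binomial_test(regions, snps, 10, genome_length_bp=1_000_000)
        assert out["trials"] == 1400
        assert out["successes"] == 1

    def test_non_autosomal_region_rejected(self):
        regions = pd.DataFrame({"chrom": ["X"], "start": [1], "end": [1000]})
        with pytest.raises(ValueError, match="autosomal"):
            snp_density_binomial_test(regions, pd.DataFrame({"chrom": [], "pos": []}), 10)

    def test_zero_region_length_impossible(self):
        regions = pd.DataFrame({"chrom": [], "start": [], "end": []})
        with pytest.raises(ValueError, match="zero"):
            snp_density_binomial_test(regions, pd.DataFrame({"chrom": [], "pos": []}), 10)

    def test_uniform_snps_give_calibrated_type_one_error(self, rng):
        # simulation oracle: with SNPs placed uniformly, p ~ U(0,1)
        genome = 1_000_000
        regions = pd.DataFrame({"chrom": ["1"], "start": [100_001], "end": [200_000]})
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            pos = rng.integers(1, genome + 1, size=300)
            snps = pd.DataFrame({"chrom": "1", "pos": pos})
            out = snp_density_binomial_test(regions, snps, 300, genome_length_bp=genome)
            rejections += out["p"] <= 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01


class TestCarrierGroupTests:
    def test_welch_identical_groups_null(self):
        x = np.arange(10.0)
        t, p = welch_t_test(x, x.copy())
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_empty_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test(np.array([]), np.array([1.0]))

    def test_fisher_balanced_table_is_null(self):
        res = fisher_exact_cmle([[1, 1], [1, 1]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_fisher_zero_margin_flagged(self):
        res = fisher_exact_cmle([[0, 0], [3, 5]])
        assert not res.or_defined

    @pytest.mark.parametrize(
        "table",
        [[[3, 1], [1, 3]], [[8, 2], [1, 5]], [[2, 7], [9, 4]], [[12, 2], [3, 9]]],
    )
    def test_cmle_matches_grid_search_oracle(self, table):
        # exhaustive-likelihood oracle: maximize the conditional likelihood
        # over a dense log-spaced psi grid
        t = np.asarray(table)
        res = fisher_exact_cmle(table, tol=1e-12)
        m1, n1, n = t[0].sum(), t[:, 0].sum(), t.sum()
        lo, hi = max(0, n1 - (n - m1)), min(m1, n1)
        x = np.arange(lo, hi + 1)
        from scipy.special import gammaln

        logw = (
            gammaln(m1 + 1) - gammaln(x + 1) - gammaln(m1 - x + 1)
            + gammaln(n - m1 + 1) - gammaln(n1 - x + 1) - gammaln(n - m1 - n1 + x + 1)
        )
        grid = np.exp(np.linspace(np.log(1e-4), np.log(1e4), 40_001))
        ll = logw[None, x == t[0, 0]].ravel() + t[0, 0] * np.log(grid)
        denom = np.array(
            [np.logaddexp.reduce(logw + x * lg) for lg in np.log(grid)]
        )
        best = grid[np.argmax(ll - denom)]
        assert res.odds_ratio == pytest.approx(best, rel=2e-3)

    def test_fisher_p_matches_r_convention(self):
        # scipy and R agree on the two-sided exact p for this table
        res = fisher_exact_cmle([[3, 1], [1, 3]])
        assert res.p == pytest.approx(0.4857142857, rel=1e-9)

    def test_binomial_enrichment_fold_and_p(self):
        fold, p = binomial_enrichment_test(10, 100, 0.05)
        assert fold == pytest.approx(2.0)
        assert p == pytest.approx(stats.binomtest(10, 100, 0.05).pvalue, rel=1e-12)

    def test_binomial_rejects_empty(self):
        with pytest.raises(ValueError):
            binomial_enrichment_test(0, 0, 0.05)


@given(
    beta=st.floats(-2, 2, allow_nan=False),
    model=st.sampled_from(["mirror", "dup-only", "del-only"]),
)
def test_direction_sign_flip_only_for_deletion_model(beta, model):
    d = per_copy_direction(model, beta)
    if beta == 0:
        assert d == 0
    elif model == "del-only":
        assert d == -np.sign(beta)
    else:
        assert d == np.sign(beta)
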