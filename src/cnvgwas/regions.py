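"""CNV region (CNVR) definition, cross-model merging, and region statistics.

An association lead probe is expanded into a CNVR by taking the most
distant probes within +/- 3 Mb whose dosage correlates with the lead at
r^2 >= 0.5. Signals from the three association models are merged into one
region when they involve the same trait, their CNVRs overlap by at least
1 bp, and their per-copy effect directions agree under a mirror reading
(deletion-only betas count with flipped sign); the merged region keeps the
union boundaries and the most significant model's statistics. Region-level
inference utilities include interval annotation, an exact binomial test of
SNP-signal density inside trait-associated regions versus the genome-wide
density, and the carrier-group tests (Welch t, Fisher's exact with the
conditional-MLE odds ratio, exact binomial enrichment).

All interval coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import gammaln

from .encoding import ModelGenotypes
from .association import pairwise_r2
from .probes import AUTOSOMES

AUTOSOMAL_GENOME_BP = 2_881_033_286


def define_cnvr(
    lead_probe: str,
    geno: ModelGenotypes,
    tag_r2: float = 0.5,
    window_bp: int = 3_000_000,
) -> tuple[str, int, int]:
    """Boundaries of the CNVR tagged by ``lead_probe``.

    Returns (chrom, start, end) spanning the outermost probes within
    +/- ``window_bp`` of the lead whose dosage r^2 with the lead reaches
    ``tag_r2``; the lead always qualifies, so an uncorrelated lead yields a
    zero-length region at its own position.
    """
    try:
        lead_row = geno.probes.loc_of(lead_probe)
    except KeyError:
        raise ValueError(f"lead probe {lead_probe!r} absent from genotype set") from None
    chrom = geno.probes.chrom[lead_row]
    pos = int(geno.probes.pos[lead_row])
    cand = geno.probes.rows_in_interval(chrom, pos - window_bp, pos + window_bp)
    sub = geno.dosage[cand]
    lead_local = int(np.flatnonzero(cand == lead_row)[0])
    r2 = pairwise_r2(sub)[lead_local]
    r2[lead_local] = 1.0
    tagged = cand[r2 >= tag_r2]
    positions = geno.probes.pos[tagged]
    return chrom, int(positions.min()), int(positions.max())


def per_copy_direction(model: str, beta: float) -> int:
    """Sign of the per-additional-copy effect implied by a model's beta."""
    s = int(np.sign(beta))
    return -s if model == "del-only" else s


def _overlap_1based(s1: int, e1: int, s2: int, e2: int) -> int:
    return min(e1, e2) - max(s1, s2) + 1


def merge_signals(signals: pd.DataFrame) -> pd.DataFrame:
    """Merge per-model CNVR signals into independent regions.

    ``signals`` needs columns trait, model, chrom, start, end, lead_probe,
    beta, se, p. Two signals join the same region iff they share the trait,
    their intervals overlap by >= 1 bp, and their per-copy directions agree;
    grouping is transitive (union-find), with all pairwise direction
    concordance guaranteed because direction is a per-signal property. The
    output is order-independent: one row per region with union boundaries,
    the smallest-p model's statistics, and the contributing model set.
    """
    df = signals.reset_index(drop=True).copy()
    df["direction"] = [per_copy_direction(m, b) for m, b in zip(df["model"], df["beta"])]

    parent = list(range(len(df)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    key = df[["trait", "chrom"]].apply(tuple, axis=1)
    for _, idx in df.groupby(key).groups.items():
        idx = list(idx)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                if df.at[i, "direction"] != df.at[j, "direction"]:
                    continue
                if df.at[i, "direction"] == 0:
                    continue
                if (
                    _overlap_1based(
                        df.at[i, "start"], df.at[i, "end"], df.at[j, "start"], df.at[j, "end"]
                    )
                    >= 1
                ):
                    union(i, j)

    rows = []
    groups: dict[int, list[int]] = {}
    for i in range(len(df)):
        groups.setdefault(find(i), []).append(i)
    for members in groups.values():
        block = df.iloc[members]
        best = block.sort_values(["p", "chrom", "start", "model"]).iloc[0]
        rows.append(
            {
                "trait": best["trait"],
                "chrom": best["chrom"],
                "start": int(block["start"].min()),
                "end": int(block["end"].max()),
                "lead_probe": best["lead_probe"],
                "model": best["model"],
                "beta": best["beta"],
                "se": best["se"],
                "p": best["p"],
                "direction": int(best["direction"]),
                "models": ",".join(sorted(set(block["model"]))),
                "n_merged": len(members),
            }
        )
    out = pd.DataFrame(rows).sort_values(["trait", "chrom", "start"]).reset_index(drop=True)
    return out


def annotate_region(
    region: tuple[str, int, int] | pd.Series,
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Features overlapping the region by >= 1 bp, with the overlap length.

    ``features`` carries chrom/start/end (1-based inclusive) plus any
    payload columns (gene name, feature class, ...). A chromosome mismatch
    simply yields an empty frame.
    """
    if isinstance(region, pd.Series):
        chrom, start, end = region["chrom"], int(region["start"]), int(region["end"])
    else:
        chrom, start, end = region[0], int(region[1]), int(region[2])
    sub = features[features["chrom"].astype(str) == str(chrom)]
    if sub.empty:
        return sub.assign(overlap_bp=pd.Series(dtype=int))
    ov = np.minimum(sub["end"].to_numpy(), end) - np.maximum(sub["start"].to_numpy(), start) + 1
    hit = ov >= 1
    out = sub[hit].copy()
    out["overlap_bp"] = ov[hit]
    return out.reset_index(drop=True)


def _union_length_and_hits(regions: pd.DataFrame, snp_positions: pd.DataFrame) -> tuple[int, int]:
    total = 0
    hits = 0
    for chrom, grp in regions.groupby("chrom"):
        iv = grp[["start", "end"]].sort_values("start").to_numpy()
        merged: list[list[int]] = []
        for s, e in iv:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], int(e))
            else:
                merged.append([int(s), int(e)])
        pos = snp_positions.loc[
            snp_positions["chrom"].astype(str) == str(chrom), "pos"
        ].to_numpy()
        for s, e in merged:
            total += e - s + 1
            if pos.size:
                hits += int(((pos >= s) & (pos <= e)).sum())
    return total, hits


def snp_density_binomial_test(
    regions: pd.DataFrame,
    snp_positions: pd.DataFrame,
    total_snp_signals: int,
    genome_length_bp: int = AUTOSOMAL_GENOME_BP,
) -> dict:
    """Exact two-sided binomial test of SNP-signal density inside regions.

    Successes are the SNP signals falling inside the (union of the) regions,
    trials the total region length in bp, and the hypothesized rate the
    genome-wide density total_snp_signals / genome_length_bp. Two-sided by
    the minimum-likelihood rule. Only autosomal regions are admissible.
    """
    bad = set(regions["chrom"].astype(str)) - set(AUTOSOMES)
    if bad:
        raise ValueError(f"non-autosomal regions not admissible: {sorted(bad)}")
    trials, successes = _union_length_and_hits(regions, snp_positions)
    if trials == 0:
        raise ValueError("zero total region length")
    rate = total_snp_signals / genome_length_bp
    res = stats.binomtest(successes, trials, rate, alternative="two-sided")
    observed_density = successes / trials
    return {
        "successes": successes,
        "trials": trials,
        "expected_rate": rate,
        "fold": observed_density / rate if rate > 0 else np.inf,
        "p": res.pvalue,
    }


# --- carrier-group tests -------------------------------------------------


def welch_t_test(
    group_a: np.ndarray, group_b: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Welch (unequal-variance) t test between two carrier groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("t test needs >= 1 observation per group")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


@dataclass
class FisherResult:
    odds_ratio: float
    p: float
    or_defined: bool


def _cmle_odds_ratio(table: np.ndarray, tol: float | None) -> float:
    """Conditional MLE of the odds ratio of a 2x2 table.

    Maximizes the noncentral hypergeometric likelihood of the top-left cell
    given all margins, i.e. solves E[X | psi] = x. The default tolerance
    reproduces R's ``fisher.test`` numerics exactly (Brent root search on
    the psi - or reciprocal - scale stopped at .Machine$double.eps^0.25);
    pass a small ``tol`` (e.g. 1e-12) for a fully converged estimate.
    """
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    m1, n1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, n1 - (n - m1)), min(m1, n1)
    if a == lo:
        return 0.0
    if a == hi:
        return np.inf
    x = np.arange(lo, hi + 1)
    logw = (
        gammaln(m1 + 1)
        - gammaln(x + 1)
        - gammaln(m1 - x + 1)
        + gammaln(n - m1 + 1)
        - gammaln(n1 - x + 1)
        - gammaln(n - m1 - n1 + x + 1)
    )

    def cond_mean(psi: float) -> float:
        ll = logw + x * np.log(psi)
        ll -= ll.max()
        w = np.exp(ll)
        return float((x * w).sum() / w.sum())

    if tol is None:
        tol = np.finfo(float).eps ** 0.25  # R uniroot default
    eps = np.finfo(float).eps
    mu = cond_mean(1.0)
    if mu > a:
        return brentq(lambda t: cond_mean(t) - a, eps, 1.0, xtol=tol)
    if mu < a:
        return 1.0 / brentq(lambda t: cond_mean(1.0 / t) - a, eps, 1.0, xtol=tol)
    return 1.0


def fisher_exact_cmle(
    table, alternative: str = "two-sided", tol: float | None = None
) -> FisherResult:
    """Fisher's exact test with the conditional-MLE odds ratio.

    The exact p-value follows the minimum-likelihood two-sided convention.
    A table with a zero margin has no defined odds ratio; the result is
    flagged rather than raising.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("Fisher test needs a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return FisherResult(odds_ratio=np.nan, p=1.0, or_defined=False)
    _, p = stats.fisher_exact(t, alternative=alternative)
    return FisherResult(odds_ratio=_cmle_odds_ratio(t, tol), p=float(p), or_defined=True)


def binomial_enrichment_test(
    n_events: int, n_total: int, background_rate: float, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Exact binomial test of carrier event counts against a background rate.

    Returns (fold enrichment over expectation, p)."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    res = stats.binomtest(n_events, n_total, background_rate, alternative=alternative)
    expected = n_total * background_rate
    fold = n_events / expected if expected > 0 else np.inf
    return fold, float(res.pvalue)
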