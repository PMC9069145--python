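"""Replication of discovery CNV signals in an independent cohort.

For each discovery region the most significantly associated replication
probe inside the discovery boundaries is selected under the discovery
region's winning model; the replication p-value is then adjusted for
directional concordance with the discovery effect (p/2 on sign agreement,
1 - p/2 otherwise), Bonferroni-corrected over the assessable signals, and
summarized by the enrichment of nominally significant replications over
chance. A simulation-based power calculation quantifies what fraction of
signals a cohort of given size and carrier frequency could be expected to
replicate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .regions import binomial_enrichment_test


def select_lead_in_region(
    scan_results: pd.DataFrame, region: pd.Series | dict
) -> pd.Series | None:
    """Most significant testable replication probe within the region.

    ``scan_results`` is a per-probe scan under the region's winning model.
    Ties in p are broken by smallest genomic position. Returns None when no
    testable probe falls inside the boundaries (record unassessable).
    """
    chrom, start, end = str(region["chrom"]), int(region["start"]), int(region["end"])
    sub = scan_results[
        (scan_results["chrom"].astype(str) == chrom)
        & (scan_results["pos"] >= start)
        & (scan_results["pos"] <= end)
        & (~scan_results["untestable"])
    ]
    if sub.empty:
        return None
    pmin = sub["p"].min()
    return sub[sub["p"] == pmin].sort_values("pos").iloc[0]


def adjust_directional_p(p_raw: float, concordant: bool) -> float:
    """One-sided replication correction: p/2 on direction agreement, else 1 - p/2."""
    if not 0.0 < p_raw <= 1.0:
        raise ValueError("p_raw must lie in (0, 1]")
    return p_raw / 2.0 if concordant else 1.0 - p_raw / 2.0


def replicate_regions(
    regions: pd.DataFrame,
    replication_scans: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Assemble the replication table for discovery regions.

    ``replication_scans`` maps model label -> per-probe scan results of the
    replication cohort for the matching trait. Direction agreement is
    judged on same-model T-scale betas; a zero replication beta counts as
    discordant (conservative).
    """
    rows = []
    for _, region in regions.iterrows():
        scan = replication_scans.get(region["model"])
        lead = None if scan is None else select_lead_in_region(scan, region)
        row = {
            "trait": region["trait"],
            "chrom": region["chrom"],
            "start": region["start"],
            "end": region["end"],
            "model": region["model"],
            "discovery_beta": region["beta"],
            "discovery_p": region["p"],
        }
        if lead is None:
            row.update(
                {"assessable": False, "rep_probe": None, "rep_beta": np.nan,
                 "rep_p_raw": np.nan, "rep_p_adj": np.nan, "concordant": False}
            )
        else:
            concordant = bool(np.sign(lead["beta"]) * np.sign(region["beta"]) > 0)
            row.update(
                {
                    "assessable": True,
                    "rep_probe": lead["probe_id"],
                    "rep_beta": lead["beta"],
                    "rep_p_raw": lead["p"],
                    "rep_p_adj": adjust_directional_p(float(lead["p"]), concordant),
                    "concordant": concordant,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def nominal_enrichment(
    n_nominal: int, n_tests: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Fold excess of nominally significant replications over chance.

    fold = n_nominal / (n_tests * alpha); p from the exact two-sided
    binomial test (minimum-likelihood rule).
    """
    if n_tests == 0:
        raise ValueError("n_tests must be > 0")
    if not 0 <= n_nominal <= n_tests:
        raise ValueError("n_nominal must lie in [0, n_tests]")
    return binomial_enrichment_test(n_nominal, n_tests, alpha)


def power_simulation(
    beta_discovery: float,
    carrier_freq: float,
    n: int,
    alpha: float,
    n_sims: int = 10_000,
    seed: int = 0,
) -> float:
    """Simulated power to replicate a signal of size ``beta_discovery`` (trait-SD
    units) at carrier frequency ``carrier_freq`` in a cohort of ``n``.

    Each simulation draws binary carrier genotypes at the carrier frequency,
    a trait beta * g + N(0,1), and the per-probe regression p-value; power is
    the fraction of non-missing p-values <= alpha. Simulations with zero
    carriers (or all carriers) have no testable contrast and yield missing
    p-values. The regression statistic is drawn from its exact sampling
    distribution given the carrier count (Binomial carrier count, Gaussian
    group contrast, scaled chi-square residual variance), which is
    distributionally identical to regressing raw per-individual draws.
    """
    if not 0.0 < carrier_freq < 1.0:
        raise ValueError("carrier_freq must lie in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    n1 = rng.binomial(n, carrier_freq, size=n_sims)
    valid = (n1 > 0) & (n1 < n)
    if not valid.any():
        raise ValueError("all simulations missing (no carriers drawn); power undefined")
    n1v = n1[valid]
    n0v = n - n1v
    contrast = rng.normal(beta_discovery, np.sqrt(1.0 / n0v + 1.0 / n1v))
    dof = n - 2
    s2 = rng.chisquare(dof, size=n1v.size) / dof
    tstat = contrast / np.sqrt(s2 * (1.0 / n0v + 1.0 / n1v))
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return float((p <= alpha).mean())


def expected_replications(powers) -> float:
    """Mean power across assessed signals times the number of signals."""
    arr = np.asarray(list(powers), dtype=float)
    if arr.size == 0:
        raise ValueError("no assessed signals")
    return float(arr.mean() * arr.size)
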