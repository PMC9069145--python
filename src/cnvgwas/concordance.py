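"""Microarray-vs-WGS CNV call concordance at the probe level.

Both call sets are reduced to probe x sample profiles taking -1 (deletion),
0 (copy neutral), or +1 (duplication); WGS calls are first merged across
small gaps (<= 20% of the merged span, mimicking the array caller's
tendency to emit one contiguous event) and both sets are size-filtered
(duplications < 1 kb, deletions < 2 kb, and anything > 10 Mb removed).
Per-probe Pearson correlation across samples then classifies each probe:
monomorphic, concordant (called by both, r >= 0.75), discordant
(called by both, lower r), apparent false positive (array-only; rescued
when a correlated neighboring probe within +/- 250 kb shows high
array-WGS concordance, indicating WGS call fragmentation), or false
negative (WGS-only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .probes import ProbeMap


def merge_adjacent_wgs(calls: pd.DataFrame, gap_fraction: float = 0.20) -> pd.DataFrame:
    """Merge same-type adjacent calls with gap <= ``gap_fraction`` x merged span.

    Greedy left-to-right within each sample/chromosome/type, iterated to a
    fixed point. The merged span includes the gap (end_next - start_first + 1).
    """
    out_rows = []
    cols = list(calls.columns)
    for (_, _, _), grp in calls.groupby(["sample_id", "chrom", "cn"], sort=False):
        rows = grp.sort_values("start").to_dict("records")
        changed = True
        while changed:
            changed = False
            merged: list[dict] = []
            for row in rows:
                if merged:
                    prev = merged[-1]
                    gap = row["start"] - prev["end"] - 1
                    span = max(row["end"], prev["end"]) - prev["start"] + 1
                    if gap <= gap_fraction * span:
                        prev["end"] = max(prev["end"], row["end"])
                        changed = True
                        continue
                merged.append(dict(row))
            rows = merged
        out_rows.extend(rows)
    out = pd.DataFrame(out_rows, columns=cols)
    return out.sort_values(["sample_id", "chrom", "start"]).reset_index(drop=True)


def size_filter(
    calls: pd.DataFrame,
    dup_min_bp: int = 1_000,
    del_min_bp: int = 2_000,
    max_bp: int = 10_000_000,
) -> pd.DataFrame:
    """Drop duplications < 1 kb, deletions < 2 kb, and any call > 10 Mb."""
    length = calls["end"] - calls["start"] + 1
    is_dup = calls["cn"] > 2
    keep = (length <= max_bp) & np.where(is_dup, length >= dup_min_bp, length >= del_min_bp)
    return calls[keep].reset_index(drop=True)


@dataclass
class ProbeProfile:
    """Probe x sample CNV-state matrix in {-1, 0, +1}."""

    probes: ProbeMap
    samples: list[str]
    values: np.ndarray = field(repr=False)  # int8 (P, S)

    def __post_init__(self) -> None:
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("profile values restricted to {-1, 0, +1}")

    def carriers_per_probe(self) -> np.ndarray:
        return (self.values != 0).sum(axis=1)


def build_profile(calls: pd.DataFrame, probes: ProbeMap, samples: list[str]) -> ProbeProfile:
    """Project calls onto the probe grid as -1/0/+1 states."""
    sample_idx = {s: j for j, s in enumerate(samples)}
    values = np.zeros((len(probes), len(samples)), dtype=np.int8)
    for call in calls.itertuples():
        j = sample_idx.get(call.sample_id)
        if j is None:
            continue
        rows = probes.rows_in_interval(str(call.chrom), int(call.start), int(call.end))
        if rows.size:
            values[rows, j] = 1 if call.cn > 2 else -1
    return ProbeProfile(probes=probes, samples=list(samples), values=values)


def profile_correlation(a: ProbeProfile, b: ProbeProfile) -> pd.DataFrame:
    """Per-probe Pearson r between the two profiles across samples.

    Probes constant in either profile have undefined correlation (NaN).
    Also reports the carrier count per probe for each method.
    """
    if a.samples != b.samples or len(a.probes) != len(b.probes):
        raise ValueError("profiles must share probe and sample axes")
    x = a.values.astype(np.float64)
    y = b.values.astype(np.float64)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc).sum(axis=1) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan
    return pd.DataFrame(
        {
            "probe_id": a.probes.probe_ids,
            "chrom": a.probes.chrom,
            "pos": a.probes.pos,
            "r": r,
            "n_carriers_a": a.carriers_per_probe(),
            "n_carriers_b": b.carriers_per_probe(),
        }
    )


def classify_probes(
    correlations: pd.DataFrame,
    array_profile: ProbeProfile,
    r_high: float = 0.75,
    rescue_r: float = 0.5,
    rescue_window_bp: int = 250_000,
) -> pd.DataFrame:
    """Assign each probe to a concordance class.

    - ``monomorphic``: no carriers by either method;
    - ``concordant``: carriers by both, r >= ``r_high``;
    - ``discordant``: carriers by both, r < ``r_high``;
    - ``false_positive``: array-only; flagged ``rescued`` when some probe
      within +/- ``rescue_window_bp`` whose array profile correlates at
      r >= ``rescue_r`` with this probe itself shows array-WGS r >= ``r_high``
      (the array call is likely real, the WGS call fragmented/shifted);
    - ``false_negative``: WGS-only.

    The classes partition the probe set.
    """
    df = correlations.copy()
    na, nb = df["n_carriers_a"].to_numpy(), df["n_carriers_b"].to_numpy()
    r = df["r"].to_numpy()
    classes = np.full(len(df), "monomorphic", dtype=object)
    both = (na > 0) & (nb > 0)
    classes[both & (r >= r_high)] = "concordant"
    classes[both & ~(r >= r_high)] = "discordant"
    classes[(na > 0) & (nb == 0)] = "false_positive"
    classes[(na == 0) & (nb > 0)] = "false_negative"

    rescued = np.zeros(len(df), dtype=bool)
    fp_rows = np.flatnonzero(classes == "false_positive")
    if fp_rows.size:
        high_rows = np.flatnonzero((classes == "concordant") | (both & (r >= r_high)))
        x = array_profile.values.astype(np.float64)
        xc = x - x.mean(axis=1, keepdims=True)
        norms = np.sqrt((xc**2).sum(axis=1))
        pos = df["pos"].to_numpy()
        chrom = df["chrom"].to_numpy()
        for i in fp_rows:
            near = high_rows[
                (chrom[high_rows] == chrom[i])
                & (np.abs(pos[high_rows] - pos[i]) <= rescue_window_bp)
            ]
            if near.size == 0 or norms[i] == 0:
                continue
            ok = near[norms[near] > 0]
            if ok.size == 0:
                continue
            rr = (xc[ok] @ xc[i]) / (norms[ok] * norms[i])
            if (rr >= rescue_r).any():
                rescued[i] = True
    df["class"] = classes
    df["rescued"] = rescued
    return df


def summarize_classes(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per concordance class, plus the rescued share of
    apparent false positives."""
    counts = classified["class"].value_counts()
    out = pd.DataFrame({"count": counts, "fraction": counts / len(classified)})
    fp = classified[classified["class"] == "false_positive"]
    out.attrs["fp_rescued_fraction"] = float(fp["rescued"].mean()) if len(fp) else np.nan
    return out
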