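"""Per-sample CNV burden and its phenotypic consequences.

The burden of an individual is the total genomic load of their
high-confidence autosomal CNVs, expressed either as affected megabases or
as the number of disrupted genes (a gene counts as disrupted only when a
CNV overlaps one of its qualifying feature classes: exon, splice site,
non-coding RNA, 3'UTR, 5'UTR - not merely the gene span). Burdens are
computed overall and separately for duplications and deletions, so
mb_cnv = mb_dup + mb_del holds exactly.

Burden-trait regressions are ordinary least squares on prepared traits (or
on non-normalized traits for natural-unit slopes). The modifier correction
removes the contribution of significantly trait-associated CNV regions:
carrier status of each such region enters a sample x region matrix G
(+1 duplication, -1 deletion), the trait is residualized on G, and the
burden is reduced by the load of region-overlapping CNVs before the
regression is rerun - a signal that survives indicates a polygenic CNV
architecture beyond the mapped regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import PreparedTrait, residualize
from .probes import AUTOSOMES

QUALIFYING_CLASSES = frozenset({"exon", "splice", "ncRNA", "UTR3", "UTR5"})
BURDEN_KINDS = ("cnv", "dup", "del")


def high_confidence(calls: pd.DataFrame, qs_threshold: float = 0.5) -> pd.DataFrame:
    """Calls with |QS| >= threshold (the analysis-grade subset)."""
    return calls[calls["qs"].abs() >= qs_threshold].reset_index(drop=True)


def _genes_hit(calls: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Per call row index -> set of disrupted gene names."""
    feats = genes[genes["feature_class"].isin(QUALIFYING_CLASSES)]
    by_chrom = {c: g for c, g in feats.groupby("chrom")}
    hits = {}
    for idx, call in calls.iterrows():
        sub = by_chrom.get(str(call["chrom"]))
        if sub is None:
            hits[idx] = set()
            continue
        ov = (sub["start"].to_numpy() <= call["end"]) & (sub["end"].to_numpy() >= call["start"])
        hits[idx] = set(sub["gene"].to_numpy()[ov])
    return pd.Series(hits)


def compute_burden(
    calls: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    samples: list[str] | None = None,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Per-sample Mb and disrupted-gene burden, split by CNV type.

    ``calls`` should already be high-confidence filtered. Samples with no
    calls (supply ``samples`` to include them) get all-zero rows.
    """
    df = calls.copy()
    if autosomes_only:
        df = df[df["chrom"].astype(str).isin(AUTOSOMES)]
    if samples is None:
        samples = sorted(df["sample_id"].unique())
    out = pd.DataFrame(
        0.0,
        index=pd.Index(samples, name="sample_id"),
        columns=["mb_cnv", "mb_dup", "mb_del", "genes_cnv", "genes_dup", "genes_del"],
    )
    if df.empty:
        out[["genes_cnv", "genes_dup", "genes_del"]] = 0
        return out
    df = df.reset_index(drop=True)
    df["mb"] = (df["end"] - df["start"] + 1) / 1e6
    is_dup = df["cn"] > 2
    mb_dup = df[is_dup].groupby("sample_id")["mb"].sum()
    mb_del = df[~is_dup].groupby("sample_id")["mb"].sum()
    out["mb_dup"] = mb_dup.reindex(samples, fill_value=0.0)
    out["mb_del"] = mb_del.reindex(samples, fill_value=0.0)
    out["mb_cnv"] = out["mb_dup"] + out["mb_del"]

    if genes is not None:
        hit = _genes_hit(df, genes)
        gd: dict[str, set] = {}
        gl: dict[str, set] = {}
        for idx, row in df.iterrows():
            target = gd if row["cn"] > 2 else gl
            target.setdefault(row["sample_id"], set()).update(hit[idx])
        out["genes_dup"] = [len(gd.get(s, ())) for s in samples]
        out["genes_del"] = [len(gl.get(s, ())) for s in samples]
        both = {s: gd.get(s, set()) | gl.get(s, set()) for s in samples}
        out["genes_cnv"] = [len(both[s]) for s in samples]
    out[["genes_cnv", "genes_dup", "genes_del"]] = out[
        ["genes_cnv", "genes_dup", "genes_del"]
    ].astype(int)
    return out


def burden_regression(
    trait: PreparedTrait | pd.Series, burden: pd.Series
) -> dict[str, float]:
    """OLS slope of the trait on the burden metric (aligned on sample id)."""
    values = trait.values if isinstance(trait, PreparedTrait) else trait
    common = values.index.intersection(burden.index)
    y = values.loc[common].to_numpy(dtype=float)
    x = burden.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if np.ptp(x) == 0:
        raise ValueError("constant burden vector")
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = (xc**2).sum()
    beta = (xc * yc).sum() / sxx
    sse = ((yc - beta * xc) ** 2).sum()
    se = np.sqrt(sse / (n - 2) / sxx)
    t = beta / se
    return {"beta": float(beta), "se": float(se), "p": float(2 * stats.t.sf(abs(t), n - 2)), "n": n}


def modifier_matrix(
    cnvrs: pd.DataFrame,
    calls: pd.DataFrame,
    samples: list[str],
    kind: str = "cnv",
) -> pd.DataFrame:
    """Sample x CNVR carrier matrix G in {-1, 0, +1}.

    An entry is +1/-1 when the sample carries a duplication/deletion
    overlapping the region by >= 1 bp. For the duplication burden
    (kind='dup') deletions are zeroed in G, and vice versa; a sample with
    both types overlapping one region keeps the type with the larger total
    overlap. A CNV overlapping several regions contributes to each column.
    """
    if kind not in BURDEN_KINDS:
        raise ValueError(f"kind must be one of {BURDEN_KINDS}")
    G = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"), columns=range(len(cnvrs)))
    for col, (_, region) in enumerate(cnvrs.iterrows()):
        sub = calls[
            (calls["chrom"].astype(str) == str(region["chrom"]))
            & (calls["start"] <= region["end"])
            & (calls["end"] >= region["start"])
        ]
        if sub.empty:
            continue
        ov = np.minimum(sub["end"], region["end"]) - np.maximum(sub["start"], region["start"]) + 1
        signed = np.where(sub["cn"] > 2, 1, -1)
        per_sample: dict[str, dict[int, int]] = {}
        for sid, s, o in zip(sub["sample_id"], signed, ov):
            per_sample.setdefault(sid, {}).setdefault(int(s), 0)
            per_sample[sid][int(s)] += int(o)
        for sid, d in per_sample.items():
            if sid not in G.index:
                continue
            sign = max(d, key=lambda s: (d[s], s))
            if kind == "dup" and sign < 0:
                sign = 0
            elif kind == "del" and sign > 0:
                sign = 0
            G.loc[sid, col] = sign
    return G


def modifier_correction(
    trait: PreparedTrait | pd.Series,
    burden: pd.Series,
    cnvrs: pd.DataFrame,
    calls: pd.DataFrame,
    kind: str = "cnv",
    genes: pd.DataFrame | None = None,
    metric: str = "mb",
) -> tuple[pd.Series, pd.Series]:
    """Remove trait-associated CNVR carrier effects from trait and burden.

    The trait is residualized on the G columns; the burden is reduced by the
    Mb (or disrupted-gene count) of CNVR-overlapping calls of the relevant
    type and clipped at 0. With no CNVRs the operation is the identity.
    """
    values = trait.values if isinstance(trait, PreparedTrait) else trait
    if len(cnvrs) == 0:
        return values.copy(), burden.copy()
    samples = list(values.index)
    G = modifier_matrix(cnvrs, calls, samples, kind=kind)
    nonzero = G.columns[(G != 0).any(axis=0)]
    if len(nonzero):
        prepared = residualize(values, G[nonzero].to_numpy(dtype=float))
        corrected_trait = pd.Series(prepared.values.to_numpy(), index=values.index)
    else:
        corrected_trait = values.copy()

    if kind == "dup":
        relevant = calls[calls["cn"] > 2]
    elif kind == "del":
        relevant = calls[calls["cn"] < 2]
    else:
        relevant = calls
    overlapping_idx: set[int] = set()
    for _, region in cnvrs.iterrows():
        sel = (
            (relevant["chrom"].astype(str) == str(region["chrom"]))
            & (relevant["start"] <= region["end"])
            & (relevant["end"] >= region["start"])
        )
        overlapping_idx.update(relevant.index[sel])
    overlapping = relevant.loc[sorted(overlapping_idx)]
    if metric == "mb":
        load = (overlapping["end"] - overlapping["start"] + 1) / 1e6
        removed = load.groupby(overlapping["sample_id"]).sum()
    elif metric == "genes":
        if genes is None:
            raise ValueError("gene table required for the gene-burden correction")
        hit = _genes_hit(overlapping.reset_index(drop=True), genes)
        per: dict[str, set] = {}
        for i, sid in enumerate(overlapping["sample_id"].to_numpy()):
            per.setdefault(sid, set()).update(hit[i])
        removed = pd.Series({s: len(g) for s, g in per.items()}, dtype=float)
    else:
        raise ValueError("metric must be 'mb' or 'genes'")
    corrected_burden = (burden - removed.reindex(burden.index, fill_value=0.0)).clip(lower=0.0)
    return corrected_trait, corrected_burden


def sex_difference_test(burden: pd.Series, sex: pd.Series) -> float:
    """Two-sided unpaired Wilcoxon rank-sum p for a burden difference by sex.

    Exact when both groups are small without ties, otherwise the normal
    approximation with tie and continuity corrections.
    """
    common = burden.index.intersection(sex.index)
    b = burden.loc[common]
    s = sex.loc[common]
    groups = [b[s == lvl].to_numpy(dtype=float) for lvl in pd.unique(s)]
    if len(groups) != 2 or any(g.size == 0 for g in groups):
        raise ValueError("need exactly two nonempty sex groups")
    x, y = groups
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) < 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def meta_fixed_effects(
    beta1: float, se1: float, beta2: float, se2: float
) -> tuple[float, float, float]:
    """Inverse-variance fixed-effects meta-analysis of two estimates."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    w1, w2 = 1.0 / se1**2, 1.0 / se2**2
    beta = (w1 * beta1 + w2 * beta2) / (w1 + w2)
    se = 1.0 / np.sqrt(w1 + w2)
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return float(beta), float(se), p


def _shared_fraction(
    own: pd.DataFrame, partner: pd.DataFrame, min_overlap_bp: int
) -> float | None:
    """Fraction of ``own`` calls matched by a same-type, same-chromosome
    partner call overlapping >= min_overlap_bp; None when own is empty."""
    if own.empty:
        return None
    shared = 0
    for call in own.itertuples():
        cand = partner[
            (partner["chrom"].astype(str) == str(call.chrom))
            & ((partner["cn"] > 2) == (call.cn > 2))
        ]
        if cand.empty:
            continue
        ov = np.minimum(cand["end"].to_numpy(), call.end) - np.maximum(
            cand["start"].to_numpy(), call.start
        ) + 1
        if (ov >= min_overlap_bp).any():
            shared += 1
    return shared / len(own)


def sibling_sharing(
    pairs: pd.DataFrame,
    index_calls: pd.DataFrame,
    sibling_calls: pd.DataFrame,
    min_overlap_bp: int = 25_000,
    qs_threshold: float = 0.5,
    seed: int = 0,
) -> dict[str, float]:
    """Mean fraction of an index sample's high-confidence CNVs shared with
    their sibling, with a random re-pairing control.

    A CNV is shared when the partner carries a same-type call on the same
    chromosome overlapping it by >= ``min_overlap_bp``. Index samples with
    no high-confidence CNVs are skipped. The control re-pairs each index
    sample with another index sample's call set (seeded permutation without
    replacement, no self-pairs).
    """
    idx_calls = high_confidence(index_calls, qs_threshold)
    sib_calls = high_confidence(sibling_calls, qs_threshold)
    by_index = {s: g for s, g in idx_calls.groupby("sample_id")}
    by_sib = {s: g for s, g in sib_calls.groupby("sample_id")}
    empty = idx_calls.iloc[0:0]

    fractions = []
    for row in pairs.itertuples():
        own = by_index.get(row.index_id, empty)
        frac = _shared_fraction(own, by_sib.get(row.sibling_id, empty), min_overlap_bp)
        if frac is not None:
            fractions.append(frac)

    rng = np.random.default_rng(seed)
    ids = pairs["index_id"].to_numpy()
    perm = rng.permutation(len(ids))
    fixed = np.flatnonzero(perm == np.arange(len(ids)))
    for i in fixed:  # break self-pairs
        j = (i + 1) % len(ids)
        perm[i], perm[j] = perm[j], perm[i]
    control = []
    for i, row in enumerate(pairs.itertuples()):
        own = by_index.get(row.index_id, empty)
        frac = _shared_fraction(own, by_index.get(ids[perm[i]], empty), min_overlap_bp)
        if frac is not None:
            control.append(frac)

    return {
        "mean_shared_fraction": float(np.mean(fractions)) if fractions else np.nan,
        "control_mean_fraction": float(np.mean(control)) if control else np.nan,
        "n_pairs_used": len(fractions),
    }
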