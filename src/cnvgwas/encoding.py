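"""Probe-level encoding of quality-scored CNV calls.

CNV calls (one row per sample x contiguous event, with a quality score
QS in [-1, 1] whose sign encodes the type and magnitude the confidence)
are projected onto the probe grid to form a probe x sample QS matrix:
a cell is nonzero only where a call interval contains the probe position,
and copy-neutral cells are 0. High-confidence calls (|QS| >= 0.5) are then
encoded into three T-allele dosage models:

==================  ========  ========  ========
QS class            mirror    dup-only  del-only
==================  ========  ========  ========
deletion  (QS<-.5)  0  (AA)   missing   2  (TT)
neutral             1  (AT)   1  (AT)   1  (AT)
duplication (>.5)   2  (TT)   2  (TT)   missing
==================  ========  ========  ========

so the mirror model counts copies (dosage = CN - 1), while each
type-specific model blanks out carriers of the other type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .probes import ProbeMap

MISSING = np.int8(-1)
MODELS = ("mirror", "dup-only", "del-only")

# sample-/plate-level QC bounds
MAX_CALLS_PER_SAMPLE = 200
MAX_SINGLE_CALL_BP = 10_000_000
MAX_PLATE_MEAN_CALLS = 100


def qc_samples(
    calls: pd.DataFrame, plate_map: Mapping[str, str] | pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop calls from samples failing cohort-level QC.

    Exclusion rules: sample carries > 200 calls; sample carries a single
    call > 10 Mb; sample sits on a plate whose mean call count per sample
    exceeds 100. Returns (filtered calls, exclusion report with one row per
    excluded sample and the rule hit).
    """
    plate = pd.Series(plate_map)
    missing = set(calls["sample_id"]) - set(plate.index)
    if missing:
        raise ValueError(f"samples without plate assignment: {sorted(missing)[:5]}")

    per_sample = calls.groupby("sample_id").size()
    lengths = calls["end"] - calls["start"] + 1
    reasons: dict[str, list[str]] = {}

    for sid in per_sample.index[per_sample > MAX_CALLS_PER_SAMPLE]:
        reasons.setdefault(sid, []).append(f">{MAX_CALLS_PER_SAMPLE} CNV calls")
    giant = calls.loc[lengths > MAX_SINGLE_CALL_BP, "sample_id"].unique()
    for sid in giant:
        reasons.setdefault(sid, []).append(f"single CNV > {MAX_SINGLE_CALL_BP // 10**6} Mb")

    plate_counts = per_sample.groupby(plate.reindex(per_sample.index)).sum()
    plate_sizes = plate.value_counts()
    plate_mean = (plate_counts / plate_sizes.reindex(plate_counts.index)).fillna(0.0)
    bad_plates = set(plate_mean.index[plate_mean > MAX_PLATE_MEAN_CALLS])
    for sid, pl in plate.items():
        if pl in bad_plates:
            reasons.setdefault(sid, []).append(f"plate mean CNV count > {MAX_PLATE_MEAN_CALLS}")

    report = pd.DataFrame(
        [(sid, "; ".join(rules)) for sid, rules in sorted(reasons.items())],
        columns=["sample_id", "rule"],
    )
    kept = calls[~calls["sample_id"].isin(reasons)].reset_index(drop=True)
    return kept, report


@dataclass
class QSMatrix:
    """Probe x sample quality-score matrix (0 = copy neutral)."""

    probes: ProbeMap
    samples: list[str]
    values: np.ndarray = field(repr=False)  # float32 (P, S)

    def __post_init__(self) -> None:
        expected = (len(self.probes), len(self.samples))
        if self.values.shape != expected:
            raise ValueError(f"QS matrix shape {self.values.shape} != {expected}")


def build_qs_matrix(
    calls: pd.DataFrame,
    probes: ProbeMap,
    samples: list[str] | None = None,
    qs_threshold: float = 0.5,
) -> QSMatrix:
    """Project calls with |QS| >= ``qs_threshold`` onto the probe grid.

    Samples absent from ``calls`` (or whose calls all fall below the cut)
    become all-zero columns. When several retained calls hit one
    probe x sample cell (e.g., nested events) the call with the larger |QS|
    wins, keeping the matrix single-valued.
    """
    if samples is None:
        samples = sorted(calls["sample_id"].unique())
    sample_idx = {s: j for j, s in enumerate(samples)}
    known_chroms = set(probes.df["chrom"])
    bad = set(calls["chrom"].astype(str)) - known_chroms
    if bad:
        raise ValueError(f"calls on chromosomes absent from the probe map: {sorted(bad)}")
    if (calls["qs"].abs() > 1).any():
        raise ValueError("|QS| must be <= 1")

    values = np.zeros((len(probes), len(samples)), dtype=np.float32)
    kept = calls[calls["qs"].abs() >= qs_threshold]
    # larger |QS| applied last wins the cell
    kept = kept.iloc[np.argsort(kept["qs"].abs().to_numpy(), kind="stable")]
    for call in kept.itertuples():
        j = sample_idx.get(call.sample_id)
        if j is None:
            continue
        rows = probes.rows_in_interval(str(call.chrom), int(call.start), int(call.end))
        if rows.size:
            values[rows, j] = call.qs
    return QSMatrix(probes=probes, samples=list(samples), values=values)


@dataclass
class ModelGenotypes:
    """Per-model T-allele dosage matrix: 0/1/2 with -1 for missing."""

    model: str
    probes: ProbeMap
    samples: list[str]
    dosage: np.ndarray = field(repr=False)  # int8 (P, S)
    a1: np.ndarray | None = None  # per-probe A1 allele label ("T"/"A"), set by PLINK I/O

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.dosage.dtype != np.int8:
            self.dosage = self.dosage.astype(np.int8)
        if self.a1 is None:
            self.a1 = np.full(len(self.probes), "T", dtype="<U1")

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def subset_probes(self, rows: np.ndarray) -> "ModelGenotypes":
        return ModelGenotypes(
            model=self.model,
            probes=self.probes.subset(rows),
            samples=self.samples,
            dosage=self.dosage[rows].copy(),
            a1=self.a1[rows].copy(),
        )


def encode_model(
    qs: QSMatrix,
    model: str,
    strict_boundary: bool = False,
    array_missing: np.ndarray | None = None,
) -> ModelGenotypes:
    """Encode a QS matrix into one of the three dosage models.

    By default a call at exactly |QS| = 0.5 counts as high confidence and is
    classed by sign; ``strict_boundary=True`` switches to the strict
    inequalities (|QS| = 0.5 treated as copy neutral). ``array_missing`` is an
    optional boolean (P, S) mask of cells typed on an array lacking the probe;
    those become missing in every model before encoding.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    v = qs.values
    if strict_boundary:
        dele, dup = v < -0.5, v > 0.5
    else:
        dele, dup = v <= -0.5, v >= 0.5
    dosage = np.ones(v.shape, dtype=np.int8)
    if model == "mirror":
        dosage[dele] = 0
        dosage[dup] = 2
    elif model == "dup-only":
        dosage[dele] = MISSING
        dosage[dup] = 2
    else:  # del-only
        dosage[dele] = 2
        dosage[dup] = MISSING
    if array_missing is not None:
        dosage[array_missing] = MISSING
    return ModelGenotypes(model=model, probes=qs.probes, samples=qs.samples, dosage=dosage)


def array_missing_mask(probes: ProbeMap, sample_arrays: pd.Series, samples: list[str]) -> np.ndarray:
    """(P, S) mask of cells where the sample's array lacks the probe.

    ``sample_arrays`` maps sample id -> 'a' or 'b'; the probe map must carry
    ``on_array_a``/``on_array_b`` flags.
    """
    arr = sample_arrays.reindex(samples).to_numpy()
    on_a = probes.df["on_array_a"].to_numpy()[:, None]
    on_b = probes.df["on_array_b"].to_numpy()[:, None]
    return np.where(arr[None, :] == "b", ~on_b, ~on_a)


def compute_frequencies(geno: ModelGenotypes) -> pd.DataFrame:
    """Per-probe carrier counts and frequencies from the mirror encoding.

    cnv_freq = 100 * N_cnv / (N_cnv + N_nonCNV), and likewise for the
    duplication and deletion frequencies, with N_cnv = N_dup + N_del; the
    denominator counts non-missing cells only. Probes with no non-missing
    samples raise, since no frequency is defined for them.
    """
    if geno.model != "mirror":
        raise ValueError("frequencies are computed from the mirror encoding")
    d = geno.dosage
    n_del = (d == 0).sum(axis=1)
    n_dup = (d == 2).sum(axis=1)
    n_neutral = (d == 1).sum(axis=1)
    n_missing = (d == MISSING).sum(axis=1)
    denom = n_del + n_dup + n_neutral
    if (denom == 0).any():
        bad = geno.probes.probe_ids[denom == 0][:5].tolist()
        raise ValueError(f"probes with zero non-missing samples: {bad}")
    out = pd.DataFrame(
        {
            "probe_id": geno.probes.probe_ids,
            "chrom": geno.probes.chrom,
            "pos": geno.probes.pos,
            "n_del": n_del,
            "n_dup": n_dup,
            "n_neutral": n_neutral,
            "n_missing": n_missing,
            "missing_frac": n_missing / d.shape[1],
        }
    )
    out["del_freq"] = 100.0 * n_del / denom
    out["dup_freq"] = 100.0 * n_dup / denom
    out["cnv_freq"] = out["del_freq"] + out["dup_freq"]
    return out


_MODEL_FREQ_COLUMN = {"mirror": "cnv_freq", "dup-only": "dup_freq", "del-only": "del_freq"}


def filter_probes(
    freq: pd.DataFrame,
    model: str,
    min_freq_pct: float = 0.005,
    max_missing: float = 0.05,
) -> np.ndarray:
    """Row indices of probes passing the model-relevant frequency bound
    (>= ``min_freq_pct`` percent) and the missingness bound (<= ``max_missing``)."""
    if model not in _MODEL_FREQ_COLUMN:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    col = _MODEL_FREQ_COLUMN[model]
    keep = (freq[col].to_numpy() >= min_freq_pct) & (freq["missing_frac"].to_numpy() <= max_missing)
    return np.flatnonzero(keep)
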