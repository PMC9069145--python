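"""Synthetic cohort generator emulating a biobank CNV architecture.

The generator produces everything the downstream pipeline consumes, with the
statistical structure the analysis assumes: recurrent CNV regions at
specified duplication/deletion carrier frequencies (rare, 0.005%-4%),
uniform breakpoint jitter around core boundaries, per-call quality scores
(QS in [-1, 1], sign = CNV type, |QS| >= 0.5 = high confidence), spurious
low-|QS| calls, covariates (sex, age, age^2, genotyping batch, PCs),
round-robin plate assignment, sibling pairs with a configurable CNV
transmission rate, and fragmented WGS-style call sets for the concordance
analysis.

Phenotypes are built from four per-region effect models:

- ``mirror``:    beta * (CN - 2)        (each extra copy shifts the trait)
- ``dup-only``:  beta * 1{duplication}
- ``del-only``:  beta * 1{deletion}
- ``u-shape``:   beta * 1{dup or del}   (both types shift the same way)

plus optional per-Mb burden effects, small covariate effects, and Gaussian
noise. Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .probes import ProbeMap

CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "cn", "n_probes", "qs"]
EFFECT_MODELS = ("mirror", "dup-only", "del-only", "u-shape")

# Fixed small covariate coefficients (trait-SD units on standardized
# covariates); they exercise residualization without claiming realism.
DEFAULT_COVARIATE_BETAS = {"sex": 0.10, "age": 0.05, "age2": 0.02, "pc": 0.05, "batch_sd": 0.03}


@dataclass(frozen=True)
class EffectSpec:
    trait: str
    model: str
    beta: float

    def __post_init__(self) -> None:
        if self.model not in EFFECT_MODELS:
            raise ValueError(f"unknown effect model {self.model!r}; expected one of {EFFECT_MODELS}")


@dataclass(frozen=True)
class RegionSpec:
    """One recurrent CNV region: core interval, carrier frequencies, effects."""

    chrom: str
    core_start: int
    core_end: int
    dup_frequency: float = 0.0
    del_frequency: float = 0.0
    breakpoint_jitter_bp: int = 0
    effects: tuple[EffectSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.core_end <= self.core_start:
            raise ValueError("core_end must exceed core_start")
        for f in (self.dup_frequency, self.del_frequency):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"carrier frequency {f} outside [0, 1]")
        if self.dup_frequency + self.del_frequency >= 1.0:
            raise ValueError("dup_frequency + del_frequency must be < 1")
        if self.breakpoint_jitter_bp < 0:
            raise ValueError("breakpoint jitter must be >= 0")


@dataclass(frozen=True)
class CNVArchitecture:
    regions: tuple[RegionSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))

    @property
    def traits(self) -> tuple[str, ...]:
        names: list[str] = []
        for region in self.regions:
            for eff in region.effects:
                if eff.trait not in names:
                    names.append(eff.trait)
        return tuple(names)


@dataclass(frozen=True)
class QSNoise:
    """miss_rate: P(true call scored below the 0.5 confidence cut);
    fp_rate: expected spurious low-|QS| calls per sample (Poisson)."""

    miss_rate: float = 0.0
    fp_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate outside [0, 1]")
        if self.fp_rate < 0.0:
            raise ValueError("fp_rate must be >= 0")


@dataclass
class SimulatedCohort:
    calls: pd.DataFrame
    samples: list[str]
    covariates: pd.DataFrame
    plates: pd.Series
    true_cn: np.ndarray  # (n_regions, n_samples) in {1, 2, 3}
    architecture: CNVArchitecture
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def true_mb_burden(self) -> pd.Series:
        """Mb affected by true (region-derived) CNVs per sample, zero-call samples included."""
        true = self.calls[self.calls["region_idx"] >= 0]
        mb = (true["end"] - true["start"] + 1) / 1e6
        out = mb.groupby(true["sample_id"]).sum()
        return out.reindex(self.samples, fill_value=0.0)


def generate_probe_map(
    n_probes: int,
    chromosome_lengths: Mapping[str, int],
    seed: int,
    array_b_missing_frac: float = 0.0,
) -> ProbeMap:
    """Place ``n_probes`` unique probes across chromosomes, proportional to length.

    Positions are drawn uniformly without replacement per chromosome (1-based)
    and sorted. A fraction of probes can be flagged as absent from a second
    array to exercise array-specific missingness downstream.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    lengths = {str(c): int(l) for c, l in chromosome_lengths.items()}
    if any(l <= 0 for l in lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    total = sum(lengths.values())
    chroms = list(lengths)
    # largest-remainder apportionment of probes to chromosomes
    quotas = {c: n_probes * lengths[c] / total for c in chroms}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    leftover = n_probes - sum(counts.values())
    for c in sorted(chroms, key=lambda c: quotas[c] - counts[c], reverse=True)[:leftover]:
        counts[c] += 1
    rows = []
    for c in chroms:
        k, length = counts[c], lengths[c]
        if k > length:
            raise ValueError(f"cannot place {k} distinct probes on a {length} bp chromosome")
        if k == 0:
            continue
        if length <= 4 * k:
            pos = rng.choice(length, size=k, replace=False) + 1
        else:  # rejection sampling avoids materializing the position range
            seen: set[int] = set()
            while len(seen) < k:
                seen.update((rng.integers(1, length + 1, size=k - len(seen))).tolist())
            pos = np.fromiter(seen, dtype=np.int64)
        for p in np.sort(pos):
            rows.append((c, int(p)))
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    df["probe_id"] = [f"probe_{c}_{p}" for c, p in zip(df["chrom"], df["pos"])]
    df["on_array_a"] = True
    df["on_array_b"] = rng.random(len(df)) >= array_b_missing_frac
    return ProbeMap(df[["probe_id", "chrom", "pos", "on_array_a", "on_array_b"]])


def _jitter_interval(
    rng: np.random.Generator, spec: RegionSpec, chrom_length: int | None
) -> tuple[int, int]:
    j = spec.breakpoint_jitter_bp
    start = spec.core_start + (int(rng.integers(-j, j + 1)) if j else 0)
    end = spec.core_end + (int(rng.integers(-j, j + 1)) if j else 0)
    start = max(1, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if end <= start:  # degenerate jitter draw; fall back to the core
        start, end = spec.core_start, spec.core_end
    return start, end


def _count_probes(probe_map: ProbeMap | None, chrom: str, start: int, end: int) -> int:
    if probe_map is None:
        return 0
    return int(probe_map.rows_in_interval(chrom, start, end).size)


def simulate_cohort(
    architecture: CNVArchitecture,
    n_samples: int,
    qs_noise: QSNoise | None = None,
    seed: int = 0,
    probe_map: ProbeMap | None = None,
    chromosome_lengths: Mapping[str, int] | None = None,
    plate_size: int = 96,
    n_batches: int = 10,
    n_pcs: int = 4,
    sample_prefix: str = "S",
) -> SimulatedCohort:
    """Draw a cohort from the declared CNV architecture.

    Per sample and region, carrier status is an independent categorical draw
    (dup with p=dup_frequency, del with p=del_frequency). True calls receive
    |QS| ~ U(0.5, 1) with probability 1 - miss_rate, otherwise |QS| ~ U(0, 0.5);
    spurious calls (Poisson(fp_rate) per sample) receive |QS| ~ U(0, 0.5).
    QS sign always matches call type (negative = deletion).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    noise = qs_noise or QSNoise()
    rng = np.random.default_rng(seed)
    samples = [f"{sample_prefix}{i:06d}" for i in range(1, n_samples + 1)]
    lengths = {str(c): int(l) for c, l in (chromosome_lengths or {}).items()}

    regions = architecture.regions
    true_cn = np.full((len(regions), n_samples), 2, dtype=np.int8)
    records: list[tuple] = []
    for ridx, spec in enumerate(regions):
        u = rng.random(n_samples)
        dup = u < spec.dup_frequency
        dele = (~dup) & (u < spec.dup_frequency + spec.del_frequency)
        true_cn[ridx, dup] = 3
        true_cn[ridx, dele] = 1
        clen = lengths.get(spec.chrom)
        for sidx in np.flatnonzero(dup | dele):
            start, end = _jitter_interval(rng, spec, clen)
            is_dup = bool(dup[sidx])
            hi_conf = rng.random() >= noise.miss_rate
            mag = rng.uniform(0.5, 1.0) if hi_conf else rng.uniform(0.0, 0.5)
            qs = mag if is_dup else -mag
            records.append(
                (
                    samples[sidx],
                    spec.chrom,
                    start,
                    end,
                    3 if is_dup else 1,
                    _count_probes(probe_map, spec.chrom, start, end),
                    round(qs, 6),
                    ridx,
                )
            )

    if noise.fp_rate > 0:
        fp_chroms = (
            probe_map.df["chrom"].unique().tolist()
            if probe_map is not None
            else (list(lengths) or [r.chrom for r in regions])
        )
        n_fp = rng.poisson(noise.fp_rate, size=n_samples)
        for sidx in np.flatnonzero(n_fp):
            for _ in range(int(n_fp[sidx])):
                chrom = fp_chroms[int(rng.integers(len(fp_chroms)))]
                clen = lengths.get(chrom, 10_000_000)
                length = int(rng.integers(5_000, 100_000))
                start = int(rng.integers(1, max(2, clen - length)))
                end = start + length - 1
                is_dup = bool(rng.random() < 0.5)
                mag = rng.uniform(0.0, 0.5)
                records.append(
                    (
                        samples[sidx],
                        chrom,
                        start,
                        end,
                        3 if is_dup else 1,
                        _count_probes(probe_map, chrom, start, end),
                        round(mag if is_dup else -mag, 6),
                        -1,
                    )
                )

    calls = pd.DataFrame(records, columns=CALL_COLUMNS + ["region_idx"])

    plates = pd.Series(
        [f"plate_{i // plate_size:04d}" for i in range(n_samples)], index=samples, name="plate"
    )
    age = rng.uniform(40, 70, size=n_samples)
    covariates = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n_samples),
            "age": age,
            "age2": age**2,
            "batch": rng.integers(0, n_batches, size=n_samples),
        },
        index=samples,
    )
    for k in range(1, n_pcs + 1):
        covariates[f"pc{k}"] = rng.standard_normal(n_samples)

    return SimulatedCohort(
        calls=calls,
        samples=samples,
        covariates=covariates,
        plates=plates,
        true_cn=true_cn,
        architecture=architecture,
        seed=seed,
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def simulate_phenotypes(
    cohort: SimulatedCohort,
    burden_beta: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    extra_null_traits: Sequence[str] = (),
    covariate_betas: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Build trait values from the architecture's effect specs.

    trait = sum of region effects (per the four models) + covariate effects
    + burden_beta * true Mb burden + N(0, noise_sd^2).
    """
    rng = np.random.default_rng(seed)
    cb = dict(DEFAULT_COVARIATE_BETAS, **(covariate_betas or {}))
    cov = cohort.covariates
    base = (
        cb["sex"] * cov["sex"].to_numpy().astype(float)
        + cb["age"] * _zscore(cov["age"].to_numpy())
        + cb["age2"] * _zscore(cov["age2"].to_numpy())
    )
    for col in cov.columns:
        if col.startswith("pc"):
            base = base + cb["pc"] * cov[col].to_numpy()
    batch_offsets = rng.normal(0.0, cb["batch_sd"], size=int(cov["batch"].max()) + 1)
    base = base + batch_offsets[cov["batch"].to_numpy()]
    if burden_beta != 0.0:
        base = base + burden_beta * cohort.true_mb_burden().to_numpy()

    traits = list(cohort.architecture.traits)
    traits += [t for t in extra_null_traits if t and t not in traits]
    out = {}
    for trait in traits:
        y = base.copy()
        for ridx, spec in enumerate(cohort.architecture.regions):
            cn = cohort.true_cn[ridx].astype(float)
            for eff in spec.effects:
                if eff.trait != trait:
                    continue
                if eff.model == "mirror":
                    y = y + eff.beta * (cn - 2.0)
                elif eff.model == "dup-only":
                    y = y + eff.beta * (cn == 3)
                elif eff.model == "del-only":
                    y = y + eff.beta * (cn == 1)
                elif eff.model == "u-shape":
                    y = y + eff.beta * (cn != 2)
                else:  # pragma: no cover - EffectSpec validates at construction
                    raise ValueError(f"unknown effect model {eff.model!r}")
        out[trait] = y + rng.normal(0.0, noise_sd, size=cohort.n_samples)
    return pd.DataFrame(out, index=cohort.samples)


def simulate_siblings(
    cohort: SimulatedCohort,
    n_pairs: int,
    transmission_rate: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach one sibling to each of ``n_pairs`` index samples.

    Every true call of the index is copied to the sibling with probability
    ``transmission_rate`` (type and coordinates preserved, so overlap with
    the original is total). On top of transmitted calls the sibling carries
    its own independent draw from the architecture, giving random-pair
    sharing its architecture-driven baseline.
    """
    if not 0.0 <= transmission_rate <= 1.0:
        raise ValueError("transmission_rate outside [0, 1]")
    if n_pairs > cohort.n_samples:
        raise ValueError("n_pairs exceeds cohort size")
    rng = np.random.default_rng(seed)
    index_ids = list(rng.choice(cohort.samples, size=n_pairs, replace=False))
    sib_of = {idx: f"SIB{j:06d}" for j, idx in enumerate(index_ids, start=1)}

    # independent background draw for the siblings
    background = simulate_cohort(
        cohort.architecture,
        n_pairs,
        qs_noise=QSNoise(),
        seed=int(rng.integers(2**31)),
        sample_prefix="SIBTMP",
    )
    remap = dict(zip(background.samples, [sib_of[i] for i in index_ids]))
    sib_calls = background.calls.copy()
    sib_calls["sample_id"] = sib_calls["sample_id"].map(remap)
    transmitted_region = {
        sid: set(grp["region_idx"]) for sid, grp in sib_calls.groupby("sample_id")
    }

    rows = []
    true_calls = cohort.calls[cohort.calls["region_idx"] >= 0]
    for idx in index_ids:
        own = true_calls[true_calls["sample_id"] == idx]
        for _, call in own.iterrows():
            if rng.random() < transmission_rate:
                rows.append(
                    (
                        sib_of[idx],
                        call["chrom"],
                        call["start"],
                        call["end"],
                        call["cn"],
                        call["n_probes"],
                        call["qs"] if abs(call["qs"]) >= 0.5 else np.sign(call["qs"]) * 0.75,
                        call["region_idx"],
                    )
                )
    transmitted = pd.DataFrame(rows, columns=CALL_COLUMNS + ["region_idx"])
    # transmitted copy replaces an independent background call at the same region
    if not transmitted.empty:
        drop = []
        for row in transmitted.itertuples():
            if row.region_idx in transmitted_region.get(row.sample_id, ()):
                sel = (sib_calls["sample_id"] == row.sample_id) & (
                    sib_calls["region_idx"] == row.region_idx
                )
                drop.extend(sib_calls.index[sel].tolist())
        sib_calls = sib_calls.drop(index=drop)
    if not transmitted.empty:
        sib_calls = pd.concat([sib_calls, transmitted], ignore_index=True)

    pairs = pd.DataFrame({"index_id": index_ids, "sibling_id": [sib_of[i] for i in index_ids]})
    return pairs, sib_calls.reset_index(drop=True)


@dataclass(frozen=True)
class FragmentationParams:
    max_fragments: int = 3
    gap_fraction: float = 0.15  # per-junction gap as a fraction of the merged pair span
    min_fragment_bp: int = 1_000

    def __post_init__(self) -> None:
        if self.max_fragments < 1:
            raise ValueError("max_fragments must be >= 1")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction outside [0, 1)")


def simulate_wgs_calls(
    true_calls: pd.DataFrame,
    fragmentation: FragmentationParams | None = None,
    fn_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a WGS-style call set: each true call dropped with probability
    ``fn_rate``, otherwise split into 1..max_fragments same-type fragments
    whose junction gaps stay below ``gap_fraction`` of the local merged span,
    so a gap-rule merge can reassemble the original call."""
    if not 0.0 <= fn_rate <= 1.0:
        raise ValueError("fn_rate outside [0, 1]")
    rng = np.random.default_rng(seed)
    cols = ["sample_id", "chrom", "start", "end", "cn"]
    rows = []
    for call in true_calls.itertuples():
        if rng.random() < fn_rate:
            continue
        start, end, length = int(call.start), int(call.end), int(call.end - call.start + 1)
        k = 1
        if fragmentation is not None and fragmentation.max_fragments > 1:
            k_cap = min(fragmentation.max_fragments, length // (2 * fragmentation.min_fragment_bp))
            k = int(rng.integers(1, k_cap + 1)) if k_cap >= 1 else 1
        if k == 1:
            rows.append((call.sample_id, call.chrom, start, end, call.cn))
            continue
        edges = np.linspace(start, end + 1, k + 1).astype(np.int64)
        frags = [[int(edges[i]), int(edges[i + 1]) - 1] for i in range(k)]
        for i in range(k - 1):
            left, right = frags[i], frags[i + 1]
            pair_len = right[1] - left[0] + 1
            gf = rng.uniform(0.2, 0.9) * fragmentation.gap_fraction
            gap = int(gf * pair_len)  # gap < gap_fraction * merged-pair span
            take_left = gap // 2
            take_right = gap - take_left
            left[1] -= take_left
            right[0] += take_right
        for fs, fe in frags:
            if fe > fs:
                rows.append((call.sample_id, call.chrom, fs, fe, call.cn))
    return pd.DataFrame(rows, columns=cols)
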