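"""PLINK 1 binary file-set I/O for the CNV dosage encodings.

Each association model's genotypes are materialized as a standard
BED/BIM/FAM triple so they can be consumed by external tooling. Alleles are
A/T: the T allele counts copies (deletion = AA, neutral = AT, duplication =
TT under the mirror model, with the type-specific models coding the
disregarded carriers as missing, "00"). A1 is assigned to the minor allele
per probe (ties to T), so downstream effect sizes must be homogenized to
the T scale by flipping the sign whenever A1 is "A".

BED layout: 3 magic bytes (0x6c 0x1b 0x01 = variant-major), then per
variant ceil(n_samples / 4) bytes, two bits per sample:
00 = homozygous A1, 01 = missing, 10 = heterozygous, 11 = homozygous A2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import MISSING, ModelGenotypes
from .probes import ProbeMap

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# two-bit code indexed by A1-allele dosage (0, 1, 2, and 3 for missing)
_CODE_FROM_A1_DOSAGE = np.array([0b11, 0b10, 0b00, 0b01], dtype=np.uint8)
_A1_DOSAGE_FROM_CODE = np.array([2, -1, 1, 0], dtype=np.int8)


def assign_a1(geno: ModelGenotypes) -> np.ndarray:
    """Minor-allele A1 label per probe; ties go to T."""
    d = geno.dosage.astype(np.int64)
    obs = d != MISSING
    t_alleles = np.where(obs, d, 0).sum(axis=1)
    total = 2 * obs.sum(axis=1)
    return np.where(t_alleles * 2 > total, "A", "T").astype("<U1")


def write_plink(geno: ModelGenotypes, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam encoding the T-allele dosage matrix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    a1 = assign_a1(geno)
    a2 = np.where(a1 == "T", "A", "T")

    bim = pd.DataFrame(
        {
            "chrom": geno.probes.chrom,
            "probe_id": geno.probes.probe_ids,
            "cm": 0,
            "pos": geno.probes.pos,
            "a1": a1,
            "a2": a2,
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in geno.samples:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")

    d = geno.dosage
    a1_dosage = np.where(a1[:, None] == "T", d, 2 - d)
    a1_dosage = np.where(d == MISSING, 3, a1_dosage).astype(np.uint8)
    codes = _CODE_FROM_A1_DOSAGE[a1_dosage]  # (P, S)
    n_probes, n_samples = codes.shape
    padded = n_samples + (-n_samples) % 4
    buf = np.zeros((n_probes, padded), dtype=np.uint8)
    buf[:, :n_samples] = codes
    buf = buf.reshape(n_probes, padded // 4, 4)
    packed = buf[:, :, 0] | buf[:, :, 1] << 2 | buf[:, :, 2] << 4 | buf[:, :, 3] << 6
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def read_plink(prefix: str | Path, model: str = "mirror") -> ModelGenotypes:
    """Read a BED/BIM/FAM triple back into T-allele dosages.

    The stored A1 labels are kept on the result so sign homogenization
    stays possible downstream.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep="\t",
        header=None,
        names=["chrom", "probe_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    samples = fam[1].astype(str).tolist()

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _MAGIC:
        raise ValueError(f"{prefix}.bed: malformed magic bytes {raw[:3]!r}")
    n_probes, n_samples = len(bim), len(samples)
    bytes_per_variant = (n_samples + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != n_probes * bytes_per_variant:
        raise ValueError(f"{prefix}.bed: unexpected payload size {body.size}")
    body = body.reshape(n_probes, bytes_per_variant)
    codes = np.stack(
        [(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(n_probes, bytes_per_variant * 4)[:, :n_samples]
    a1_dosage = _A1_DOSAGE_FROM_CODE[codes]
    a1 = bim["a1"].to_numpy(dtype="<U1")
    dosage = np.where(a1[:, None] == "T", a1_dosage, 2 - a1_dosage)
    dosage = np.where(a1_dosage == MISSING, MISSING, dosage).astype(np.int8)

    probes = ProbeMap(bim[["probe_id", "chrom", "pos"]].copy())
    # ProbeMap sorts by (chrom, pos); realign rows if the BIM was unsorted
    if not np.array_equal(probes.probe_ids, bim["probe_id"].to_numpy()):
        order = [int(np.flatnonzero(bim["probe_id"].to_numpy() == pid)[0]) for pid in probes.probe_ids]
        dosage, a1 = dosage[order], a1[order]
    return ModelGenotypes(model=model, probes=probes, samples=samples, dosage=dosage, a1=a1)
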