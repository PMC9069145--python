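"""Text-format readers and writers.

Conventions: CNV call tables and probe maps are TSV; call files may carry
``# key=value`` header comments (the generator records its seed there).
BED inputs are 0-based half-open and are converted to the 1-based
inclusive coordinates used everywhere inside the package at this boundary.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .synthetic import CALL_COLUMNS, CNVArchitecture, EffectSpec, RegionSpec
from .probes import ProbeMap


def write_calls(calls: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        calls[CALL_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})


def write_probe_map(probes: ProbeMap, path: str | Path) -> None:
    """BIM-style: chrom, probe id, 0 cM, position."""
    df = probes.df
    out = pd.DataFrame(
        {"chrom": df["chrom"], "probe_id": df["probe_id"], "cm": 0, "pos": df["pos"]}
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_probe_map(path: str | Path) -> ProbeMap:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "probe_id", "cm", "pos"], dtype={"chrom": str}
    )
    return ProbeMap(df[["probe_id", "chrom", "pos"]])


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "sample_id") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True, index_label=index_label)


def read_table(path: str | Path, index_col: str = "sample_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_bed_features(path: str | Path, extra_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a BED-like file into 1-based inclusive intervals.

    Columns: chrom, start, end, then ``extra_columns`` (e.g. gene and
    feature_class for gene files, or a name for SNP-signal lists).
    """
    names = ["chrom", "start", "end"] + (extra_columns or [])
    df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#", dtype={"chrom": str})
    df["chrom"] = df["chrom"].str.removeprefix("chr")
    df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based inclusive
    df["end"] = df["end"].astype(int)
    return df


def architecture_to_yaml(arch: CNVArchitecture, path: str | Path, seed: int | None = None) -> None:
    doc = {
        "seed": seed,
        "regions": [
            {
                "chrom": r.chrom,
                "core_start": r.core_start,
                "core_end": r.core_end,
                "dup_frequency": r.dup_frequency,
                "del_frequency": r.del_frequency,
                "breakpoint_jitter_bp": r.breakpoint_jitter_bp,
                "effects": [
                    {"trait": e.trait, "model": e.model, "beta": e.beta} for e in r.effects
                ],
            }
            for r in arch.regions
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def architecture_from_yaml(path: str | Path) -> CNVArchitecture:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    regions = [
        RegionSpec(
            chrom=str(r["chrom"]),
            core_start=int(r["core_start"]),
            core_end=int(r["core_end"]),
            dup_frequency=float(r.get("dup_frequency", 0.0)),
            del_frequency=float(r.get("del_frequency", 0.0)),
            breakpoint_jitter_bp=int(r.get("breakpoint_jitter_bp", 0)),
            effects=tuple(
                EffectSpec(trait=e["trait"], model=e["model"], beta=float(e["beta"]))
                for e in r.get("effects", [])
            ),
        )
        for r in doc.get("regions", [])
    ]
    return CNVArchitecture(regions=tuple(regions))
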