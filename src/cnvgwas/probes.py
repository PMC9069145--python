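"""Probe maps: the genomic scaffold onto which CNV calls are projected.

A probe map is the microarray's marker list (BIM-like): one row per probe
with a unique identifier, a chromosome label, and a 1-based GRCh37 basepair
position, sorted by (chromosome, position) with strictly increasing
positions within each chromosome. Optional per-array presence flags mark
probes absent from one of the genotyping arrays; cells for samples typed on
such an array are treated as missing before encoding, which feeds the
missingness filter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(c) for c in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("X",)


def _chrom_sort_key(chrom: str) -> int:
    c = str(chrom)
    return 23 if c == "X" else int(c)


@dataclass
class ProbeMap:
    """Sorted probe table with per-chromosome position lookup."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"probe_id", "chrom", "pos"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"probe map missing columns: {sorted(missing)}")
        df = self.df.copy()
        df["chrom"] = df["chrom"].astype(str)
        bad = set(df["chrom"]) - set(CHROMOSOMES)
        if bad:
            raise ValueError(f"unknown chromosome labels: {sorted(bad)}")
        df["pos"] = df["pos"].astype(np.int64)
        if (df["pos"] < 1).any():
            raise ValueError("probe positions must be >= 1 (1-based)")
        df = df.sort_values(
            ["chrom", "pos"], key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s
        ).reset_index(drop=True)
        if df["probe_id"].duplicated().any():
            dupes = df.loc[df["probe_id"].duplicated(), "probe_id"].head().tolist()
            raise ValueError(f"duplicate probe ids: {dupes}")
        for _, grp in df.groupby("chrom", sort=False):
            if (np.diff(grp["pos"].to_numpy()) <= 0).any():
                raise ValueError("probe positions must be strictly increasing per chromosome")
        self.df = df
        self._index = {pid: i for i, pid in enumerate(df["probe_id"])}

    def __len__(self) -> int:
        return len(self.df)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.df["probe_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    def loc_of(self, probe_id: str) -> int:
        return self._index[probe_id]

    def rows_in_interval(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row indices of probes whose position lies in [start, end] (1-based inclusive)."""
        mask = self.df["chrom"].to_numpy() == str(chrom)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return idx
        pos = self.df["pos"].to_numpy()[idx]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return idx[lo:hi]

    def subset(self, rows: np.ndarray) -> "ProbeMap":
        return ProbeMap(self.df.iloc[rows].reset_index(drop=True))
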