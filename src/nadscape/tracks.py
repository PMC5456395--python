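"""Probe-level track containers for tiling-array signals.

A :class:`ProbeTrack` holds raw (linear-scale) hybridization intensities
at ordered probe positions, one column per sample.  An
:class:`EnrichmentTrack` holds derived log2 nucleolar-over-background
enrichment values on the same probe grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _validate_grid(frame: pd.DataFrame, value_cols: list[str]) -> None:
    if "chrom" not in frame.columns or "pos" not in frame.columns:
        raise ValueError("track frame needs 'chrom' and 'pos' columns")
    for col in value_cols:
        if col not in frame.columns:
            raise ValueError(f"missing sample column {col!r}")
    for chrom, grp in frame.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"{chrom}: probe positions must be strictly increasing")


@dataclass
class ProbeTrack:
    """Probe positions with one intensity column per sample.

    ``frame`` columns: chrom, pos, then ``samples`` in order.  Values are
    linear-scale intensities unless ``log_space`` is set.
    """

    frame: pd.DataFrame
    samples: list[str]
    log_space: bool = False

    def __post_init__(self) -> None:
        _validate_grid(self.frame, self.samples)
        self.frame = self.frame.sort_values(["chrom", "pos"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.frame)

    def values(self) -> np.ndarray:
        """(probe, sample) value matrix."""
        return self.frame[self.samples].to_numpy(dtype=float)

    def same_grid(self, other: "ProbeTrack | EnrichmentTrack") -> bool:
        a = self.frame[["chrom", "pos"]]
        b = other.frame[["chrom", "pos"]]
        return len(a) == len(b) and bool((a.to_numpy() == b.to_numpy()).all())

    def with_values(self, matrix: np.ndarray) -> "ProbeTrack":
        frame = self.frame.copy()
        frame[self.samples] = matrix
        return ProbeTrack(frame, list(self.samples), self.log_space)


@dataclass
class EnrichmentTrack:
    """Log2 enrichment values per probe, one column per retained sample."""

    frame: pd.DataFrame
    samples: list[str] = field(default_factory=lambda: ["E"])

    def __post_init__(self) -> None:
        _validate_grid(self.frame, self.samples)
        self.frame = self.frame.sort_values(["chrom", "pos"], kind="stable").reset_index(
            drop=True
        )
        if not np.isfinite(self.frame[self.samples].to_numpy(dtype=float)).all():
            raise ValueError("enrichment values must be finite")

    def __len__(self) -> int:
        return len(self.frame)

    def values(self) -> np.ndarray:
        return self.frame[self.samples].to_numpy(dtype=float)

    def single_values(self) -> np.ndarray:
        if len(self.samples) != 1:
            raise ValueError("track has multiple sample columns; average first")
        return self.frame[self.samples[0]].to_numpy(dtype=float)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    def chrom_slice(self, chrom: str) -> pd.DataFrame:
        return self.frame[self.frame["chrom"] == chrom]

    def with_values(self, matrix: np.ndarray) -> "EnrichmentTrack":
        frame = self.frame.copy()
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim == 1:
            matrix = matrix[:, None]
        frame[self.samples] = matrix
        return EnrichmentTrack(frame, list(self.samples))

    def probe_spacing(self) -> float:
        """Median distance between consecutive probes (bp)."""
        diffs = []
        for _, grp in self.frame.groupby("chrom", sort=False):
            d = np.diff(grp["pos"].to_numpy())
            if len(d):
                diffs.append(d)
        if not diffs:
            raise ValueError("cannot estimate spacing from single-probe chromosomes")
        return float(np.median(np.concatenate(diffs)))
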