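"""Genomic region containers: domain sets, feature sets, signal tracks.

All containers wrap a pandas DataFrame in BED-style 0-based half-open
coordinates and validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import as_interval_array
from .layout import GenomeLayout

NAD = "NAD"
INAD = "iNAD"


def _check_sorted_disjoint(frame: pd.DataFrame) -> None:
    for chrom, grp in frame.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if np.any(starts >= ends):
            raise ValueError(f"{chrom}: intervals must satisfy start < end")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: intervals overlap or are unsorted")


@dataclass
class DomainSet:
    """Sorted, disjoint labeled intervals with optional per-interval score.

    ``frame`` columns: chrom, start, end, label (NAD | iNAD), score
    (mean log2 enrichment within the interval; NaN when not scored).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "label"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"DomainSet frame missing columns: {sorted(missing)}")
        if "score" not in self.frame.columns:
            self.frame = self.frame.assign(score=np.nan)
        self.frame = self.frame.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )
        _check_sorted_disjoint(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, label: str) -> "DomainSet":
        return DomainSet(self.frame[self.frame["label"] == label].copy())

    def nads(self) -> "DomainSet":
        return self.subset(NAD)

    def inads(self) -> "DomainSet":
        return self.subset(INAD)

    def intervals(self, chrom: str) -> np.ndarray:
        grp = self.frame[self.frame["chrom"] == chrom]
        return as_interval_array(grp[["start", "end"]].to_numpy())

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    def total_bp(self, label: str | None = None) -> int:
        frame = self.frame if label is None else self.frame[self.frame["label"] == label]
        return int((frame["end"] - frame["start"]).sum())

    def widths(self, label: str | None = None) -> np.ndarray:
        frame = self.frame if label is None else self.frame[self.frame["label"] == label]
        return (frame["end"] - frame["start"]).to_numpy()

    @classmethod
    def from_intervals(
        cls, chrom_intervals: dict[str, np.ndarray], label: str = NAD
    ) -> "DomainSet":
        rows = []
        for chrom, arr in chrom_intervals.items():
            for s, e in as_interval_array(arr):
                rows.append((chrom, int(s), int(e), label, np.nan))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "score"]))

    def check_tiles(self, layout: GenomeLayout) -> None:
        """Assert the set tiles every chromosome of the layout exactly."""
        for chrom, length in layout.lengths.items():
            iv = self.intervals(chrom)
            if len(iv) == 0:
                raise AssertionError(f"{chrom}: no intervals")
            if iv[0, 0] != 0 or iv[-1, 1] != length:
                raise AssertionError(f"{chrom}: tiling does not span [0, {length})")
            if np.any(iv[1:, 0] != iv[:-1, 1]):
                raise AssertionError(f"{chrom}: gaps or overlaps in tiling")


@dataclass
class FeatureSet:
    """Named, classed features (genes, repeats, chromatin-state segments).

    ``frame`` columns: chrom, start, end, name, feature_class and an
    optional strand column.  Unlike :class:`DomainSet`, features may
    overlap each other unless a caller demands a partition.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "name", "feature_class"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"FeatureSet frame missing columns: {sorted(missing)}")
        if np.any(self.frame["start"].to_numpy() >= self.frame["end"].to_numpy()):
            raise ValueError("features must satisfy start < end")
        self.frame = self.frame.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.frame)

    def classes(self) -> list[str]:
        return sorted(self.frame["feature_class"].unique())

    def is_partition(self) -> bool:
        """True when features are pairwise disjoint within each chromosome."""
        try:
            _check_sorted_disjoint(self.frame)
        except ValueError:
            return False
        return True


@dataclass
class SignalTrack:
    """Stepwise-constant signal with bedGraph semantics.

    ``frame`` columns: chrom, start, end, value.  Intervals must not
    overlap within a chromosome; uncovered bases are treated as zero by
    downstream per-base averages.
    """

    frame: pd.DataFrame
    name: str = "signal"

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "value"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"SignalTrack frame missing columns: {sorted(missing)}")
        self.frame = self.frame.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )
        _check_sorted_disjoint(self.frame)

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        grp = self.frame[self.frame["chrom"] == chrom]
        return (
            grp["start"].to_numpy(dtype=np.int64),
            grp["end"].to_numpy(dtype=np.int64),
            grp["value"].to_numpy(dtype=float),
        )


def interval_means(
    starts: np.ndarray,
    ends: np.ndarray,
    values: np.ndarray,
    query_starts: np.ndarray,
    query_ends: np.ndarray,
) -> np.ndarray:
    """Per-base mean of a stepwise signal over query intervals, zero-filled.

    ``starts/ends/values`` describe one chromosome of a
    :class:`SignalTrack` (sorted, disjoint).  Uses a prefix integral of
    the signal so each query costs O(log n).  Bases not covered by any
    signal interval contribute zero to the mean (bedGraph convention).
    """
    query_starts = np.asarray(query_starts, dtype=np.int64)
    query_ends = np.asarray(query_ends, dtype=np.int64)
    if np.any(query_starts >= query_ends):
        raise ValueError("queries must satisfy start < end")
    if len(starts) == 0:
        return np.zeros(len(query_starts), dtype=float)

    # prefix[i] = integral of the signal over [0, starts[i]);
    # a query position inside interval i adds value[i] * overlap.
    seg_area = values * (ends - starts)
    prefix = np.concatenate([[0.0], np.cumsum(seg_area)])

    def integral(pos: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(starts, pos, side="right") - 1
        out = np.zeros(len(pos), dtype=float)
        has = idx >= 0
        idx_h = idx[has]
        out[has] = prefix[idx_h]
        clip = np.minimum(pos[has], ends[idx_h])
        out[has] += values[idx_h] * np.maximum(clip - starts[idx_h], 0)
        return out

    area = integral(query_ends) - integral(query_starts)
    return area / (query_ends - query_starts)
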