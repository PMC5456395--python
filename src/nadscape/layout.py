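"""Genome layout: chromosome lengths and centromere (arm boundary) intervals.

All coordinates in this package are 0-based, half-open, in base pairs —
the BED convention.  A layout describes the analyzed genome extent:
chromosome lengths plus, optionally, one centromere interval per
chromosome that splits it into a p and a q arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths and optional centromere intervals.

    Parameters
    ----------
    lengths
        Mapping chromosome name -> length in bp.
    centromeres
        Mapping chromosome name -> (start, end) of the centromere gap,
        half-open.  Chromosomes without an entry have no arm annotation;
        contacts on them cannot be arm-classified.
    """

    lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("layout must contain at least one chromosome")
        for chrom, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {n}")
        for chrom, (s, e) in self.centromeres.items():
            if chrom not in self.lengths:
                raise ValueError(f"centromere given for unknown chromosome {chrom!r}")
            if not (0 <= s < e <= self.lengths[chrom]):
                raise ValueError(f"centromere [{s}, {e}) outside chromosome {chrom!r}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    @classmethod
    def toy(
        cls,
        n_chromosomes: int = 1,
        length: int = 10_000_000,
        centromere_fraction: float = 0.02,
    ) -> "GenomeLayout":
        """Equal-length toy genome with a centered centromere on each chromosome."""
        lengths = {f"chr{i + 1}": int(length) for i in range(n_chromosomes)}
        half_gap = int(length * centromere_fraction / 2)
        mid = int(length) // 2
        centromeres = {
            c: (mid - half_gap, mid + half_gap) for c in lengths
        }
        return cls(lengths=lengths, centromeres=centromeres)

    @classmethod
    def from_table(cls, frame: pd.DataFrame) -> "GenomeLayout":
        """Build a layout from a table with columns chrom, length and
        optionally cen_start, cen_end (use -1/-1 for no centromere)."""
        lengths = dict(zip(frame["chrom"], frame["length"].astype(int)))
        centromeres: dict[str, tuple[int, int]] = {}
        if "cen_start" in frame.columns:
            for _, row in frame.iterrows():
                s, e = int(row["cen_start"]), int(row["cen_end"])
                if s >= 0 and e > s:
                    centromeres[row["chrom"]] = (s, e)
        return cls(lengths=lengths, centromeres=centromeres)
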