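"""Readers and writers for the plain-text genomic formats the package uses.

All interval output is BED-style 0-based half-open.  Domain sets go out
as BED6 (the score column is the NAD score × 1000, rounded and clipped
to the BED 0–1000 convention) with a sidecar TSV carrying the
full-precision scores.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .regions import DomainSet, FeatureSet, SignalTrack
from .tracks import ProbeTrack


def read_bed(path, feature_class: str | None = None) -> FeatureSet:
    """Read BED3/4/6 into a FeatureSet (class defaults to the name column)."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    frame = frame.rename(columns={0: "chrom", 1: "start", 2: "end"})
    frame["name"] = frame[3] if 3 in frame.columns else [
        f"feat{i}" for i in range(len(frame))
    ]
    frame["feature_class"] = feature_class if feature_class else frame["name"]
    return FeatureSet(frame[["chrom", "start", "end", "name", "feature_class"]])


def read_domain_bed(path, label: str = "NAD") -> DomainSet:
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    frame = frame.rename(columns={0: "chrom", 1: "start", 2: "end"})
    out = frame[["chrom", "start", "end"]].copy()
    out["label"] = label
    out["score"] = np.nan
    return DomainSet(out)


def write_domain_bed(domains: DomainSet, path, sidecar: bool = True) -> None:
    """Write a DomainSet as BED6 plus a full-precision score TSV."""
    path = Path(path)
    frame = domains.frame
    score = frame["score"].fillna(0.0)
    bed = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "start": frame["start"],
            "end": frame["end"],
            "name": frame["label"],
            "score": np.clip(np.round(score * 1000), 0, 1000).astype(int),
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
    if sidecar:
        frame.to_csv(path.with_suffix(path.suffix + ".scores.tsv"), sep="\t", index=False)


def read_bedgraph(path, name: str = "signal") -> SignalTrack:
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
    )
    return SignalTrack(frame, name=name)


def write_bedgraph(track: SignalTrack, path) -> None:
    track.frame[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_probe_bedgraphs(paths: list, samples: list[str] | None = None) -> ProbeTrack:
    """Merge single-sample probe bedGraphs (chrom, pos, pos+1, value) onto
    one grid; all files must share identical probe positions."""
    samples = samples or [f"s{i + 1}" for i in range(len(paths))]
    base = None
    for path, sample in zip(paths, samples):
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "pos", "_end", "value"]
        )
        frame = frame[["chrom", "pos", "value"]].rename(columns={"value": sample})
        if base is None:
            base = frame
        else:
            if len(frame) != len(base) or not (
                frame[["chrom", "pos"]].to_numpy() == base[["chrom", "pos"]].to_numpy()
            ).all():
                raise ValueError(f"{path}: probe grid differs from the first file")
            base[sample] = frame[sample].to_numpy()
    return ProbeTrack(base, samples)


def write_probe_bedgraph(track: ProbeTrack, prefix) -> list[Path]:
    """One bedGraph per sample: chrom, pos, pos+1, value."""
    written = []
    for sample in track.samples:
        out = Path(f"{prefix}.{sample}.bedGraph")
        frame = pd.DataFrame(
            {
                "chrom": track.frame["chrom"],
                "start": track.frame["pos"],
                "end": track.frame["pos"] + 1,
                "value": track.frame[sample],
            }
        )
        frame.to_csv(out, sep="\t", header=False, index=False)
        written.append(out)
    return written
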