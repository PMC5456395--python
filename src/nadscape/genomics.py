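"""Comparative genomics of domain sets.

Complements, bp-overlap / Jaccard statistics, chromatin-state
composition, feature densities, per-segment signal means, border-aligned
metaprofiles and class-wise score summaries.  Jaccard here is the
bedtools convention: intersecting bp divided by union bp of two interval
sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from .layout import GenomeLayout
from .regions import INAD, NAD, DomainSet, FeatureSet, SignalTrack, interval_means


def complement_intervals(domains: DomainSet, layout: GenomeLayout) -> DomainSet:
    """Per-chromosome set complement over the full layout extent."""
    out = {}
    for chrom, length in layout.lengths.items():
        arr = domains.intervals(chrom)
        if len(arr) and arr[-1, 1] > length:
            raise ValueError(f"{chrom}: interval exceeds chromosome length")
        out[chrom] = iv.complement(arr, length)
    comp = DomainSet.from_intervals(out, INAD)
    return comp


def overlap_stats(a: DomainSet, b: DomainSet) -> dict:
    """Intersection / set-difference / union bp and the Jaccard index."""
    chroms = sorted(set(a.chromosomes()) | set(b.chromosomes()))
    inter = a_only = b_only = 0
    for chrom in chroms:
        ia, ib = a.intervals(chrom), b.intervals(chrom)
        inter += iv.total_bp(iv.intersect(ia, ib))
        a_only += iv.total_bp(iv.subtract(ia, ib))
        b_only += iv.total_bp(iv.subtract(ib, ia))
    union = inter + a_only + b_only
    return {
        "intersection_bp": inter,
        "a_only_bp": a_only,
        "b_only_bp": b_only,
        "union_bp": union,
        "jaccard": inter / union if union else 0.0,
    }


def state_composition(domains: DomainSet, states: FeatureSet) -> pd.DataFrame:
    """Per-state bp and class-normalized fractions in NADs vs iNADs.

    ``states`` must partition (no overlaps).  The log2 ratio compares
    class-size-normalized fractions; a state absent from one class gets
    an infinite ratio rather than being dropped.
    """
    if not states.is_partition():
        raise ValueError("state intervals overlap; a partition is required")
    nad_bp = domains.total_bp(NAD)
    inad_bp = domains.total_bp(INAD)
    rows = []
    for state in states.classes():
        sframe = states.frame[states.frame["feature_class"] == state]
        in_nad = in_inad = 0
        for chrom in domains.chromosomes():
            s_iv = sframe.loc[sframe["chrom"] == chrom, ["start", "end"]].to_numpy()
            if len(s_iv) == 0:
                continue
            in_nad += iv.overlap_bp(s_iv, domains.nads().intervals(chrom))
            in_inad += iv.overlap_bp(s_iv, domains.inads().intervals(chrom))
        f_nad = in_nad / nad_bp if nad_bp else np.nan
        f_inad = in_inad / inad_bp if inad_bp else np.nan
        # explicit sentinels for states absent from one class
        if not f_nad and not f_inad:
            ratio = np.nan
        elif not f_inad:
            ratio = np.inf
        elif not f_nad:
            ratio = -np.inf
        else:
            ratio = float(np.log2(f_nad / f_inad))
        rows.append((state, in_nad, in_inad, f_nad, f_inad, ratio))
    return pd.DataFrame(
        rows,
        columns=[
            "state",
            "nad_bp",
            "inad_bp",
            "nad_fraction",
            "inad_fraction",
            "log2_ratio",
        ],
    )


def _majority_class(domains: DomainSet, chrom: str, start: int, end: int) -> str:
    ov = iv.overlap_bp(np.array([[start, end]]), domains.nads().intervals(chrom))
    # majority overlap assigns the feature; an exact 50/50 tie goes to NAD
    return NAD if 2 * ov >= (end - start) else INAD


def feature_density(
    domains: DomainSet, features: FeatureSet, per: int = 1_000_000
) -> pd.DataFrame:
    """Feature counts per Mb of domain class, by feature class.

    Each feature counts in the domain class covering the majority of its
    length.  Densities are emitted both per Mb of the domain class and
    per Mb of the whole analyzed extent.
    """
    class_bp = {NAD: domains.total_bp(NAD), INAD: domains.total_bp(INAD)}
    genome_bp = class_bp[NAD] + class_bp[INAD]
    counts = {
        (fc, dc): 0 for fc in features.classes() for dc in (NAD, INAD)
    }
    for _, row in features.frame.iterrows():
        dc = _majority_class(domains, row["chrom"], row["start"], row["end"])
        counts[(row["feature_class"], dc)] += 1
    rows = []
    for (fc, dc), n in sorted(counts.items()):
        bp = class_bp[dc]
        rows.append(
            (
                fc,
                dc,
                n,
                n / (bp / per) if bp else np.nan,
                n / (genome_bp / per) if genome_bp else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_class",
            "domain_class",
            "count",
            "density_per_mb_class",
            "density_per_mb_genome",
        ],
    )


def segment_mean_signal(domains: DomainSet, signal: SignalTrack) -> pd.DataFrame:
    """Length-weighted per-base mean signal for every domain segment.

    Bases without signal coverage count as zero.  Returns one row per
    segment (chrom, start, end, label, mean) for box-plotting per class.
    """
    rows = []
    for chrom in domains.chromosomes():
        grp = domains.frame[domains.frame["chrom"] == chrom]
        starts, ends, values = signal.chrom_arrays(chrom)
        means = interval_means(
            starts, ends, values, grp["start"].to_numpy(), grp["end"].to_numpy()
        )
        for (_, row), m in zip(grp.iterrows(), means):
            rows.append((chrom, row["start"], row["end"], row["label"], float(m)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "mean"])


@dataclass
class MetaProfile:
    """Border-aligned average signal profile.

    ``offsets`` are bin-center offsets in bp relative to the aligned
    border; negative offsets lie outside the domain, positive inside,
    for both the 5' and the (mirrored) 3' border.  ``means`` maps
    (signal name, side) -> per-bin mean, side in {"5p", "3p"}.
    """

    offsets: np.ndarray
    means: dict[tuple[str, str], np.ndarray]
    n_domains: int


def border_metaprofile(
    domains: DomainSet,
    signals: list[SignalTrack],
    flank: int = 500_000,
    bin_size: int = 1_000,
    min_width: int = 500_000,
    label: str = NAD,
) -> MetaProfile:
    """Average signals in fixed bins around 5'/3' borders of wide domains.

    Only domains with width > ``min_width`` contribute.  The 5' border is
    each domain's start on the p→q axis; the 3' border (domain end) is
    mirrored before averaging so that in both profiles negative offsets
    point away from the domain interior's side, i.e. outside.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin size")
    n_bins = 2 * flank // bin_size
    offsets = -flank + bin_size * np.arange(n_bins) + bin_size // 2

    frame = domains.frame[domains.frame["label"] == label]
    wide = frame[(frame["end"] - frame["start"]) > min_width]
    n_domains = len(wide)
    if n_domains == 0:
        warnings.warn("no domain wider than min_width; empty profile", stacklevel=2)
        return MetaProfile(offsets, {}, 0)

    means: dict[tuple[str, str], np.ndarray] = {}
    for sig in signals:
        acc = {"5p": np.zeros(n_bins), "3p": np.zeros(n_bins)}
        cnt = {"5p": np.zeros(n_bins), "3p": np.zeros(n_bins)}
        for chrom, grp in wide.groupby("chrom", sort=False):
            starts, ends, values = sig.chrom_arrays(chrom)
            # analyzed extent: windows beyond it would zero-fill artificially
            extent = int(domains.frame.loc[domains.frame["chrom"] == chrom, "end"].max())
            for _, row in grp.iterrows():
                for side, border in (("5p", row["start"]), ("3p", row["end"])):
                    qs = border - flank + bin_size * np.arange(n_bins)
                    qe = qs + bin_size
                    valid = (qs >= 0) & (qe <= extent)
                    if not valid.any():
                        continue
                    vals = interval_means(starts, ends, values, qs[valid], qe[valid])
                    if side == "3p":
                        # mirror so positive offsets lie inside the domain
                        idx = np.nonzero(valid)[0]
                        tgt = n_bins - 1 - idx
                    else:
                        tgt = np.nonzero(valid)[0]
                    acc[side][tgt] += vals
                    cnt[side][tgt] += 1
        for side in ("5p", "3p"):
            with np.errstate(invalid="ignore"):
                means[(sig.name, side)] = np.where(
                    cnt[side] > 0, acc[side] / np.maximum(cnt[side], 1), np.nan
                )
    return MetaProfile(offsets, means, n_domains)


def class_score_summary(values, classes) -> pd.DataFrame:
    """Per-class n, median, quartiles and notch half-width.

    The notch is 1.58·IQR/√n — the conventional 95% confidence band on
    a boxplot median.  Classes with no members are omitted with a
    warning.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    if len(values) != len(classes):
        raise ValueError("values and classes must have equal length")
    rows = []
    for cls in pd.unique(classes):
        vals = values[classes == cls]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            warnings.warn(f"class {cls!r} has no finite values; omitted", stacklevel=2)
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        notch = 1.58 * iqr / np.sqrt(len(vals))
        rows.append((cls, len(vals), med, q1, q3, notch))
    return pd.DataFrame(
        rows, columns=["class", "n", "median", "q1", "q3", "notch"]
    )
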