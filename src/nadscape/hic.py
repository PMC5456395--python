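"""Domain-class analysis of normalized intrachromosomal Hi-C contacts.

Contacts are loaded from sparse triplet files (bin_i_start, bin_j_start,
raw_count — the GSE63525 dialect) with a one-value-per-line per-bin
normalization vector; normalized frequency = raw / (v_i · v_j).  Each
10 kb bin gets a NAD/iNAD label by majority-bp overlap with the NAD set,
every contact a pair class (NAD-NAD, iNAD-iNAD, mixed) and an arm class
(pp, qq or pq relative to the centromere), and class-wise distance
profiles, band summaries (10–50 Mb and >100 Mb) and masked dense
matrices are aggregated from the classified records.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .intervals import coverage_in_bins
from .layout import GenomeLayout
from .regions import NAD, DomainSet

PAIR_CLASSES = ["NAD-NAD", "iNAD-iNAD", "mixed"]
DEFAULT_BANDS = [(10_000_000, 50_000_000), (100_000_000, None)]


def load_normalized_contacts(
    triplet_file, norm_vector_file, bin_size: int = 10_000, chrom: str = "chr1"
) -> tuple[pd.DataFrame, dict]:
    """Load raw triplets, apply the normalization vector, drop bad bins.

    Records whose bins have a NaN or zero normalization entry are
    dropped and counted in the returned report.  Coordinates that are
    not multiples of ``bin_size``, or bins beyond the vector's reach,
    reject the file.
    """
    trip = pd.read_csv(
        triplet_file,
        sep=r"\s+",
        header=None,
        names=["bin_i", "bin_j", "raw"],
        dtype={"bin_i": np.int64, "bin_j": np.int64, "raw": float},
    )
    if np.any(trip[["bin_i", "bin_j"]].to_numpy() % bin_size != 0):
        raise ValueError("triplet coordinates are not multiples of the bin size")
    with open(norm_vector_file) as fh:
        vec = np.array([float(line) for line in fh if line.strip()], dtype=float)
    i_idx = trip["bin_i"].to_numpy() // bin_size
    j_idx = trip["bin_j"].to_numpy() // bin_size
    if max(i_idx.max(initial=0), j_idx.max(initial=0)) >= len(vec):
        raise ValueError("normalization vector shorter than the contact extent")
    vi, vj = vec[i_idx], vec[j_idx]
    good = np.isfinite(vi) & np.isfinite(vj) & (vi != 0) & (vj != 0)
    records = trip.loc[good].copy()
    records["normalized"] = records["raw"].to_numpy() / (vi[good] * vj[good])
    lo = records[["bin_i", "bin_j"]].min(axis=1)
    hi = records[["bin_i", "bin_j"]].max(axis=1)
    records["bin_i"], records["bin_j"] = lo, hi
    records["distance"] = records["bin_j"] - records["bin_i"]
    records.insert(0, "chrom", chrom)
    report = {
        "loaded": int(len(trip)),
        "dropped_norm": int((~good).sum()),
        "retained": int(len(records)),
    }
    return records.reset_index(drop=True), report


def bin_domain_labels(
    nads: DomainSet, chrom: str, bin_size: int, n_bins: int
) -> np.ndarray:
    """True where a bin's majority of bp overlaps the NAD set (tie -> NAD)."""
    cov = coverage_in_bins(nads.nads().intervals(chrom), bin_size, n_bins)
    return cov * 2 >= bin_size


def classify_contacts(
    records: pd.DataFrame,
    nads: DomainSet,
    layout: GenomeLayout,
    bin_size: int = 10_000,
) -> tuple[pd.DataFrame, dict]:
    """Attach pair_class and arm_class to every contact record.

    Bins overlapping the centromere gap cannot be arm-classified; their
    contacts are dropped and counted so that loaded = classified +
    dropped always holds.
    """
    out_frames = []
    dropped_cen = 0
    for chrom, grp in records.groupby("chrom", sort=False):
        length = layout.lengths[chrom]
        n_bins = int(np.ceil(length / bin_size))
        if np.any(grp["bin_j"].to_numpy() + bin_size > n_bins * bin_size):
            raise ValueError(f"{chrom}: bin beyond chromosome end")
        is_nad = bin_domain_labels(nads, chrom, bin_size, n_bins)
        i_idx = grp["bin_i"].to_numpy() // bin_size
        j_idx = grp["bin_j"].to_numpy() // bin_size
        ni, nj = is_nad[i_idx], is_nad[j_idx]
        pair = np.where(ni & nj, "NAD-NAD", np.where(~ni & ~nj, "iNAD-iNAD", "mixed"))

        cen = layout.centromeres.get(chrom)
        if cen is None:
            arm_code = np.zeros(n_bins, dtype=np.int8)  # single-arm chromosome
        else:
            cs, ce = cen
            starts = np.arange(n_bins, dtype=np.int64) * bin_size
            ends = starts + bin_size
            arm_code = np.full(n_bins, -1, dtype=np.int8)  # -1 = centromeric
            arm_code[ends <= cs] = 0  # p arm
            arm_code[starts >= ce] = 1  # q arm
        ai, aj = arm_code[i_idx], arm_code[j_idx]
        keep = (ai >= 0) & (aj >= 0)
        dropped_cen += int((~keep).sum())
        arm = np.where(ai == aj, np.where(ai == 0, "pp", "qq"), "pq")
        sub = grp.loc[keep].copy()
        sub["pair_class"] = pair[keep]
        sub["arm_class"] = arm[keep]
        out_frames.append(sub)
    classified = pd.concat(out_frames, ignore_index=True) if out_frames else records.iloc[0:0]
    report = {
        "input": int(len(records)),
        "dropped_centromeric": dropped_cen,
        "classified": int(len(classified)),
    }
    return classified, report


def _all_pair_counts(
    bin_is_nad: np.ndarray, bin_size: int, bin_width: int
) -> pd.DataFrame:
    """Possible bin pairs per distance bin per class via autocorrelation."""
    from scipy.signal import fftconvolve

    nad = np.asarray(bin_is_nad, dtype=float)
    inad = 1.0 - nad
    n = len(nad)

    def autocorr(x):
        full = fftconvolve(x, x[::-1])
        return np.rint(full[n - 1 :]).astype(np.int64)  # lags 0..n-1

    nn = autocorr(nad)
    ii = autocorr(inad)
    total = n - np.arange(n)
    mixed = total - nn - ii
    dist = np.arange(n) * bin_size
    frame = pd.DataFrame(
        {
            "dist_bin": (dist // bin_width) * bin_width,
            "NAD-NAD": nn,
            "iNAD-iNAD": ii,
            "mixed": mixed,
        }
    ).iloc[1:]  # drop the zero-distance diagonal
    melted = frame.melt(id_vars="dist_bin", var_name="pair_class", value_name="n_possible")
    return melted.groupby(["pair_class", "dist_bin"], as_index=False)["n_possible"].sum()


def distance_profiles(
    records: pd.DataFrame,
    max_distance: int | None = None,
    bin_width: int = 1_000_000,
    split_arms: bool = False,
    denominator: str = "observed",
    bin_labels: dict[str, np.ndarray] | None = None,
    bin_size: int = 10_000,
) -> pd.DataFrame:
    """Mean normalized frequency per pair class per distance bin.

    ``denominator="observed"`` (default) averages over recorded pairs
    only.  ``denominator="all"`` divides instead by the number of
    possible bin pairs of that class at that distance (unrecorded pairs
    count as zero contacts); it requires ``bin_labels`` — per-chromosome
    boolean NAD arrays as produced by :func:`bin_domain_labels` — and is
    incompatible with the arm split.
    """
    if denominator not in ("observed", "all"):
        raise ValueError("denominator must be 'observed' or 'all'")
    recs = records
    if max_distance is not None:
        recs = recs[recs["distance"] <= max_distance]
    keys = ["pair_class"] + (["arm_class"] if split_arms else [])
    dist_bin = (recs["distance"] // bin_width) * bin_width
    grouped = recs.assign(dist_bin=dist_bin).groupby(keys + ["dist_bin"], observed=True)
    agg = grouped["normalized"].agg(["sum", "count"]).reset_index()
    if denominator == "observed":
        agg["mean"] = agg["sum"] / agg["count"]
    else:
        if split_arms:
            raise ValueError("all-pairs denominator does not support the arm split")
        if bin_labels is None:
            raise ValueError("all-pairs denominator requires bin_labels")
        totals = pd.concat(
            [_all_pair_counts(lab, bin_size, bin_width) for lab in bin_labels.values()]
        )
        totals = totals.groupby(["pair_class", "dist_bin"], as_index=False)[
            "n_possible"
        ].sum()
        agg = agg.merge(totals, on=["pair_class", "dist_bin"], how="left")
        agg["mean"] = agg["sum"] / agg["n_possible"]
    return agg.drop(columns=["sum"]).rename(columns={"count": "n_pairs"})


def band_summaries(
    records: pd.DataFrame,
    layout: GenomeLayout,
    bands=None,
) -> pd.DataFrame:
    """Per-chromosome, per-class mean normalized frequency in distance bands.

    Default bands: 10–50 Mb and >100 Mb.  Chromosomes too short to host
    a band are omitted with a warning (the >100 Mb band is only
    meaningful on long chromosomes).
    """
    bands = DEFAULT_BANDS if bands is None else bands
    rows = []
    for chrom, grp in records.groupby("chrom", sort=False):
        length = layout.lengths[chrom]
        for lo, hi in bands:
            hi_label = hi if hi is not None else np.inf
            if length <= lo:
                warnings.warn(
                    f"{chrom}: length {length} too short for band ({lo}, {hi_label})",
                    stacklevel=2,
                )
                continue
            sel = grp["distance"] >= lo
            if hi is not None:
                sel &= grp["distance"] < hi
            sub = grp.loc[sel]
            if len(sub) == 0:
                warnings.warn(f"{chrom}: empty band ({lo}, {hi_label})", stacklevel=2)
                continue
            for cls, cgrp in sub.groupby("pair_class", observed=True):
                rows.append(
                    (chrom, cls, lo, hi_label, float(cgrp["normalized"].mean()), len(cgrp))
                )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pair_class", "band_lo", "band_hi", "mean_freq", "n_pairs"],
    )


def mask_matrix(
    matrix: np.ndarray, bin_is_nad: np.ndarray, keep: str, sentinel: float = np.nan
) -> np.ndarray:
    """Blank rows/columns of bins outside the kept domain class.

    Kept entries are bit-identical to the input; masking is idempotent.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square matrix")
    if len(bin_is_nad) != matrix.shape[0]:
        raise ValueError("bin annotation length mismatch")
    if keep == NAD:
        keep_mask = np.asarray(bin_is_nad, dtype=bool)
    elif keep in ("iNAD",):
        keep_mask = ~np.asarray(bin_is_nad, dtype=bool)
    elif keep == "all":
        return matrix.copy()
    else:
        raise ValueError(f"unknown keep class {keep!r}")
    out = matrix.copy()
    out[~keep_mask, :] = sentinel
    out[:, ~keep_mask] = sentinel
    return out
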