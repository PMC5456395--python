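"""Synthetic intrachromosomal Hi-C contacts with homotypic NAD enrichment.

The expected normalized contact frequency between bins separated by d
bins follows a power-law distance decay d^(−decay_exponent).  Pairs in
which both bins lie in NADs and whose genomic distance falls inside a
configured band receive a multiplicative homotypic boost — the signal
the downstream band summaries are designed to recover.  Multiplicative
lognormal noise keeps frequencies positive.  Raw counts are produced by
multiplying the normalized values by a non-trivial per-bin normalization
vector, so that dividing raw by v_i · v_j (the GSE63525-style
convention) recovers the intended normalized values exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..intervals import coverage_in_bins
from .genomic import TruthSegmentation


@dataclass(frozen=True)
class HiCSimParams:
    """Parameters of the synthetic contact generator.

    ``keep_fraction`` subsamples bin pairs uniformly (emulating finite
    sequencing depth); class-mean statistics are unbiased under it.
    ``norm_nan_fraction`` masks a fraction of normalization-vector
    entries with NaN to exercise the loader's dropping logic.
    """

    bin_size: int = 10_000
    decay_exponent: float = 1.0
    homotypic_boost: float = 2.0
    band: tuple[int, int] = (10_000_000, 50_000_000)
    noise_cv: float = 0.2
    amplitude: float = 100.0
    keep_fraction: float = 1.0
    norm_nan_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.homotypic_boost < 1:
            raise ValueError("homotypic_boost must be >= 1")
        if self.band[0] >= self.band[1]:
            raise ValueError("band minimum must be below band maximum")
        if not (0 < self.keep_fraction <= 1):
            raise ValueError("keep_fraction must be in (0, 1]")
        if not (0 <= self.norm_nan_fraction < 1):
            raise ValueError("norm_nan_fraction must be in [0, 1)")


@dataclass
class SimulatedHiC:
    """One chromosome of simulated contacts plus ground truth.

    ``triplets`` columns: bin_i, bin_j (bin start bp, bin_i <= bin_j),
    raw (count after un-normalization) and normalized (the intended
    normalized frequency, kept for closed-loop testing).  ``norm_vector``
    carries NaN at masked bins; ``norm_vector_full`` is the unmasked
    vector actually used to build raw counts.
    """

    chrom: str
    bin_size: int
    triplets: pd.DataFrame
    norm_vector: np.ndarray
    norm_vector_full: np.ndarray
    bin_is_nad: np.ndarray

    def write_triplets(self, path) -> None:
        self.triplets[["bin_i", "bin_j", "raw"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def write_norm_vector(self, path) -> None:
        with open(path, "w") as fh:
            for v in self.norm_vector:
                fh.write("NaN\n" if np.isnan(v) else f"{v:.10g}\n")


def simulate_hic(
    truth: TruthSegmentation, params: HiCSimParams, chrom: str | None = None
) -> SimulatedHiC:
    """Simulate normalized + raw intrachromosomal contacts for one chromosome."""
    if chrom is None:
        chrom = truth.layout.chromosomes[0]
    length = truth.layout.lengths[chrom]
    n_bins = length // params.bin_size
    if n_bins < 4:
        raise ValueError(f"{chrom}: chromosome too short for bin size {params.bin_size}")
    if params.band[0] >= length:
        warnings.warn(
            f"{chrom}: boost band {params.band} lies outside the chromosome span",
            stacklevel=2,
        )
    rng = np.random.default_rng(params.seed)

    nad_iv = truth.domains.nads().intervals(chrom)
    cov = coverage_in_bins(nad_iv, params.bin_size, n_bins)
    bin_is_nad = cov * 2 >= params.bin_size  # majority rule, tie -> NAD

    v_full = rng.uniform(0.5, 2.0, size=n_bins)
    v_masked = v_full.copy()
    n_nan = int(round(params.norm_nan_fraction * n_bins))
    if n_nan:
        v_masked[rng.choice(n_bins, size=n_nan, replace=False)] = np.nan

    sigma = float(np.sqrt(np.log1p(params.noise_cv**2)))
    chunks = []
    chunk_rows = 512
    for i0 in range(0, n_bins - 1, chunk_rows):
        i1 = min(i0 + chunk_rows, n_bins - 1)
        i_idx, j_idx = [], []
        for i in range(i0, i1):
            j = np.arange(i + 1, n_bins)
            if params.keep_fraction < 1.0:
                j = j[rng.random(len(j)) < params.keep_fraction]
            i_idx.append(np.full(len(j), i, dtype=np.int64))
            j_idx.append(j.astype(np.int64))
        if not i_idx:
            continue
        i_arr = np.concatenate(i_idx)
        j_arr = np.concatenate(j_idx)
        d_bins = j_arr - i_arr
        expected = params.amplitude * d_bins.astype(float) ** (-params.decay_exponent)
        d_bp = d_bins * params.bin_size
        boosted = (
            bin_is_nad[i_arr]
            & bin_is_nad[j_arr]
            & (d_bp >= params.band[0])
            & (d_bp < params.band[1])
        )
        expected = np.where(boosted, expected * params.homotypic_boost, expected)
        noise = np.exp(sigma * rng.standard_normal(len(expected)) - sigma**2 / 2)
        normalized = expected * noise
        raw = normalized * v_full[i_arr] * v_full[j_arr]
        chunks.append(
            pd.DataFrame(
                {
                    "bin_i": i_arr * params.bin_size,
                    "bin_j": j_arr * params.bin_size,
                    "raw": raw,
                    "normalized": normalized,
                }
            )
        )
    triplets = pd.concat(chunks, ignore_index=True)
    return SimulatedHiC(
        chrom=chrom,
        bin_size=params.bin_size,
        triplets=triplets,
        norm_vector=v_masked,
        norm_vector_full=v_full,
        bin_is_nad=bin_is_nad,
    )
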