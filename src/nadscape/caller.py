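"""NAD calling from nucleolar/background tiling-array tracks.

Pipeline, in the order the stages are meant to run:

1. :func:`quantile_normalize` raw probe intensities across samples;
2. :func:`compute_enrichment` — per-probe log2 nucleolar-over-background
   ratio E (the background may be genomic input or the non-nucleolar
   supernatant; both are interchangeable denominators);
3. :func:`smooth_sliding_median` — sliding medians in 100 kb windows,
   per sample, per chromosome;
4. :func:`average_replicates` across replicates of a condition;
5. :func:`fit_two_state_hmm` — two-state Gaussian-emission HMM on the
   smoothed averaged track (the genome-wide E distribution is bimodal);
6. :func:`call_domains` — Viterbi decoding into NAD/iNAD intervals with
   a 10 kb minimum NAD length; the mean E within each domain is its
   NAD score;
7. :func:`differential_domains` — set algebra between two conditions
   (young-only, senescent-only, constitutive NAD regions).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor

from . import intervals as iv
from .regions import INAD, NAD, DomainSet
from .tracks import EnrichmentTrack, ProbeTrack


class DegenerateFitError(RuntimeError):
    """Raised when the HMM collapses to one state or a zero-variance state."""


@dataclass
class TwoStateHMM:
    """Fitted two-state Gaussian HMM; state 0 is NAD (larger mean)."""

    transmat: np.ndarray
    means: np.ndarray  # (mu_NAD, mu_iNAD)
    sds: np.ndarray
    startprob: np.ndarray
    log_likelihoods: list[float] = field(default_factory=list)
    converged: bool = False
    _model: GaussianHMM | None = None
    _order: np.ndarray | None = None  # raw-state index of (NAD, iNAD)

    def __post_init__(self) -> None:
        if self.means[0] < self.means[1]:
            raise ValueError("labeling convention requires mu_NAD >= mu_iNAD")
        if np.any(self.sds <= 0):
            raise ValueError("emission sds must be positive")
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")

    def decode(self, values: np.ndarray) -> np.ndarray:
        """Viterbi path for one chromosome; True where the NAD state wins."""
        raw = self._model.predict(np.asarray(values, dtype=float).reshape(-1, 1))
        return raw == self._order[0]


class _HistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that records the full log-likelihood trajectory."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)


def quantile_normalize(track: ProbeTrack) -> ProbeTrack:
    """Force every sample column onto the mean order-statistic distribution.

    After normalization all columns share an identical multiset of
    values (the across-sample mean of order statistics); the rank order
    within each column is preserved.
    """
    values = track.values()
    if values.shape[1] == 1:
        return track.with_values(values.copy())
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[order[:, j], j] = reference
    return track.with_values(out)


def compute_enrichment(
    nucleolar: ProbeTrack, background: ProbeTrack
) -> tuple[EnrichmentTrack, dict]:
    """Per-probe E = log2(nucleolar) − log2(background), per replicate.

    Probes with a non-positive intensity in any sample are masked out;
    the returned report counts them.  Tracks already in log space
    (``log_space=True``) are subtracted directly.
    """
    if not nucleolar.same_grid(background):
        raise ValueError("nucleolar and background tracks are on different probe grids")
    if len(nucleolar.samples) != len(background.samples):
        raise ValueError("sample counts differ between channels")
    nuc = nucleolar.values()
    bg = background.values()
    if nucleolar.log_space != background.log_space:
        raise ValueError("channels must agree on linear vs log space")
    if nucleolar.log_space:
        enrich = nuc - bg
        bad = ~np.isfinite(enrich).all(axis=1)
    else:
        positive = (nuc > 0) & (bg > 0)
        bad = ~positive.all(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            enrich = np.log2(nuc) - np.log2(bg)
    keep = ~bad
    frame = nucleolar.frame.loc[keep, ["chrom", "pos"]].copy()
    samples = [f"E_{s}" for s in nucleolar.samples]
    frame[samples] = enrich[keep]
    report = {"masked_probes": int(bad.sum()), "retained_probes": int(keep.sum())}
    return EnrichmentTrack(frame, samples), report


def _sliding_median(positions: np.ndarray, column: np.ndarray, half: float) -> np.ndarray:
    lo = np.searchsorted(positions, positions - half, side="left")
    hi = np.searchsorted(positions, positions + half, side="right")
    widths = hi - lo
    out = np.empty(len(column), dtype=float)
    # fast path: most probes share the full (interior) window width
    w = int(widths.max())
    interior = widths == w
    if w <= len(column) and interior.sum() > len(column) // 2:
        windows = np.lib.stride_tricks.sliding_window_view(column, w)
        # probe p's full window starts at lo[p]
        out[interior] = np.median(windows[lo[interior]], axis=1)
        edges = np.nonzero(~interior)[0]
    else:
        edges = np.arange(len(column))
    for p in edges:
        out[p] = np.median(column[lo[p] : hi[p]])
    return out


def smooth_sliding_median(track: EnrichmentTrack, window: int = 100_000) -> EnrichmentTrack:
    """Sliding-median smoothing in bp windows centered on each probe.

    The window at probe p covers probes within ``window / 2`` bp of p's
    position; at chromosome edges the truncated window is used.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    half = window / 2
    values = track.values().copy()
    for chrom in track.chromosomes():
        sel = (track.frame["chrom"] == chrom).to_numpy()
        pos = track.frame.loc[sel, "pos"].to_numpy(dtype=float)
        for j in range(values.shape[1]):
            values[sel, j] = _sliding_median(pos, values[sel, j], half)
    return track.with_values(values)


def average_replicates(tracks: list[EnrichmentTrack]) -> EnrichmentTrack:
    """Arithmetic per-probe mean over replicate tracks (or columns)."""
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    mats = []
    for t in tracks:
        if len(t) != len(first) or not (
            t.frame[["chrom", "pos"]].to_numpy() == first.frame[["chrom", "pos"]].to_numpy()
        ).all():
            raise ValueError("replicate tracks are on different probe grids")
        mats.append(t.values())
    stacked = np.concatenate(mats, axis=1)
    frame = first.frame[["chrom", "pos"]].copy()
    frame["E"] = stacked.mean(axis=1)
    return EnrichmentTrack(frame, ["E"])


def _init_model(
    values: np.ndarray, lo_q: float, hi_q: float, tol: float, max_iter: int
) -> GaussianHMM:
    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        n_iter=max_iter,
        tol=tol,
        init_params="",
        params="stmc",
        random_state=0,
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.99, 0.01], [0.01, 0.99]])
    mu_hi = np.quantile(values, hi_q)
    mu_lo = np.quantile(values, lo_q)
    if mu_hi <= mu_lo:
        mu_hi = mu_lo + 1e-3
    model.means_ = np.array([[mu_lo], [mu_hi]])
    var = max(float(values.var()) / 4.0, 1e-6)
    model.covars_ = np.array([[var], [var]])
    model.monitor_ = _HistoryMonitor(model.tol, model.n_iter, False)
    return model


def fit_two_state_hmm(
    track: EnrichmentTrack,
    tol: float = 1e-3,
    max_iter: int = 200,
    seed: int = 0,
    max_restarts: int = 3,
    min_sd: float = 1e-4,
) -> TwoStateHMM:
    """Baum–Welch fit of a two-state Gaussian HMM on the enrichment track.

    Chromosomes are treated as independent sequences (no transitions
    across boundaries).  Initialization is deterministic: emission means
    at the 25th/75th percentiles of the smoothed E values, equal
    variances, sticky symmetric transitions (0.99 self).  The state with
    the larger fitted mean is labeled NAD.  A degenerate fit (collapsed
    variance or a state never visited by Viterbi) triggers restarts from
    wider percentile pairs, then :class:`DegenerateFitError`.
    """
    values = track.values()
    if values.shape[1] != 1:
        raise ValueError("fit on a single (replicate-averaged) value column")
    flat = values[:, 0]
    if len(flat) < 100:
        warnings.warn(
            f"only {len(flat)} probes; HMM parameter estimates may be unstable",
            stacklevel=2,
        )
    lengths = [int(n) for n in track.frame.groupby("chrom", sort=False).size()]
    X = flat.reshape(-1, 1)

    percentile_pairs = [(0.25, 0.75), (0.10, 0.90), (0.40, 0.60), (0.05, 0.95)]
    last_error = None
    for attempt in range(min(max_restarts + 1, len(percentile_pairs))):
        lo_q, hi_q = percentile_pairs[attempt]
        model = _init_model(flat, lo_q, hi_q, tol, max_iter)
        hmm_log = logging.getLogger("hmmlearn.base")
        old_level = hmm_log.level
        hmm_log.setLevel(logging.ERROR)  # float-noise "not converging" chatter
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X, lengths)
        finally:
            hmm_log.setLevel(old_level)
        sds = np.sqrt(model.covars_.reshape(-1))
        path = model.predict(X, lengths)
        used = np.bincount(path, minlength=2)
        if np.any(sds < min_sd) or np.any(used == 0):
            last_error = DegenerateFitError(
                f"degenerate fit on attempt {attempt + 1}: sds={sds}, "
                f"state occupancy={used}"
            )
            continue
        order = np.argsort(model.means_.reshape(-1))[::-1]  # NAD first
        history = list(model.monitor_.full_history)
        return TwoStateHMM(
            transmat=model.transmat_[np.ix_(order, order)],
            means=model.means_.reshape(-1)[order],
            sds=sds[order],
            startprob=model.startprob_[order],
            log_likelihoods=history,
            converged=bool(model.monitor_.converged),
            _model=model,
            _order=order,
        )
    raise last_error


def call_domains(
    track: EnrichmentTrack, model: TwoStateHMM, min_len: int = 10_000
) -> DomainSet:
    """Viterbi segmentation of the track into scored NAD/iNAD intervals.

    Consecutive same-state probes merge into intervals whose boundaries
    sit at the first probe position of the next segment (chromosome ends
    extend by one probe spacing).  NAD intervals shorter than ``min_len``
    are relabeled iNAD and merged with their neighbors.  Each interval's
    score is the mean (smoothed) E of its probes.
    """
    spacing = int(round(track.probe_spacing()))
    rows = []
    for chrom in track.chromosomes():
        grp = track.chrom_slice(chrom)
        if len(grp) < 2:
            warnings.warn(f"{chrom}: fewer than 2 probes, skipped", stacklevel=2)
            continue
        pos = grp["pos"].to_numpy(dtype=np.int64)
        vals = grp[track.samples[0]].to_numpy(dtype=float)
        is_nad = model.decode(vals)

        change = np.nonzero(np.diff(is_nad.astype(np.int8)))[0]
        seg_first = np.concatenate([[0], change + 1])
        seg_last = np.concatenate([change, [len(pos) - 1]])
        starts = pos[seg_first]
        ends = np.concatenate([pos[seg_first[1:]], [pos[-1] + spacing]])
        labels = [NAD if is_nad[i] else INAD for i in seg_first]

        # enforce minimum NAD length by relabeling short NADs as iNAD
        for k in range(len(labels)):
            if labels[k] == NAD and ends[k] - starts[k] < min_len:
                labels[k] = INAD
        # merge consecutive same-label segments, scoring by probe means
        merged: list[list] = []
        for k in range(len(labels)):
            if merged and merged[-1][2] == labels[k]:
                merged[-1][1] = ends[k]
            else:
                merged.append([int(starts[k]), int(ends[k]), labels[k]])
        for s, e, lab in merged:
            in_seg = (pos >= s) & (pos < e)
            score = float(vals[in_seg].mean()) if in_seg.any() else np.nan
            rows.append((chrom, s, e, lab, score))
    return DomainSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "score"]))


@dataclass
class DifferentialDomains:
    """Young-only (¬S), senescent-only (¬Y) and constitutive (Y∧S) NADs."""

    young_only: DomainSet
    senescent_only: DomainSet
    constitutive: DomainSet

    @property
    def totals_bp(self) -> dict[str, int]:
        return {
            "young_only": self.young_only.total_bp(),
            "senescent_only": self.senescent_only.total_bp(),
            "constitutive": self.constitutive.total_bp(),
        }


def differential_domains(young: DomainSet, senescent: DomainSet) -> DifferentialDomains:
    """Bp-level set algebra between two conditions' NAD sets."""
    y_chroms = set(young.nads().chromosomes())
    s_chroms = set(senescent.nads().chromosomes())
    chroms = sorted(y_chroms | s_chroms)
    y_only, s_only, const = {}, {}, {}
    for chrom in chroms:
        y = young.nads().intervals(chrom)
        s = senescent.nads().intervals(chrom)
        y_only[chrom] = iv.subtract(y, s)
        s_only[chrom] = iv.subtract(s, y)
        const[chrom] = iv.intersect(y, s)
    return DifferentialDomains(
        young_only=DomainSet.from_intervals(y_only, NAD),
        senescent_only=DomainSet.from_intervals(s_only, NAD),
        constitutive=DomainSet.from_intervals(const, NAD),
    )
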