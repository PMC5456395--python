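"""Genomic synthetic data: domain truth, tiling-array signals, annotations.

The truth segmentation emulates a two-state (NAD / iNAD) partition of
each chromosome with exponentially distributed segment lengths — the
length law implied by a two-state Markov process.  Array signals are
drawn so that the per-probe log2 nucleolar-over-background enrichment is
Gaussian within each state, giving the bimodal genome-wide signal
distribution that motivates a two-state HMM segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..layout import GenomeLayout
from ..regions import INAD, NAD, DomainSet, FeatureSet, SignalTrack
from ..tracks import ProbeTrack

REPLISEQ_FRACTIONS = ["S1", "S2", "S3", "S4", "G2"]
# percentage-normalized replication signal by fraction: early-replicating
# profile outside NADs, late-replicating profile inside.
_EARLY_PROFILE = np.array([40.0, 30.0, 15.0, 10.0, 5.0])
_LATE_PROFILE = np.array([5.0, 10.0, 15.0, 30.0, 40.0])

CHROMATIN_STATES = ["TssA", "Tx", "Enh", "Het", "Quies"]
GENE_CLASSES = ["escaper", "heterogeneous", "inactive"]
CHANGE_CLASSES = ["constitutive", "young_only", "senescent_only"]


@dataclass(frozen=True)
class TruthSegmentation:
    """Ground-truth NAD/iNAD tiling of a genome layout."""

    layout: GenomeLayout
    domains: DomainSet

    def __post_init__(self) -> None:
        self.domains.check_tiles(self.layout)
        # labels must alternate within each chromosome
        for chrom in self.layout.chromosomes:
            labels = self.domains.frame.loc[
                self.domains.frame["chrom"] == chrom, "label"
            ].to_numpy()
            if any(labels[i] == labels[i + 1] for i in range(len(labels) - 1)):
                raise ValueError(f"{chrom}: truth labels do not alternate")

    def state_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean array: True where a position lies inside a NAD."""
        grp = self.domains.frame[self.domains.frame["chrom"] == chrom]
        starts = grp["start"].to_numpy()
        labels = (grp["label"] == NAD).to_numpy()
        idx = np.searchsorted(starts, positions, side="right") - 1
        if np.any(idx < 0):
            raise ValueError("position before chromosome start")
        return labels[idx]


@dataclass(frozen=True)
class EmissionParams:
    """Per-state Gaussian emission model for simulated array enrichment.

    Means and sds are in log2-ratio units.  ``background_log2_mean`` and
    ``background_log2_sd`` describe the (biologically uninformative)
    log2 intensity of the background channel; the nucleolar channel is
    background plus the state-dependent enrichment draw, so the log2
    difference is exactly the state's Gaussian.
    """

    mean_nad: float = 1.0
    mean_inad: float = -1.0
    sd_nad: float = 0.3
    sd_inad: float = 0.3
    probe_spacing: int = 1_000
    n_replicates: int = 2
    background_log2_mean: float = 10.0
    background_log2_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_nad < 0 or self.sd_inad < 0:
            raise ValueError("emission sds must be >= 0")
        if self.mean_nad <= self.mean_inad:
            raise ValueError("mean_nad must exceed mean_inad")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def simulate_domain_truth(
    layout: GenomeLayout,
    mean_nad_len: float = 400_000,
    mean_inad_len: float = 400_000,
    seed: int = 0,
) -> TruthSegmentation:
    """Tile each chromosome with alternating NAD/iNAD segments.

    Segment lengths are exponential with the stated means, truncated at
    chromosome ends; the first label of each chromosome is a fair coin
    flip.  Deterministic given ``seed``.
    """
    if mean_nad_len <= 0 or mean_inad_len <= 0:
        raise ValueError("mean segment lengths must be positive")
    rng = np.random.default_rng(seed)
    means = {NAD: mean_nad_len, INAD: mean_inad_len}
    rows = []
    for chrom, length in layout.lengths.items():
        label = NAD if rng.random() < 0.5 else INAD
        pos = 0
        while pos < length:
            seg = max(int(round(rng.exponential(means[label]))), 1)
            end = min(pos + seg, length)
            rows.append((chrom, pos, end, label, np.nan))
            pos = end
            label = INAD if label == NAD else NAD
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "score"])
    return TruthSegmentation(layout=layout, domains=DomainSet(frame))


def simulate_enrichment_arrays(
    truth: TruthSegmentation, params: EmissionParams
) -> tuple[ProbeTrack, ProbeTrack]:
    """Simulate nucleolar and background probe intensity tracks.

    Returns linear-scale intensity tracks (one column per replicate)
    whose per-probe log2 nucleolar-minus-background difference is an
    independent draw from the truth state's Gaussian.
    """
    min_seg = int(truth.domains.widths().min())
    if params.probe_spacing > min_seg:
        warnings.warn(
            f"probe spacing {params.probe_spacing} exceeds the smallest "
            f"segment ({min_seg} bp); some segments will contain no probe",
            stacklevel=2,
        )
    rng = np.random.default_rng(params.seed)
    chroms, positions, is_nad = [], [], []
    for chrom, length in truth.layout.lengths.items():
        pos = np.arange(params.probe_spacing // 2, length, params.probe_spacing)
        chroms.append(np.full(len(pos), chrom, dtype=object))
        positions.append(pos)
        is_nad.append(truth.state_at(chrom, pos))
    chrom_col = np.concatenate(chroms)
    pos_col = np.concatenate(positions)
    nad_col = np.concatenate(is_nad)
    n = len(pos_col)
    r = params.n_replicates

    mu = np.where(nad_col, params.mean_nad, params.mean_inad)[:, None]
    sd = np.where(nad_col, params.sd_nad, params.sd_inad)[:, None]
    enrichment = mu + sd * rng.standard_normal((n, r))
    background_log2 = params.background_log2_mean + params.background_log2_sd * (
        rng.standard_normal((n, r))
    )
    nucleolar_log2 = background_log2 + enrichment

    samples = [f"rep{i + 1}" for i in range(r)]
    base = pd.DataFrame({"chrom": chrom_col, "pos": pos_col})
    nucleolar = base.copy()
    nucleolar[samples] = 2.0**nucleolar_log2
    background = base.copy()
    background[samples] = 2.0**background_log2
    return (
        ProbeTrack(nucleolar, samples),
        ProbeTrack(background, samples),
    )


def _tile_positions(length: int, tile: int) -> np.ndarray:
    return np.arange(0, length, tile)


def simulate_annotation_tracks(
    truth: TruthSegmentation,
    seed: int = 0,
    *,
    state_tile: int = 25_000,
    het_prob_nad: float = 0.7,
    het_prob_inad: float = 0.2,
    repliseq_bin: int = 10_000,
    repliseq_noise_sd: float = 2.0,
    genes_per_mb: float = 10.0,
    fc_effect: float = 0.5,
    fc_noise_sd: float = 0.3,
) -> dict:
    """Generate annotation fixtures coupled to the truth segmentation.

    Returns a dict with keys:

    ``chromatin_states``
        :class:`FeatureSet` of a toy 5-state segmentation in which the
        heterochromatin state ("Het") occurs with probability
        ``het_prob_nad`` inside NADs and ``het_prob_inad`` outside.
        Setting the two probabilities equal yields the null (uncoupled)
        model.
    ``repliseq``
        List of five :class:`SignalTrack` objects (S1–S4, G2),
        percentage-normalized per bin, switching from an
        early-replicating profile outside NADs to a late-replicating one
        inside — a step exactly at every NAD border.
    ``genes``
        :class:`FeatureSet` of genes with an activity class label
        (escaper / heterogeneous / inactive) whose distribution is
        coupled to the domain state (inactive genes favour NADs).
    ``fold_changes``
        Per-gene table with a ground-truth domain-change class
        (constitutive / young_only / senescent_only) and a log2
        fold-change whose sign couples to the class: loss of nucleolus
        association (young_only) drives activation (+``fc_effect``),
        gain drives repression (−``fc_effect``).  ``fc_effect = 0``
        yields the null model.
    """
    rng = np.random.default_rng(seed)

    # --- chromatin states -------------------------------------------------
    other_states = [s for s in CHROMATIN_STATES if s != "Het"]
    state_rows = []
    for chrom, length in truth.layout.lengths.items():
        starts = _tile_positions(length, state_tile)
        ends = np.minimum(starts + state_tile, length)
        mids = (starts + ends) // 2
        in_nad = truth.state_at(chrom, mids)
        p_het = np.where(in_nad, het_prob_nad, het_prob_inad)
        draws = rng.random(len(starts))
        other_idx = rng.integers(0, len(other_states), size=len(starts))
        for s, e, het, oi in zip(starts, ends, draws < p_het, other_idx):
            state = "Het" if het else other_states[oi]
            state_rows.append((chrom, int(s), int(e), state, state))
    chromatin = FeatureSet(
        pd.DataFrame(
            state_rows, columns=["chrom", "start", "end", "name", "feature_class"]
        )
    )

    # --- replication timing ----------------------------------------------
    frac_frames: dict[str, list] = {f: [] for f in REPLISEQ_FRACTIONS}
    for chrom, length in truth.layout.lengths.items():
        starts = _tile_positions(length, repliseq_bin)
        ends = np.minimum(starts + repliseq_bin, length)
        mids = (starts + ends) // 2
        in_nad = truth.state_at(chrom, mids)
        base = np.where(in_nad[:, None], _LATE_PROFILE, _EARLY_PROFILE)
        noisy = np.clip(base + repliseq_noise_sd * rng.standard_normal(base.shape), 0, None)
        noisy = 100.0 * noisy / noisy.sum(axis=1, keepdims=True)
        for k, frac in enumerate(REPLISEQ_FRACTIONS):
            frac_frames[frac].append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "value": noisy[:, k]}
                )
            )
    repliseq = [
        SignalTrack(pd.concat(frac_frames[f], ignore_index=True), name=f)
        for f in REPLISEQ_FRACTIONS
    ]

    # --- genes ------------------------------------------------------------
    gene_rows = []
    gid = 0
    for chrom, length in truth.layout.lengths.items():
        n_genes = int(round(genes_per_mb * length / 1e6))
        starts = rng.integers(0, max(length - 5_000, 1), size=n_genes)
        lens = rng.integers(5_000, 100_000, size=n_genes)
        ends = np.minimum(starts + lens, length)
        mids = (starts + ends) // 2
        in_nad = truth.state_at(chrom, mids)
        for s, e, nad in zip(starts, ends, in_nad):
            probs = [0.1, 0.3, 0.6] if nad else [0.6, 0.3, 0.1]
            cls = GENE_CLASSES[rng.choice(3, p=probs)]
            gene_rows.append((chrom, int(s), int(e), f"gene{gid}", cls))
            gid += 1
    genes = FeatureSet(
        pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name", "feature_class"])
    )

    # --- expression fold-changes by domain-change class -------------------
    n_genes_total = len(genes)
    change = rng.choice(3, size=n_genes_total, p=[0.8, 0.1, 0.1])
    effect = np.select(
        [change == 1, change == 2], [fc_effect, -fc_effect], default=0.0
    )
    log2fc = effect + fc_noise_sd * rng.standard_normal(n_genes_total)
    fold_changes = pd.DataFrame(
        {
            "name": genes.frame["name"].to_numpy(),
            "change_class": np.asarray(CHANGE_CLASSES, dtype=object)[change],
            "log2fc": log2fc,
        }
    )

    return {
        "chromatin_states": chromatin,
        "repliseq": repliseq,
        "genes": genes,
        "fold_changes": fold_changes,
    }
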