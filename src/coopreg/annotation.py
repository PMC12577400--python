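"""Active-element filtering of TF peaks, nearest-TSS target assignment, and
anchor-centered signal metaprofiles."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome import GeneModel, GenomicInterval, SignalTrack, intersect_many, nearest_tss

__all__ = [
    "ActivePeakSet",
    "PeakTargetMap",
    "Metaprofile",
    "filter_active",
    "assign_targets",
    "metaprofile",
]

logger = logging.getLogger(__name__)


@dataclass
class ActivePeakSet:
    """TF peaks retained as active elements, with per-peak evidence flags."""

    peaks: list[GenomicInterval]
    evidence: list[tuple[bool, bool]]  # (h3k27ac, polII), parallel to peaks
    filter_mode: str
    n_input: int

    @property
    def retained_fraction(self) -> float:
        return len(self.peaks) / self.n_input


@dataclass
class PeakTargetMap:
    """Per-peak nearest-TSS assignment and its per-gene inversion."""

    assignments: list[tuple[GenomicInterval, Optional[str], Optional[int]]]
    gene_to_peaks: dict[str, list[GenomicInterval]]

    @property
    def target_genes(self) -> set[str]:
        return set(self.gene_to_peaks)

    @property
    def n_unassigned(self) -> int:
        return sum(1 for _, g, _ in self.assignments if g is None)


@dataclass
class Metaprofile:
    """Mean signal around a set of anchors, resampled to an odd number of bins."""

    offsets: np.ndarray  # bin-center offsets in bp relative to the anchor
    mean_signal: np.ndarray
    n_anchors: int
    window: int
    matrix: Optional[np.ndarray] = None

    @property
    def n_bins(self) -> int:
        return len(self.mean_signal)


def filter_active(
    tf_peaks: Sequence[GenomicInterval],
    h3k27ac_peaks: Sequence[GenomicInterval],
    polII_peaks: Sequence[GenomicInterval],
    mode: str = "AND",
) -> ActivePeakSet:
    """Refine TF peaks to active elements carrying H3K27ac and RNA-PolII evidence.

    A peak is retained iff it overlaps (>= 1 bp) an H3K27ac peak AND/OR a
    PolII peak; the default conjunction is the natural reading of "active".
    Evidence flags are recorded for every input peak either way.
    """
    if not tf_peaks:
        raise ValueError("empty TF peak set")
    if mode not in ("AND", "OR"):
        raise ValueError(f"mode must be AND or OR, got {mode!r}")
    k27_hits = intersect_many(tf_peaks, h3k27ac_peaks)
    pol_hits = intersect_many(tf_peaks, polII_peaks)
    kept: list[GenomicInterval] = []
    evidence: list[tuple[bool, bool]] = []
    for peak, k27, pol in zip(tf_peaks, k27_hits, pol_hits):
        has_k27, has_pol = bool(k27), bool(pol)
        ok = (has_k27 and has_pol) if mode == "AND" else (has_k27 or has_pol)
        if ok:
            kept.append(peak)
            evidence.append((has_k27, has_pol))
    logger.info(
        "filter_active(%s): retained %d/%d peaks", mode, len(kept), len(tf_peaks)
    )
    return ActivePeakSet(kept, evidence, mode, n_input=len(tf_peaks))


def assign_targets(
    peaks: Sequence[GenomicInterval] | ActivePeakSet,
    genes: Sequence[GeneModel],
    max_distance: Optional[int] = None,
    anchor: str = "midpoint",
) -> PeakTargetMap:
    """Assign each peak to its nearest-TSS gene; genes with >= 1 peak form the
    ChIP target-gene set.

    Assignments farther than ``max_distance`` (absolute bp) are dropped to
    unassigned when the cap is set. Peaks on chromosomes without genes are
    reported unassigned, never raised.
    """
    if isinstance(peaks, ActivePeakSet):
        peaks = peaks.peaks
    if not genes:
        raise ValueError("gene list is empty")
    assignments: list[tuple[GenomicInterval, Optional[str], Optional[int]]] = []
    gene_to_peaks: dict[str, list[GenomicInterval]] = {}
    for peak in peaks:
        gene_id, dist = nearest_tss(peak, genes, anchor=anchor)
        if gene_id is not None and max_distance is not None and abs(dist) > max_distance:
            gene_id, dist = None, None
        assignments.append((peak, gene_id, dist))
        if gene_id is not None:
            gene_to_peaks.setdefault(gene_id, []).append(peak)
    return PeakTargetMap(assignments, gene_to_peaks)


def _symmetric_chunk_edges(length: int, n_bins: int) -> np.ndarray:
    """Split points for ``n_bins`` chunks whose size pattern is mirror-symmetric
    about the central bin, so minus-strand reversal maps chunks onto chunks."""
    sizes = np.full(n_bins, length // n_bins)
    extra = length % n_bins
    center = n_bins // 2
    if extra % 2 == 1:
        sizes[center] += 1
        extra -= 1
    step = 1
    while extra > 0:
        sizes[center - step] += 1
        sizes[center + step] += 1
        extra -= 2
        step += 1
    return np.cumsum(sizes)[:-1]


def metaprofile(
    signal: SignalTrack,
    anchors: Sequence[tuple[str, int, str]],
    window: int,
    n_bins: int = 101,
    keep_matrix: bool = False,
) -> Metaprofile:
    """Average signal in ``[pos - window, pos + window]`` over anchors.

    Each anchor is a (chrom, position, strand) triple; the +/- window is split
    into ``n_bins`` (odd, so the anchor bin is central) near-equal bp chunks
    averaged within each chunk. Minus-strand anchors are flipped before
    averaging so profiles are 5'->3' oriented. Positions outside the
    chromosome are dropped (not padded); anchors with no usable signal are
    skipped, and zero usable anchors is an error.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if n_bins < 1 or n_bins % 2 == 0:
        raise ValueError("n_bins must be odd and positive")

    offsets = np.arange(-window, window + 1)
    edges = _symmetric_chunk_edges(len(offsets), n_bins)
    rows: list[np.ndarray] = []
    for chrom, pos, strand in anchors:
        vec = signal.data.get(chrom)
        if vec is None:
            continue
        limit = len(vec) * signal.bin_size
        positions = pos + offsets
        valid = (positions >= 0) & (positions < limit)
        if not valid.any():
            continue
        values = np.full(len(positions), np.nan)
        values[valid] = vec[positions[valid] // signal.bin_size]
        if strand == "-":
            values = values[::-1]
        chunks = np.split(values, edges)
        with np.errstate(invalid="ignore"):
            row = np.array([np.nanmean(c) if np.isfinite(c).any() else np.nan for c in chunks])
        if np.isfinite(row).any():
            rows.append(row)
    if not rows:
        raise ValueError("zero usable anchors")

    matrix = np.vstack(rows)
    mean = np.nanmean(matrix, axis=0)
    bin_centers = np.array([c.mean() for c in np.split(offsets, edges)])
    return Metaprofile(
        offsets=bin_centers,
        mean_signal=mean,
        n_anchors=len(rows),
        window=window,
        matrix=matrix if keep_matrix else None,
    )
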