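"""ChromHMM-style chromatin-state model: a K-state HMM over M binarized marks.

Each state emits a product of independent Bernoulli variables, one per mark
(the standard multivariate-Bernoulli emission model for chromatin
segmentation). Learning is plain Baum-Welch EM with scaled forward-backward;
decoding is per-bin posterior argmax (Viterbi behind a flag), and segmentation
coverage of a peak set is computed per base pair.
"""

from __future__ import annotations

import json
import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import poisson

from .genome import Genome, GenomicInterval, SignalTrack

__all__ = [
    "BinarizedTracks",
    "ChromatinStateModel",
    "Segmentation",
    "StateCoverageProfile",
    "poisson_threshold",
    "binarize",
    "binarize_tracks",
    "fit_hmm",
    "posterior_marginals",
    "decode",
    "state_coverage",
    "group_states",
    "match_states",
]

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-6


@dataclass
class BinarizedTracks:
    """Ordered mark names plus one (n_bins x M) 0/1 matrix per chromosome."""

    marks: list[str]
    data: dict[str, np.ndarray]
    bin_size: int = 200

    def __post_init__(self) -> None:
        m = len(self.marks)
        clean = {}
        for chrom, mat in self.data.items():
            mat = np.asarray(mat, dtype=np.uint8)
            if mat.ndim != 2 or mat.shape[1] != m:
                raise ValueError(f"{chrom}: expected (n_bins, {m}) matrix, got {mat.shape}")
            if not np.isin(mat, (0, 1)).all():
                raise ValueError(f"{chrom}: binarized entries must be 0/1")
            clean[chrom] = mat
        self.data = clean

    @property
    def n_marks(self) -> int:
        return len(self.marks)


@dataclass
class ChromatinStateModel:
    """Initial/transition probabilities and per-state Bernoulli emission rates."""

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray
    mark_names: list[str]
    log_likelihood_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        k = self.n_states
        if self.transition.shape != (k, k):
            raise ValueError("transition matrix shape mismatch")
        if self.emission.shape != (k, len(self.mark_names)):
            raise ValueError("emission matrix shape mismatch")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial probabilities must sum to 1")
        if np.abs(self.transition.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("transition rows must sum to 1")
        if ((self.emission < 0) | (self.emission > 1)).any():
            raise ValueError("emission probabilities must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return len(self.initial)

    @property
    def n_marks(self) -> int:
        return len(self.mark_names)

    @property
    def state_labels(self) -> list[str]:
        return [f"E{i + 1}" for i in range(self.n_states)]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_states": self.n_states,
            "mark_names": self.mark_names,
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "emission": self.emission.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ChromatinStateModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            initial=np.array(doc["initial"]),
            transition=np.array(doc["transition"]),
            emission=np.array(doc["emission"]),
            mark_names=list(doc["mark_names"]),
        )


@dataclass
class Segmentation:
    """Exhaustive run-length state labelling: chrom -> [(start, end, label), ...].

    Runs tile each chromosome without gaps or overlaps; boundaries are bin
    multiples except the final chromosome end.
    """

    runs: dict[str, list[tuple[int, int, str]]]
    state_labels: list[str]

    def __post_init__(self) -> None:
        for chrom, runs in self.runs.items():
            prev_end = 0
            for start, end, _label in runs:
                if start != prev_end:
                    raise ValueError(f"{chrom}: segmentation has a gap/overlap at {start}")
                if end <= start:
                    raise ValueError(f"{chrom}: empty run at {start}")
                prev_end = end

    def chrom_length(self, chrom: str) -> int:
        return self.runs[chrom][-1][1]

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_length(c) for c in self.runs)

    def to_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(chrom, start, end, name=label)
            for chrom, runs in self.runs.items()
            for start, end, label in runs
        ]

    @classmethod
    def from_intervals(cls, intervals: Sequence[GenomicInterval]) -> "Segmentation":
        runs: dict[str, list[tuple[int, int, str]]] = {}
        labels: list[str] = []
        for iv in intervals:
            runs.setdefault(iv.chrom, []).append((iv.start, iv.end, str(iv.name)))
            if iv.name not in labels:
                labels.append(str(iv.name))
        for chrom in runs:
            runs[chrom].sort()
        return cls(runs, labels)


@dataclass
class StateCoverageProfile:
    """Fraction of peak-set bp per state, with the genome-wide baseline."""

    fractions: dict[str, float]
    total_peak_bp: int
    genome_fraction: dict[str, float]


# ---------------------------------------------------------------------------
# binarization


def poisson_threshold(mean_rate: float, p_threshold: float) -> int:
    """Smallest count k with P(X >= k) < p_threshold under Poisson(mean_rate)."""
    if p_threshold >= 1.0:
        return 0
    k = int(mean_rate)
    while poisson.sf(k - 1, mean_rate) >= p_threshold:
        k += 1
    return k


def binarize(track: SignalTrack, p_threshold: float = 1e-4) -> dict[str, np.ndarray]:
    """ChromHMM-style binarization against the track's genome-wide mean rate.

    A bin is called present (1) when its count reaches the Poisson upper-tail
    threshold at ``p_threshold`` for the mark's global mean; no local control
    track is used.
    """
    total = sum(v.sum() for v in track.data.values())
    n = sum(len(v) for v in track.data.values())
    if total == 0:
        logger.warning("all-zero track: binarization yields all zeros")
        return {c: np.zeros(len(v), dtype=np.uint8) for c, v in track.data.items()}
    thresh = poisson_threshold(total / n, p_threshold)
    return {c: (v >= thresh).astype(np.uint8) for c, v in track.data.items()}


def binarize_tracks(
    tracks: dict[str, SignalTrack], p_threshold: float = 1e-4
) -> BinarizedTracks:
    marks = list(tracks)
    bin_size = next(iter(tracks.values())).bin_size
    per_mark = {m: binarize(tracks[m], p_threshold) for m in marks}
    chroms = next(iter(per_mark.values())).keys()
    data = {c: np.column_stack([per_mark[m][c] for m in marks]) for c in chroms}
    return BinarizedTracks(marks, data, bin_size=bin_size)


# ---------------------------------------------------------------------------
# EM (Baum-Welch) for the product-Bernoulli HMM


def _emission_log_prob(emission: np.ndarray, x: np.ndarray) -> np.ndarray:
    """(n, K) log P(x_t | state k) for a 0/1 observation matrix x of shape (n, M)."""
    e = np.clip(emission, _PROB_FLOOR, 1 - _PROB_FLOOR)
    return x @ np.log(e).T + (1 - x) @ np.log(1 - e).T


def _forward_backward(
    initial: np.ndarray, transition: np.ndarray, log_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward. Returns (gamma, xi_sum, log_likelihood)."""
    n, k = log_b.shape
    b = np.exp(log_b - log_b.max(axis=1, keepdims=True))
    alpha = np.empty((n, k))
    beta = np.empty((n, k))
    scale = np.empty(n)

    alpha[0] = initial * b[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ transition) * b[t]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]

    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (transition @ (b[t + 1] * beta[t + 1])) / scale[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi_sum = np.zeros((k, k))
    for t in range(n - 1):
        xi = transition * np.outer(alpha[t], b[t + 1] * beta[t + 1]) / scale[t + 1]
        xi_sum += xi

    loglik = float(np.log(scale).sum() + log_b.max(axis=1).sum())
    return gamma, xi_sum, loglik


def _floor_and_normalize(mat: np.ndarray) -> np.ndarray:
    mat = np.maximum(mat, _PROB_FLOOR)
    return mat / mat.sum(axis=-1, keepdims=True)


def fit_hmm(
    tracks: BinarizedTracks,
    K: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> ChromatinStateModel:
    """Learn a K-state product-Bernoulli HMM by Baum-Welch EM.

    Chromosomes are treated as independent sequences. Initialization is
    seeded: emissions drawn uniform(0.2, 0.8), transitions sticky (0.9 self).
    Stops when the per-bin log-likelihood improves by less than ``tol``.
    The fitted model records its log-likelihood trajectory, which is
    non-decreasing by the EM guarantee.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    seqs = [tracks.data[c].astype(float) for c in tracks.data]
    n_total = sum(len(s) for s in seqs)
    m = tracks.n_marks
    n_combos = len({tuple(row) for s in seqs for row in s.astype(int)})
    if K > n_combos:
        logger.warning(
            "K=%d exceeds the %d distinct observed mark combinations; states may collapse",
            K, n_combos,
        )

    rng = np.random.default_rng(seed)
    emission = rng.uniform(0.2, 0.8, size=(K, m))
    transition = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(transition, 0.9 if K > 1 else 1.0)
    transition = _floor_and_normalize(transition)
    initial = np.full(K, 1.0 / K)

    history: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        gamma_first = np.zeros(K)
        xi_total = np.zeros((K, K))
        occ = np.zeros(K)
        emit_num = np.zeros((K, m))
        loglik = 0.0
        for x in seqs:
            log_b = _emission_log_prob(emission, x)
            gamma, xi_sum, ll = _forward_backward(initial, transition, log_b)
            loglik += ll
            gamma_first += gamma[0]
            xi_total += xi_sum
            occ += gamma.sum(axis=0)
            emit_num += gamma.T @ x
        history.append(loglik)

        initial = _floor_and_normalize(gamma_first / len(seqs))
        if K > 1:
            transition = _floor_and_normalize(xi_total)
        emission = np.clip(emit_num / occ[:, None], _PROB_FLOOR, 1 - _PROB_FLOOR)

        if (loglik - prev) / n_total < tol and np.isfinite(prev):
            break
        prev = loglik

    return ChromatinStateModel(
        initial=initial,
        transition=transition,
        emission=emission,
        mark_names=list(tracks.marks),
        log_likelihood_history=history,
    )


def posterior_marginals(model: ChromatinStateModel, x: np.ndarray) -> np.ndarray:
    """(n, K) per-bin state posteriors for one chromosome's 0/1 matrix."""
    log_b = _emission_log_prob(model.emission, np.asarray(x, dtype=float))
    gamma, _, _ = _forward_backward(model.initial, model.transition, log_b)
    return gamma


def _viterbi(model: ChromatinStateModel, x: np.ndarray) -> np.ndarray:
    log_b = _emission_log_prob(model.emission, np.asarray(x, dtype=float))
    n, k = log_b.shape
    log_a = np.log(np.clip(model.transition, _PROB_FLOOR, 1))
    delta = np.log(np.clip(model.initial, _PROB_FLOOR, 1)) + log_b[0]
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + log_a
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + log_b[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def decode(
    model: ChromatinStateModel,
    tracks: BinarizedTracks,
    genome: Optional[Genome] = None,
    method: str = "posterior",
) -> Segmentation:
    """Label every bin with its most probable state and merge runs.

    Default is per-bin posterior argmax (forward-backward); ``method="viterbi"``
    gives the single best path instead. Ties break toward the lower state
    index. The final run of each chromosome is clipped to the true chromosome
    end when a genome is supplied.
    """
    if model.n_marks != tracks.n_marks or model.mark_names != tracks.marks:
        raise ValueError("model and tracks disagree on marks")
    labels = model.state_labels
    runs: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, x in tracks.data.items():
        if len(x) < 1:
            raise ValueError(f"{chrom}: chromosome shorter than one bin")
        if method == "posterior":
            states = posterior_marginals(model, x).argmax(axis=1)
        elif method == "viterbi":
            states = _viterbi(model, x)
        else:
            raise ValueError(f"unknown decode method {method!r}")
        limit = genome.chrom_lengths[chrom] if genome else len(x) * tracks.bin_size
        chrom_runs: list[tuple[int, int, str]] = []
        i = 0
        while i < len(states):
            j = i
            while j + 1 < len(states) and states[j + 1] == states[i]:
                j += 1
            start = i * tracks.bin_size
            end = min((j + 1) * tracks.bin_size, limit)
            chrom_runs.append((start, end, labels[states[i]]))
            i = j + 1
        runs[chrom] = chrom_runs
    return Segmentation(runs, labels)


# ---------------------------------------------------------------------------
# coverage profiling


def _merge_intervals(peaks: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    merged: list[GenomicInterval] = []
    for iv in sorted(peaks, key=lambda p: (p.chrom, p.start, p.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def state_coverage(
    peaks: Sequence[GenomicInterval], seg: Segmentation, merge: bool = False
) -> StateCoverageProfile:
    """Fraction of total peak bp falling in each chromatin state.

    Overlapping peaks are counted once per peak (each peak's bp contributes
    independently) unless ``merge=True`` flattens the peak set first. The
    genome-wide state fractions over the segmented chromosomes are returned as
    the baseline.
    """
    if not peaks:
        raise ValueError("no peak bp: empty peak set")
    if merge:
        peaks = _merge_intervals(peaks)

    starts = {c: [r[0] for r in runs] for c, runs in seg.runs.items()}
    bp: dict[str, int] = {label: 0 for label in seg.state_labels}
    total = 0
    for p in peaks:
        if p.chrom not in seg.runs:
            raise ValueError(f"peak chromosome {p.chrom!r} absent from segmentation")
        runs = seg.runs[p.chrom]
        i = max(bisect_right(starts[p.chrom], p.start) - 1, 0)
        while i < len(runs) and runs[i][0] < p.end:
            s, e, label = runs[i]
            ov = min(e, p.end) - max(s, p.start)
            if ov > 0:
                bp[label] = bp.get(label, 0) + ov
            i += 1
        total += len(p)

    genome_bp: dict[str, int] = {label: 0 for label in seg.state_labels}
    for runs in seg.runs.values():
        for s, e, label in runs:
            genome_bp[label] = genome_bp.get(label, 0) + (e - s)
    genome_total = seg.total_bp

    return StateCoverageProfile(
        fractions={label: bp.get(label, 0) / total for label in genome_bp},
        total_peak_bp=total,
        genome_fraction={label: v / genome_total for label, v in genome_bp.items()},
    )


def group_states(
    profile: StateCoverageProfile, group_map: dict[str, str]
) -> StateCoverageProfile:
    """Collapse opaque state labels into named groups (promoter, enhancer, ...).

    Sums are preserved; every state present in the profile must be mapped.
    """
    missing = [s for s in profile.fractions if s not in group_map]
    if missing:
        raise ValueError(f"states not covered by group_map: {missing}")
    grouped: dict[str, float] = {}
    grouped_genome: dict[str, float] = {}
    for state, frac in profile.fractions.items():
        g = group_map[state]
        grouped[g] = grouped.get(g, 0.0) + frac
        grouped_genome[g] = grouped_genome.get(g, 0.0) + profile.genome_fraction[state]
    return StateCoverageProfile(grouped, profile.total_peak_bp, grouped_genome)


def match_states(reference_emission: np.ndarray, emission: np.ndarray) -> np.ndarray:
    """Permutation aligning fitted states to reference states.

    Solves the assignment problem on mean absolute emission distance; returns
    ``perm`` with ``emission[perm[k]]`` matched to ``reference_emission[k]``.
    """
    ref = np.asarray(reference_emission, dtype=float)
    est = np.asarray(emission, dtype=float)
    cost = np.abs(ref[:, None, :] - est[None, :, :]).mean(axis=2)
    _, perm = linear_sum_assignment(cost)
    return perm
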