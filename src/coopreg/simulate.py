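"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates, at desk scale, the structure of a paired
ChIP-seq/knockdown study of two cooperating transcription factors:

* a hidden chromatin-state chain emitting binary marks per 200-bp bin,
* TF-A peaks enriched near TSSs, each spawning a TF-B peak that overlaps it
  with a planted co-bound rate,
* H3K27ac / RNA-PolII evidence peaks covering exact planted fractions of the
  TF-A peaks,
* two knockdown DEG tables with planted affected genes and planted
  cooperatively regulated genes (correlated shifts in both contrasts),
* mito-stress OCR traces with phase-level means, a planted fold-change on the
  mitochondrial components, and Gaussian well noise.

Planted peaks are mutually exclusive within a guard margin so every truth set
(co-bound fraction, active fraction, proximal target genes) is exact rather
than approximate. Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .chromatin import BinarizedTracks, ChromatinStateModel, Segmentation
from .genome import (
    GeneModel,
    Genome,
    GenomicInterval,
    SignalTrack,
    write_gene_table,
    write_genome,
    write_intervals,
)
from .ocr import OCRTrace, write_ocr_table
from .targets import DEGTable

__all__ = [
    "make_genome_and_genes",
    "default_state_model",
    "simulate_marks",
    "simulate_peaks",
    "PeakSimulation",
    "simulate_deg_tables",
    "simulate_ocr",
    "simulate_all",
    "SimulationConfig",
]


# ---------------------------------------------------------------------------
# genome and genes


def make_genome_and_genes(
    n_chrom: int = 1,
    chrom_length: int = 2_000_000,
    n_genes: int = 200,
    seed: int = 0,
) -> tuple[Genome, list[GeneModel]]:
    """Place non-overlapping genes (1-2 kb) with random gaps; strands Bernoulli(0.5)."""
    if n_genes * 2000 > n_chrom * chrom_length:
        raise ValueError("infeasible packing: n_genes * 2 kb exceeds total genome length")
    rng = np.random.default_rng(seed)
    genome = Genome({f"chr{i + 1}": chrom_length for i in range(n_chrom)})
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0) for i in range(n_chrom)]
    genes: list[GeneModel] = []
    gid = 0
    for ci, chrom in enumerate(genome.chrom_lengths):
        n = per_chrom[ci]
        if n == 0:
            continue
        lengths = rng.integers(1000, 2001, size=n)
        slack = chrom_length - int(lengths.sum())
        if slack < 0:
            raise ValueError("infeasible packing on one chromosome")
        w = rng.random(n + 1)
        gaps = np.floor(w / w.sum() * slack).astype(int)
        pos = 0
        for i in range(n):
            pos += int(gaps[i])
            start = pos
            end = start + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(GeneModel(f"g{gid:04d}", chrom, strand, start, end))
            pos = end
    return genome, genes


# ---------------------------------------------------------------------------
# chromatin marks


def default_state_model(K: int = 3, M: int = 2, mark_names: Optional[list[str]] = None,
                        self_transition: float = 0.9) -> ChromatinStateModel:
    """A well-separated sticky reference model: state k emits mark m at 0.9 when
    m < M * (K - k) / K, else 0.1 (a nested 'activity ladder')."""
    marks = mark_names or [f"mark{m + 1}" for m in range(M)]
    emission = np.full((K, M), 0.1)
    for k in range(K):
        n_on = M if K == 1 else round(M * (K - 1 - k) / (K - 1))
        emission[k, :n_on] = 0.9
    transition = np.full((K, K), (1 - self_transition) / max(K - 1, 1))
    np.fill_diagonal(transition, self_transition if K > 1 else 1.0)
    initial = np.full(K, 1.0 / K)
    return ChromatinStateModel(initial, transition, emission, marks)


def simulate_marks(
    model: ChromatinStateModel,
    genome: Genome,
    bin_size: int = 200,
    seed: int = 0,
) -> tuple[BinarizedTracks, Segmentation]:
    """Sample the hidden state chain and Bernoulli mark emissions per chromosome."""
    rng = np.random.default_rng(seed)
    k = model.n_states
    labels = model.state_labels
    data: dict[str, np.ndarray] = {}
    runs: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, length in genome.chrom_lengths.items():
        n = genome.n_bins(chrom, bin_size)
        states = np.empty(n, dtype=int)
        states[0] = rng.choice(k, p=model.initial)
        for t in range(1, n):
            states[t] = rng.choice(k, p=model.transition[states[t - 1]])
        marks = (rng.random((n, model.n_marks)) < model.emission[states]).astype(np.uint8)
        data[chrom] = marks
        chrom_runs: list[tuple[int, int, str]] = []
        i = 0
        while i < n:
            j = i
            while j + 1 < n and states[j + 1] == states[i]:
                j += 1
            chrom_runs.append((i * bin_size, min((j + 1) * bin_size, length), labels[states[i]]))
            i = j + 1
        runs[chrom] = chrom_runs
    tracks = BinarizedTracks(list(model.mark_names), data, bin_size=bin_size)
    return tracks, Segmentation(runs, labels)


# ---------------------------------------------------------------------------
# peaks


@dataclass
class PeakSimulation:
    """Planted peak sets plus the truth needed to score downstream stages."""

    peaks_a: list[GenomicInterval]
    peaks_b: list[GenomicInterval]
    k27_peaks: list[GenomicInterval]
    pol2_peaks: list[GenomicInterval]
    proximal_genes: set[str]  # genes owning a planted TSS-proximal A peak
    peak_gene: dict[str, Optional[str]]  # A-peak name -> planted gene (proximal only)
    cobound_a: set[str]  # A-peak names whose B partner overlaps them
    active_both: set[str]  # A-peak names covered by both H3K27ac and PolII
    active_k27_only: set[str]
    active_pol2_only: set[str]

    def truth_dict(self) -> dict:
        return {
            "proximal_genes": sorted(self.proximal_genes),
            "peak_gene": {k: v for k, v in sorted(self.peak_gene.items()) if v},
            "cobound_a": sorted(self.cobound_a),
            "active_both": sorted(self.active_both),
            "active_k27_only": sorted(self.active_k27_only),
            "active_pol2_only": sorted(self.active_pol2_only),
        }


class _ZoneKeeper:
    """Per-chromosome sorted exclusion zones for non-overlapping placement."""

    def __init__(self) -> None:
        self._zones: dict[str, list[tuple[int, int]]] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        zones = self._zones.setdefault(chrom, [])
        i = bisect_left(zones, (start, start))
        if i < len(zones) and zones[i][0] < end:
            return False
        if i > 0 and zones[i - 1][1] > start:
            return False
        return True

    def reserve(self, chrom: str, start: int, end: int) -> None:
        insort(self._zones.setdefault(chrom, []), (start, end))


def simulate_peaks(
    genes: Sequence[GeneModel],
    genome: Genome,
    n_peaks: int = 600,
    frac_tss_proximal: float = 0.3,
    co_bound_rate: float = 0.44,
    frac_active_both: float = 0.6,
    frac_k27_only: float = 0.1,
    frac_pol2_only: float = 0.1,
    width_range: tuple[int, int] = (200, 400),
    margin: int = 150,
    seed: int = 0,
    max_tries: int = 500,
) -> PeakSimulation:
    """Plant the two TF peak sets, their evidence marks, and exact truth sets.

    A fraction of A peaks is centered within 500 bp of sampled TSSs (rejecting
    placements whose nearest TSS is not the intended gene, so the proximal
    truth is exact); the rest are uniform background. Every A peak spawns one
    B peak: overlapping (small shift) with probability ``co_bound_rate``,
    otherwise placed in free background. Mark peaks pad their A peak by 40 bp.
    Active fractions are planted as exact counts, not Bernoulli draws.
    """
    for name, v in [("frac_tss_proximal", frac_tss_proximal),
                    ("co_bound_rate", co_bound_rate)]:
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    zones = _ZoneKeeper()
    pad = 40
    chroms = list(genome.chrom_lengths)

    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for c in tss_by_chrom:
        tss_by_chrom[c].sort()

    def nearest_gene(chrom: str, pos: int) -> Optional[str]:
        entries = tss_by_chrom.get(chrom)
        if not entries:
            return None
        i = bisect_left(entries, (pos, ""))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(entries):
                d = abs(entries[j][0] - pos)
                key = (d, entries[j][1])
                if best is None or key < best:
                    best = key
        return best[1] if best else None

    n_prox = round(n_peaks * frac_tss_proximal)
    peaks_a: list[GenomicInterval] = []
    peak_gene: dict[str, Optional[str]] = {}
    proximal_genes: set[str] = set()

    def place_a(idx: int, proximal: bool) -> GenomicInterval:
        for _ in range(max_tries):
            w = int(rng.integers(width_range[0], width_range[1] + 1))
            gene = None
            if proximal:
                gene = genes[int(rng.integers(len(genes)))]
                center = gene.tss + int(rng.integers(-500, 501))
                chrom = gene.chrom
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                center = int(rng.integers(0, genome.chrom_lengths[chrom]))
            start, end = center - w // 2, center - w // 2 + w
            if start < margin or end > genome.chrom_lengths[chrom] - margin:
                continue
            if proximal and nearest_gene(chrom, (start + end) // 2) != gene.gene_id:
                continue
            if not zones.free(chrom, start - margin, end + margin):
                continue
            zones.reserve(chrom, start - margin, end + margin)
            name = f"peakA_{idx:05d}"
            iv = GenomicInterval(chrom, start, end, name=name)
            peak_gene[name] = gene.gene_id if gene else None
            if gene:
                proximal_genes.add(gene.gene_id)
            return iv
        raise RuntimeError("peak placement failed; genome too crowded for n_peaks")

    for i in range(n_peaks):
        peaks_a.append(place_a(i, proximal=i < n_prox))

    # B peaks: one per A peak, overlapping with probability co_bound_rate.
    peaks_b: list[GenomicInterval] = []
    cobound_a: set[str] = set()
    for i, a in enumerate(peaks_a):
        name = f"peakB_{i:05d}"
        if rng.random() < co_bound_rate:
            w = len(a)
            shift = int(rng.integers(-(w // 4), w // 4 + 1))
            peaks_b.append(GenomicInterval(a.chrom, a.start + shift, a.end + shift, name=name))
            cobound_a.add(a.name)
        else:
            for _ in range(max_tries):
                w = int(rng.integers(width_range[0], width_range[1] + 1))
                chrom = chroms[int(rng.integers(len(chroms)))]
                start = int(rng.integers(margin, genome.chrom_lengths[chrom] - w - margin))
                if zones.free(chrom, start - margin, start + w + margin):
                    zones.reserve(chrom, start - margin, start + w + margin)
                    peaks_b.append(GenomicInterval(chrom, start, start + w, name=name))
                    break
            else:
                raise RuntimeError("background B-peak placement failed")

    # evidence marks: exact planted counts
    order = rng.permutation(n_peaks)
    n_both = round(frac_active_both * n_peaks)
    n_k27 = round(frac_k27_only * n_peaks)
    n_pol2 = round(frac_pol2_only * n_peaks)
    both_idx = order[:n_both]
    k27_idx = order[n_both:n_both + n_k27]
    pol2_idx = order[n_both + n_k27:n_both + n_k27 + n_pol2]
    k27_peaks, pol2_peaks = [], []
    for j, i in enumerate(sorted(np.concatenate([both_idx, k27_idx]).tolist())):
        a = peaks_a[i]
        k27_peaks.append(GenomicInterval(a.chrom, a.start - pad, a.end + pad, name=f"k27_{j:05d}"))
    for j, i in enumerate(sorted(np.concatenate([both_idx, pol2_idx]).tolist())):
        a = peaks_a[i]
        pol2_peaks.append(GenomicInterval(a.chrom, a.start - pad, a.end + pad, name=f"pol2_{j:05d}"))

    return PeakSimulation(
        peaks_a=peaks_a,
        peaks_b=peaks_b,
        k27_peaks=k27_peaks,
        pol2_peaks=pol2_peaks,
        proximal_genes=proximal_genes,
        peak_gene=peak_gene,
        cobound_a=cobound_a,
        active_both={peaks_a[i].name for i in both_idx},
        active_k27_only={peaks_a[i].name for i in k27_idx},
        active_pol2_only={peaks_a[i].name for i in pol2_idx},
    )


# ---------------------------------------------------------------------------
# DEG tables


def simulate_deg_tables(
    genes: Sequence[GeneModel],
    affected_a: set[str],
    affected_b: set[str],
    cooperative: set[str],
    effect_size: float = 5.0,
    cooperative_effect: float = 3.0,
    se: float | tuple[float, float] = 0.5,
    noise: bool = True,
    seed: int = 0,
) -> tuple[DEGTable, DEGTable, dict]:
    """Two knockdown DEG tables with planted effects.

    Effects are expressed in SE units: an affected gene's true log2FC is
    ``±effect_size * se``; cooperative genes (a subset of both affected sets)
    receive correlated shifts of ``cooperative_effect * se`` with a shared
    sign in both contrasts. Null genes are N(0, se^2). p-values come from the
    two-sided normal model and are BH-adjusted within each table. With
    ``noise=False`` the observed log2FC equals its planted mean exactly.
    """
    if not cooperative <= (affected_a & affected_b):
        raise ValueError("cooperative genes must be affected in both contrasts")
    rng = np.random.default_rng(seed)
    rows_a, rows_b = [], []
    truth_sign: dict[str, dict[str, int]] = {}
    for g in genes:
        if isinstance(se, tuple):
            se_a = float(rng.uniform(*se))
            se_b = float(rng.uniform(*se))
        else:
            se_a = se_b = float(se)
        coop_sign = int(rng.choice((-1, 1)))
        sign_a = int(rng.choice((-1, 1)))
        sign_b = int(rng.choice((-1, 1)))
        if g.gene_id in cooperative:
            mu_a = coop_sign * cooperative_effect * se_a
            mu_b = coop_sign * cooperative_effect * se_b
        else:
            mu_a = sign_a * effect_size * se_a if g.gene_id in affected_a else 0.0
            mu_b = sign_b * effect_size * se_b if g.gene_id in affected_b else 0.0
        eps_a = rng.normal(0.0, se_a) if noise else 0.0
        eps_b = rng.normal(0.0, se_b) if noise else 0.0
        fc_a, fc_b = mu_a + eps_a, mu_b + eps_b
        rows_a.append((g.gene_id, fc_a, se_a))
        rows_b.append((g.gene_id, fc_b, se_b))
        truth_sign[g.gene_id] = {"mu_a": mu_a, "mu_b": mu_b}

    def build(rows, contrast) -> DEGTable:
        df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "se"])
        pvals = 2 * norm.sf(np.abs(df["log2fc"] / df["se"]))
        df["padj"] = multipletests(pvals, method="fdr_bh")[1]
        return DEGTable(df, contrast=contrast)

    truth = {
        "affected_a": sorted(affected_a),
        "affected_b": sorted(affected_b),
        "cooperative": sorted(cooperative),
        "effect_size": effect_size,
        "cooperative_effect": cooperative_effect,
    }
    return build(rows_a, "KD_A"), build(rows_b, "KD_B"), truth


# ---------------------------------------------------------------------------
# OCR traces


def simulate_ocr(
    phase_means: Sequence[float] = (100.0, 40.0, 180.0, 20.0),
    noise_sd: float = 4.0,
    n_wells: int = 6,
    planted_fold: float = 1.5,
    cell_count: int = 50_000,
    n_points: int = 3,
    seed: int = 0,
) -> tuple[list[OCRTrace], list[OCRTrace]]:
    """CTRL and KD well traces for the four-phase mito-stress protocol.

    ``phase_means`` are raw per-well OCR levels (baseline, oligomycin, FCCP,
    rotenone+antimycin A). KD wells scale the mitochondrial component of each
    phase by ``planted_fold`` while the non-mitochondrial floor is untouched,
    so basal, ATP-linked and maximal OCR all change by exactly the planted
    fold in expectation.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    bl, ol, fc, nm = (float(v) for v in phase_means)
    rng = np.random.default_rng(seed)
    from .ocr import PHASES

    kd_means = {
        "baseline": nm + planted_fold * (bl - nm),
        "oligomycin": nm + planted_fold * (ol - nm),
        "fccp": nm + planted_fold * (fc - nm),
        "rot_aa": nm,
    }
    ctrl_means = dict(zip(PHASES, (bl, ol, fc, nm)))

    def wells(means: dict[str, float], condition: str) -> list[OCRTrace]:
        out = []
        for w in range(n_wells):
            times, values, phases = [], [], []
            t = 0.0
            for phase in PHASES:
                for _ in range(n_points):
                    times.append(t)
                    values.append(means[phase] + rng.normal(0.0, noise_sd))
                    phases.append(phase)
                    t += 6.5
            out.append(
                OCRTrace(np.array(times), np.array(values), phases,
                         cell_count=cell_count, sample=f"{condition}_w{w + 1}",
                         condition=condition)
            )
        return out

    return wells(ctrl_means, "CTRL"), wells(kd_means, "KD")


# ---------------------------------------------------------------------------
# full-dataset orchestration


@dataclass
class SimulationConfig:
    """Study conditions for a full synthetic dataset (toy scale: 1 x 2 Mb)."""

    n_chrom: int = 1
    chrom_length: int = 2_000_000
    n_genes: int = 200
    bin_size: int = 200
    n_states: int = 3
    n_marks: int = 2
    n_peaks: int = 600
    frac_tss_proximal: float = 0.3
    co_bound_rate: float = 0.44
    frac_active_both: float = 0.6
    frac_affected: float = 0.25
    frac_cooperative: float = 0.05
    effect_size: float = 5.0
    cooperative_effect: float = 3.0
    deg_se: float = 0.5
    ocr_noise_sd: float = 4.0
    ocr_fold: float = 1.5
    n_wells: int = 6


def simulate_all(outdir: str | Path, seed: int, config: Optional[SimulationConfig] = None) -> dict:
    """Generate every pipeline input under ``outdir`` plus ``truth.json``.

    Deterministic per (config, seed): sub-generators receive children of one
    SeedSequence, and all files are written with fixed formatting, so reruns
    are byte-identical.
    """
    cfg = config or SimulationConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(6)]

    genome, genes = make_genome_and_genes(
        cfg.n_chrom, cfg.chrom_length, cfg.n_genes, seed=seeds[0]
    )
    write_genome(genome, outdir / "genome.tsv")
    write_gene_table(genes, outdir / "genes.tsv")

    model = default_state_model(cfg.n_states, cfg.n_marks)
    tracks, true_seg = simulate_marks(model, genome, cfg.bin_size, seed=seeds[1])
    (outdir / "marks").mkdir(exist_ok=True)
    for mi, mark in enumerate(tracks.marks):
        st = SignalTrack(
            {c: tracks.data[c][:, mi].astype(float) for c in tracks.data}, cfg.bin_size
        )
        st.to_bedgraph(outdir / "marks" / f"{mark}.bedgraph", genome)
    write_intervals(true_seg.to_intervals(), outdir / "true_segments.bed", "segments")
    with open(outdir / "marks.yaml", "w") as fh:
        fh.write(f"bin_size: {cfg.bin_size}\n")
        fh.write("genome: genome.tsv\n")
        fh.write("marks:\n")
        for mark in tracks.marks:
            fh.write(f"  {mark}: marks/{mark}.bedgraph\n")

    sim = simulate_peaks(
        genes, genome,
        n_peaks=cfg.n_peaks,
        frac_tss_proximal=cfg.frac_tss_proximal,
        co_bound_rate=cfg.co_bound_rate,
        frac_active_both=cfg.frac_active_both,
        seed=seeds[2],
    )
    write_intervals(sim.peaks_a, outdir / "peaks_a.bed", "bed6")
    write_intervals(sim.peaks_b, outdir / "peaks_b.bed", "bed6")
    write_intervals(sim.k27_peaks, outdir / "k27.bed", "bed6")
    write_intervals(sim.pol2_peaks, outdir / "pol2.bed", "bed6")

    # planted expression effects: bound-and-active genes first, topped up with
    # unbound genes so an indirect class exists; cooperative genes come from
    # co-bound active peaks.
    rng = np.random.default_rng(seeds[3])
    active_prox = sorted(
        {sim.peak_gene[n] for n in sim.active_both if sim.peak_gene.get(n)}
    )
    coop_pool = sorted(
        {sim.peak_gene[n] for n in (sim.active_both & sim.cobound_a) if sim.peak_gene.get(n)}
    )
    n_coop = min(round(cfg.frac_cooperative * cfg.n_genes), len(coop_pool))
    cooperative = {str(g) for g in rng.choice(coop_pool, size=n_coop, replace=False)}
    unbound = sorted(set(g.gene_id for g in genes) - set(active_prox))

    def affected_set() -> set[str]:
        n_affected = round(cfg.frac_affected * cfg.n_genes)
        n_direct = min(round(0.6 * n_affected), len(active_prox))
        n_indirect = n_affected - n_direct
        chosen = {str(g) for g in rng.choice(active_prox, size=n_direct, replace=False)}
        chosen |= {str(g) for g in rng.choice(unbound, size=min(n_indirect, len(unbound)), replace=False)}
        return chosen | cooperative

    affected_a = affected_set()
    affected_b = affected_set()
    deg_a, deg_b, deg_truth = simulate_deg_tables(
        genes, affected_a, affected_b, cooperative,
        effect_size=cfg.effect_size,
        cooperative_effect=cfg.cooperative_effect,
        se=cfg.deg_se,
        seed=seeds[4],
    )
    deg_a.to_tsv(outdir / "deg_a.tsv")
    deg_b.to_tsv(outdir / "deg_b.tsv")

    ctrl, kd = simulate_ocr(
        noise_sd=cfg.ocr_noise_sd, n_wells=cfg.n_wells,
        planted_fold=cfg.ocr_fold, seed=seeds[5],
    )
    write_ocr_table(ctrl + kd, outdir / "ocr.tsv")

    truth = {
        "seed": seed,
        "config": asdict(cfg),
        "state_model": {
            "emission": model.emission.tolist(),
            "transition": model.transition.tolist(),
        },
        "peaks": sim.truth_dict(),
        "degs": deg_truth,
        "ocr_planted_fold": cfg.ocr_fold,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return truth
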