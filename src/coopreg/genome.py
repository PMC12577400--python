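"""Core genomic data types, interval arithmetic, and on-disk format readers/writers.

All coordinates are 0-based half-open (BED convention). GTF input, which is
1-based closed, is converted at the reader boundary and never leaks inward.
"""

from __future__ import annotations

import math
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "Genome",
    "GenomicInterval",
    "GeneModel",
    "SignalTrack",
    "read_intervals",
    "write_intervals",
    "overlap_bp",
    "intersect_many",
    "nearest_tss",
    "read_gene_table",
    "write_gene_table",
    "read_gtf_genes",
    "read_genome",
    "write_genome",
]

INTERVAL_FORMATS = ("bed3", "bed6", "narrowPeak", "segments")


@dataclass(frozen=True)
class Genome:
    """Chromosome name -> length (bp). Names unique by construction (dict keys)."""

    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.chrom_lengths[chrom] / bin_size)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region with optional strand, label and score.

    ``summit`` is the narrowPeak point-source offset relative to ``start``
    (-1 when not determined); ``signal``/``pvalue``/``qvalue`` carry the
    remaining narrowPeak columns so round-trips are lossless.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None
    summit: Optional[int] = None
    signal: Optional[float] = None
    pvalue: Optional[float] = None
    qvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def validate_against(self, genome: Genome) -> None:
        length = genome.chrom_lengths.get(self.chrom)
        if length is None:
            raise ValueError(f"chromosome {self.chrom!r} not in genome")
        if self.end > length:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds chromosome length {length}"
            )


@dataclass(frozen=True)
class GeneModel:
    """Gene with transcript extent; TSS is the strand-dependent 5' end."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.tx_start < 0 or self.tx_start >= self.tx_end:
            raise ValueError(f"gene {self.gene_id}: invalid extent {self.tx_start}-{self.tx_end}")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass
class SignalTrack:
    """Per-bin non-negative signal, one vector per chromosome."""

    data: dict[str, np.ndarray]
    bin_size: int = 200

    def __post_init__(self) -> None:
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}

    @classmethod
    def zeros(cls, genome: Genome, bin_size: int = 200) -> "SignalTrack":
        return cls(
            {c: np.zeros(genome.n_bins(c, bin_size)) for c in genome.chrom_lengths},
            bin_size=bin_size,
        )

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.data[chrom][pos // self.bin_size])

    @classmethod
    def from_bedgraph(cls, path: str | Path, genome: Genome, bin_size: int = 200) -> "SignalTrack":
        """Read a bedGraph; record values are spread over bins weighted by bp overlap."""
        track = cls.zeros(genome, bin_size)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}: malformed bedGraph line {lineno}")
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                vec = track.data[chrom]
                b0, b1 = start // bin_size, (end - 1) // bin_size
                for b in range(b0, b1 + 1):
                    lo = max(start, b * bin_size)
                    hi = min(end, (b + 1) * bin_size)
                    vec[b] += value * (hi - lo) / bin_size
        return track

    def to_bedgraph(self, path: str | Path, genome: Optional[Genome] = None) -> None:
        """Write run-length-merged bedGraph; final interval clipped to the genome if given."""
        with open(path, "w") as fh:
            for chrom in self.data:
                vec = self.data[chrom]
                limit = genome.chrom_lengths[chrom] if genome else len(vec) * self.bin_size
                i = 0
                while i < len(vec):
                    j = i
                    while j + 1 < len(vec) and vec[j + 1] == vec[i]:
                        j += 1
                    start = i * self.bin_size
                    end = min((j + 1) * self.bin_size, limit)
                    fh.write(f"{chrom}\t{start}\t{end}\t{vec[i]:.6g}\n")
                    i = j + 1


# ---------------------------------------------------------------------------
# interval I/O


def _fmt_score(score: Optional[float]) -> str:
    if score is None:
        return "."
    return f"{score:.10g}"


def _parse_score(token: str) -> Optional[float]:
    return None if token == "." else float(token)


def read_intervals(path: str | Path, format: str = "bed6") -> list[GenomicInterval]:
    """Read intervals in one of the supported BED dialects, preserving file order.

    ``segments`` is the ChromHMM segmentation dialect: four columns with the
    state label in column 4 (carried on ``name``).
    """
    if format not in INTERVAL_FORMATS:
        raise ValueError(f"unsupported format {format!r}; expected one of {INTERVAL_FORMATS}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            f = line.split("\t")
            try:
                if format == "bed3":
                    if len(f) < 3:
                        raise ValueError("expected >=3 columns")
                    iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
                elif format == "bed6":
                    if len(f) < 6:
                        raise ValueError("expected >=6 columns")
                    iv = GenomicInterval(
                        f[0], int(f[1]), int(f[2]),
                        strand=f[5], name=f[3], score=_parse_score(f[4]),
                    )
                elif format == "narrowPeak":
                    if len(f) < 10:
                        raise ValueError("expected 10 columns")
                    iv = GenomicInterval(
                        f[0], int(f[1]), int(f[2]),
                        strand=f[5], name=f[3], score=_parse_score(f[4]),
                        signal=float(f[6]), pvalue=float(f[7]), qvalue=float(f[8]),
                        summit=int(f[9]),
                    )
                else:  # segments
                    if len(f) < 4:
                        raise ValueError("expected 4 columns")
                    iv = GenomicInterval(f[0], int(f[1]), int(f[2]), name=f[3])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_intervals(
    intervals: Iterable[GenomicInterval], path: str | Path, format: str = "bed6"
) -> None:
    if format not in INTERVAL_FORMATS:
        raise ValueError(f"unsupported format {format!r}; expected one of {INTERVAL_FORMATS}")
    with open(path, "w") as fh:
        for iv in intervals:
            if format == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif format == "bed6":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{_fmt_score(iv.score)}\t{iv.strand}\n"
                )
            elif format == "narrowPeak":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{_fmt_score(iv.score)}\t{iv.strand}\t"
                    f"{0.0 if iv.signal is None else iv.signal:.10g}\t"
                    f"{-1.0 if iv.pvalue is None else iv.pvalue:.10g}\t"
                    f"{-1.0 if iv.qvalue is None else iv.qvalue:.10g}\t"
                    f"{-1 if iv.summit is None else iv.summit}\n"
                )
            else:  # segments
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


# ---------------------------------------------------------------------------
# interval arithmetic


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals; 0 across chromosomes and for adjacency."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _sort_key(iv: GenomicInterval):
    return (iv.chrom, iv.start, iv.end, iv.name or "")


def intersect_many(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[list[GenomicInterval]]:
    """For each query interval, the subject intervals overlapping it by >= 1 bp.

    Equivalent to the all-pairs brute force; uses a per-chromosome interval tree,
    so runs in O((n+m) log(n+m)). Hits are sorted by (start, end, name).
    """
    trees: dict[str, IntervalTree] = {}
    for iv in subject:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    out: list[list[GenomicInterval]] = []
    for q in query:
        tree = trees.get(q.chrom)
        hits = [h.data for h in tree.overlap(q.start, q.end)] if tree else []
        hits.sort(key=_sort_key)
        out.append(hits)
    return out


def nearest_tss(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    anchor: str = "midpoint",
) -> tuple[Optional[str], Optional[int]]:
    """Assign a peak to the gene with the nearest TSS on its chromosome.

    The signed distance runs from the peak anchor (midpoint by default; the
    narrowPeak summit when ``anchor="summit"`` and the peak carries one) to the
    TSS, and is 0 whenever the TSS lies inside the peak. Ties are broken by
    smaller absolute distance, then lexicographically smaller gene_id. Returns
    (None, None) when no gene shares the peak's chromosome.
    """
    if anchor not in ("midpoint", "summit"):
        raise ValueError(f"unknown anchor {anchor!r}")
    pos = peak.midpoint
    if anchor == "summit" and peak.summit is not None and peak.summit >= 0:
        pos = peak.start + peak.summit
    best: Optional[tuple[int, str]] = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        d = 0 if peak.start <= g.tss < peak.end else g.tss - pos
        key = (abs(d), g.gene_id)
        if best is None or key < (abs(best[0]), best[1]):
            best = (d, g.gene_id)
    if best is None:
        return None, None
    return best[1], best[0]


# ---------------------------------------------------------------------------
# gene-table / GTF / genome I/O


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """TSV with header: gene_id, chrom, strand, tx_start, tx_end."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("gene_id", "chrom", "strand", "tx_start", "tx_end"):
            if col not in idx:
                raise ValueError(f"{path}: missing column {col!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            g = GeneModel(
                f[idx["gene_id"]], f[idx["chrom"]], f[idx["strand"]],
                int(f[idx["tx_start"]]), int(f[idx["tx_end"]]),
            )
            if g.gene_id in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            genes.append(g)
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttx_start\ttx_end\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\n")


_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Minimal GTF reader consuming only ``gene`` features (1-based closed -> half-open)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GTF columns")
            if f[2] != "gene":
                continue
            m = _GENE_ID_RE.search(f[8])
            if not m:
                raise ValueError(f"{path}: line {lineno}: no gene_id attribute")
            genes.append(GeneModel(m.group(1), f[0], f[6], int(f[3]) - 1, int(f[4])))
    return genes


def read_genome(path: str | Path) -> Genome:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, length = line.split("\t")[:2]
            lengths[chrom] = int(length)
    return Genome(lengths)


def write_genome(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
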