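"""Two-TF co-occupancy and the cooperative-regulation test.

Co-occupancy counts the second TF's peaks overlapped by the first and keeps
their intersections as the co-bound regions. Cooperation is then called on
the paired knockdown fold-change plane: per-contrast log2FCs are shrunk by a
normal-normal empirical-Bayes model, both axes are robustly standardized
(median/MAD), and a gene is cooperatively regulated when it is assigned to a
co-bound region and its standardized radius exceeds the chi-square(df=2)
boundary of the independence null (a 95% circle at alpha = 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genome import GenomicInterval, intersect_many
from .targets import DEGTable

__all__ = [
    "OverlapSummary",
    "ShrunkenFC",
    "IndependenceRegion",
    "CooperationResult",
    "co_occupancy",
    "shrink_fc",
    "independence_region",
    "call_cooperative",
]

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # consistency factor: MAD * 1.4826 estimates sigma for a normal


@dataclass
class OverlapSummary:
    """Co-occupancy of peak set B by peak set A."""

    n_a: int
    n_b: int
    n_overlap: int  # B peaks overlapped by >= 1 bp of A
    overlapping_regions: list[GenomicInterval]  # pairwise intersections, merged when contiguous

    @property
    def fraction_of_b(self) -> float:
        return round(self.n_overlap / self.n_b, 4)


def co_occupancy(
    peaks_a: Sequence[GenomicInterval], peaks_b: Sequence[GenomicInterval]
) -> OverlapSummary:
    """Count B peaks co-occupied by A and extract the shared regions."""
    if not peaks_a or not peaks_b:
        raise ValueError("co_occupancy requires two non-empty peak sets")
    hits = intersect_many(peaks_b, peaks_a)
    n_overlap = sum(1 for h in hits if h)

    pieces: list[tuple[str, int, int]] = []
    for b, h in zip(peaks_b, hits):
        for a in h:
            pieces.append((b.chrom, max(a.start, b.start), min(a.end, b.end)))
    pieces.sort()
    regions: list[GenomicInterval] = []
    for chrom, start, end in pieces:
        if regions and regions[-1].chrom == chrom and start <= regions[-1].end:
            last = regions[-1]
            if end > last.end:
                regions[-1] = GenomicInterval(chrom, last.start, end)
        else:
            regions.append(GenomicInterval(chrom, start, end))
    return OverlapSummary(len(peaks_a), len(peaks_b), n_overlap, regions)


@dataclass
class ShrunkenFC:
    """Raw and empirical-Bayes shrunken log2 fold-changes for one contrast."""

    data: pd.DataFrame  # columns: gene_id, log2fc, se, shrunken
    prior_variance: float
    contrast: str = ""

    def shrunken_map(self) -> dict[str, float]:
        return dict(zip(self.data["gene_id"], self.data["shrunken"]))


def shrink_fc(table: DEGTable) -> ShrunkenFC:
    """Normal-normal empirical-Bayes shrinkage of log2 fold-changes toward 0.

    The prior is N(0, tau^2) with tau^2 estimated by moments:
    tau^2 = max(0, var(raw FCs) - mean(se^2)). The posterior mean is
    raw * tau^2 / (tau^2 + se^2), so precise estimates are barely moved while
    noisy ones are pulled hard toward zero; tau^2 = 0 collapses everything.
    """
    df = table.data
    if len(df) < 3:
        raise ValueError("need at least 3 genes to estimate the prior variance")
    if (df["se"] <= 0).any():
        raise ValueError("all standard errors must be positive")
    raw = df["log2fc"].to_numpy(dtype=float)
    se2 = df["se"].to_numpy(dtype=float) ** 2
    tau2 = max(0.0, float(np.var(raw, ddof=1) - se2.mean()))
    shrunken = raw * (tau2 / (tau2 + se2)) if tau2 > 0 else np.zeros_like(raw)
    out = df[["gene_id", "log2fc", "se"]].copy()
    out["shrunken"] = shrunken
    return ShrunkenFC(out, prior_variance=tau2, contrast=table.contrast)


@dataclass
class IndependenceRegion:
    """Robustly standardized FC plane with its chi-square(df=2) null boundary."""

    radius_threshold: float
    radius: np.ndarray
    x_std: np.ndarray
    y_std: np.ndarray
    alpha: float


def independence_region(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> IndependenceRegion:
    """Standardized radius of each gene and the (1 - alpha) null circle.

    Each axis is centered on its median and scaled by MAD * 1.4826, so the
    bulk of (independently regulated) genes is approximately standard normal
    and planted outliers cannot inflate the null. Under an independent
    bivariate standard normal, r^2 is chi-square(df=2); the threshold
    sqrt(chi2_{1-alpha}(2)) therefore flags a fraction alpha.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 10:
        raise ValueError("x and y must be equal-length vectors with >= 10 entries")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")

    def standardize(v: np.ndarray) -> np.ndarray:
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            raise ValueError("degenerate axis: MAD is zero")
        return (v - med) / (mad * MAD_SCALE)

    xs, ys = standardize(x), standardize(y)
    r = np.sqrt(xs**2 + ys**2)
    threshold = float(np.sqrt(chi2.ppf(1 - alpha, df=2)))
    return IndependenceRegion(threshold, r, xs, ys, alpha)


@dataclass
class CooperationResult:
    """Per-gene cooperation call on the paired shrunken-FC plane."""

    data: pd.DataFrame  # columns: gene_id, x, y, r, cobound, cooperative
    radius_threshold: float
    alpha: float
    require_concordance: bool

    @property
    def cooperative_genes(self) -> set[str]:
        return set(self.data.loc[self.data["cooperative"], "gene_id"])

    def summary(self) -> dict:
        return {
            "n_genes": int(len(self.data)),
            "n_cobound": int(self.data["cobound"].sum()),
            "n_cooperative": int(self.data["cooperative"].sum()),
            "radius_threshold": self.radius_threshold,
            "alpha": self.alpha,
        }


def call_cooperative(
    cobound_targets: set[str],
    shrunk_a: ShrunkenFC,
    shrunk_b: ShrunkenFC,
    alpha: float = 0.05,
    require_concordance: bool = False,
) -> CooperationResult:
    """Call cooperatively regulated genes from the paired knockdown contrasts.

    A gene is cooperative iff it is assigned to a co-bound region (nearest-TSS
    gating) AND its standardized radius exceeds the independence-null
    threshold; direction concordance between the two contrasts is reported
    and, optionally, required. The region test is a single geometric gate, not
    per-gene p-values, so no multiple-testing layer is applied.
    """
    a = shrunk_a.shrunken_map()
    b = shrunk_b.shrunken_map()
    genes = sorted(set(a) & set(b))
    if not genes:
        raise ValueError("no genes shared by the two shrunken tables")
    if not cobound_targets:
        logger.warning("empty co-bound target set: no gene can be called cooperative")
    x = np.array([a[g] for g in genes])
    y = np.array([b[g] for g in genes])
    region = independence_region(x, y, alpha)

    cobound = np.array([g in cobound_targets for g in genes])
    outside = region.radius > region.radius_threshold
    cooperative = cobound & outside
    concordant = x * y > 0
    if require_concordance:
        cooperative = cooperative & concordant

    df = pd.DataFrame(
        {
            "gene_id": genes,
            "x": x,
            "y": y,
            "r": region.radius,
            "cobound": cobound,
            "concordant": concordant,
            "cooperative": cooperative,
        }
    )
    return CooperationResult(df, region.radius_threshold, alpha, require_concordance)
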