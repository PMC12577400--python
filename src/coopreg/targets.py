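"""Direct/indirect classification of knockdown DEGs against ChIP target genes,
and cross-cell-line coherence of the resulting direct-target programs.

A gene is a *direct* target when it is both significantly deregulated in the
knockdown contrast and assigned (nearest TSS) to a filtered binding site of
the TF; significant-but-unbound genes are *indirect* (secondary effects).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEGTable",
    "SignificantDEGs",
    "TargetClassification",
    "CoherenceReport",
    "read_deg_table",
    "significant_degs",
    "classify_targets",
    "cross_line_coherence",
]

logger = logging.getLogger(__name__)

DEG_COLUMNS = ("gene_id", "log2fc", "se", "padj")


@dataclass
class DEGTable:
    """Per-gene log2 fold-change, standard error and adjusted p for one contrast."""

    data: pd.DataFrame
    contrast: str = ""

    def __post_init__(self) -> None:
        for col in DEG_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"DEG table missing column {col!r}")
        if self.data["gene_id"].duplicated().any():
            dupes = self.data.loc[self.data["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene_ids in DEG table: {dupes[:5]}")
        padj = self.data["padj"]
        if ((padj < 0) | (padj > 1)).any():
            raise ValueError("padj values must lie in [0, 1]")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> set[str]:
        return set(self.data["gene_id"])

    def lfc_map(self) -> dict[str, float]:
        return dict(zip(self.data["gene_id"], self.data["log2fc"]))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_deg_table(path: str | Path, contrast: str = "") -> DEGTable:
    """Read a DEG TSV. If only raw p-values (``pval``) are present,
    Benjamini-Hochberg adjustment is applied and logged — raw and adjusted
    significance are never silently mixed."""
    df = pd.read_csv(path, sep="\t")
    if "padj" not in df.columns:
        if "pval" not in df.columns:
            raise ValueError(f"{path}: need a padj or pval column")
        logger.info("%s: no padj column; applying Benjamini-Hochberg to pval", path)
        df["padj"] = multipletests(df["pval"], method="fdr_bh")[1]
    return DEGTable(df, contrast=contrast or str(path))


@dataclass
class SignificantDEGs:
    """Significant genes partitioned by fold-change sign."""

    up: set[str]
    down: set[str]
    zero_lfc: set[str]  # significant but log2fc == 0: flagged, in neither class
    alpha: float

    @property
    def genes(self) -> set[str]:
        return self.up | self.down


def significant_degs(table: DEGTable, alpha: float = 0.1) -> SignificantDEGs:
    """Genes with adjusted p <= alpha, split into up/down by log2FC sign.

    The boundary is inclusive (padj == alpha is significant). Significant
    genes with exactly zero fold-change are flagged and excluded from both
    sign classes.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    sig = table.data[table.data["padj"] <= alpha]
    up = set(sig.loc[sig["log2fc"] > 0, "gene_id"])
    down = set(sig.loc[sig["log2fc"] < 0, "gene_id"])
    zero = set(sig.loc[sig["log2fc"] == 0, "gene_id"])
    if zero:
        logger.warning("%d significant genes with log2fc == 0 excluded from sign classes", len(zero))
    return SignificantDEGs(up, down, zero, alpha)


@dataclass
class TargetClassification:
    """Partition of the significant DEG set into direct and indirect targets."""

    direct: set[str]
    indirect: set[str]
    lfc: dict[str, float]
    n_significant: int
    contrast: str = ""

    @property
    def fraction_direct(self) -> float:
        return len(self.direct) / self.n_significant

    def summary(self) -> dict:
        return {
            "contrast": self.contrast,
            "n_significant": self.n_significant,
            "n_direct": len(self.direct),
            "n_indirect": len(self.indirect),
            "fraction_direct": self.fraction_direct,
        }


def classify_targets(
    degs: SignificantDEGs,
    chip_targets: set[str],
    table: Optional[DEGTable] = None,
    contrast: str = "",
) -> TargetClassification:
    """Intersect the significant DEG set with the ChIP target-gene set.

    ChIP targets absent from the DEG universe are bound-but-unchanged and are
    ignored: direct means bound AND deregulated. The direct fraction is
    reported over the significant DEG count (its explicit denominator).
    """
    sig = degs.genes
    if not sig:
        raise ValueError("empty significant DEG set")
    direct = sig & chip_targets
    indirect = sig - chip_targets
    lfc = {}
    if table is not None:
        full = table.lfc_map()
        lfc = {g: full[g] for g in sig if g in full}
    return TargetClassification(direct, indirect, lfc, len(sig), contrast=contrast)


@dataclass
class CoherenceReport:
    """Direction agreement of shared direct targets across two cell lines."""

    common: set[str]
    coherent_up: set[str]
    coherent_down: set[str]
    discordant: set[str]

    @property
    def coherent_fraction(self) -> float:
        return (len(self.coherent_up) + len(self.coherent_down)) / len(self.common)

    def summary(self) -> dict:
        return {
            "n_common": len(self.common),
            "n_coherent_up": len(self.coherent_up),
            "n_coherent_down": len(self.coherent_down),
            "n_discordant": len(self.discordant),
        }


def cross_line_coherence(
    class_a: TargetClassification, class_b: TargetClassification
) -> CoherenceReport:
    """Shared direct targets split by fold-change concordance in the two lines."""
    common = class_a.direct & class_b.direct
    up, down, disc = set(), set(), set()
    for g in common:
        fa, fb = class_a.lfc.get(g), class_b.lfc.get(g)
        if fa is None or fb is None:
            raise ValueError(f"gene {g!r} lacks a log2fc in one classification")
        if fa > 0 and fb > 0:
            up.add(g)
        elif fa < 0 and fb < 0:
            down.add(g)
        else:
            disc.add(g)
    return CoherenceReport(common, up, down, disc)
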