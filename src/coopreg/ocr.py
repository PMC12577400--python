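"""Mito-stress-test summary metrics from oxygen consumption rate (OCR) traces.

The protocol injects oligomycin (blocks ATP synthase), FCCP (uncouples the
membrane potential) and rotenone + antimycin A (shuts down the electron
transport chain) in that order. Derived metrics, after normalizing OCR per
cell:

    non_mito   = OCR after rotenone + antimycin A
    basal      = OCR before oligomycin  - non_mito
    maximal    = OCR after FCCP         - non_mito
    atp_linked = OCR before oligomycin  - OCR after oligomycin
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["OCRTrace", "MitoStressSummary", "summarize_trace", "fold_change",
           "read_ocr_table", "write_ocr_table", "PHASES"]

PHASES = ("baseline", "oligomycin", "fccp", "rot_aa")
METRICS = ("basal", "atp_linked", "maximal", "non_mito")


@dataclass
class OCRTrace:
    """One well's OCR time course: (time, value, phase) rows plus metadata."""

    time: np.ndarray
    ocr: np.ndarray
    phase: list[str]
    cell_count: int
    sample: str = ""
    condition: str = "CTRL"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        if not (len(self.time) == len(self.ocr) == len(self.phase)):
            raise ValueError("time, ocr and phase must have equal length")
        if self.cell_count <= 0:
            raise ValueError("cell_count must be positive")
        seen = [p for i, p in enumerate(self.phase) if i == 0 or p != self.phase[i - 1]]
        expected = [p for p in PHASES if p in seen]
        if seen != expected or set(seen) != set(PHASES):
            missing = [p for p in PHASES if p not in set(self.phase)]
            if missing:
                raise ValueError(f"missing phase(s): {missing}")
            raise ValueError(
                f"phases must appear once each in protocol order {PHASES}, got {seen}"
            )

    def phase_values(self, phase: str) -> np.ndarray:
        mask = np.array([p == phase for p in self.phase])
        return self.ocr[mask] / self.cell_count


@dataclass
class MitoStressSummary:
    """Per-cell respiration metrics for one well."""

    basal: float
    atp_linked: float
    maximal: float
    non_mito: float
    sample: str = ""
    condition: str = "CTRL"

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}


def summarize_trace(trace: OCRTrace, baseline_stat: str = "mean") -> MitoStressSummary:
    """Compute basal, ATP-linked, maximal and non-mitochondrial OCR per cell.

    The pre-injection representative of each phase is its mean by default;
    ``baseline_stat="last_point"`` uses each phase's final measurement instead
    (the two conventions differ only under within-phase drift).
    """
    if baseline_stat not in ("mean", "last_point"):
        raise ValueError(f"unknown baseline_stat {baseline_stat!r}")

    def rep(phase: str) -> float:
        v = trace.phase_values(phase)
        return float(v.mean() if baseline_stat == "mean" else v[-1])

    non_mito = rep("rot_aa")
    baseline = rep("baseline")
    return MitoStressSummary(
        basal=baseline - non_mito,
        atp_linked=baseline - rep("oligomycin"),
        maximal=rep("fccp") - non_mito,
        non_mito=non_mito,
        sample=trace.sample,
        condition=trace.condition,
    )


def fold_change(
    kd: MitoStressSummary, ctrl: MitoStressSummary
) -> dict[str, Optional[float]]:
    """Per-metric KD / CTRL ratios; a zero control yields None, never infinity."""
    out: dict[str, Optional[float]] = {}
    for metric in METRICS:
        denom = getattr(ctrl, metric)
        out[metric] = None if denom == 0 else getattr(kd, metric) / denom
    return out


def read_ocr_table(path: str | Path) -> list[OCRTrace]:
    """Read a long-format trace TSV (time, ocr, phase, well, condition, cell_count),
    one OCRTrace per well, preserving row order within wells."""
    df = pd.read_csv(path, sep="\t")
    needed = {"time", "ocr", "phase", "well", "condition", "cell_count"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    traces = []
    for well, grp in df.groupby("well", sort=True):
        traces.append(
            OCRTrace(
                time=grp["time"].to_numpy(),
                ocr=grp["ocr"].to_numpy(),
                phase=list(grp["phase"]),
                cell_count=int(grp["cell_count"].iloc[0]),
                sample=str(well),
                condition=str(grp["condition"].iloc[0]),
            )
        )
    return traces


def write_ocr_table(traces: Sequence[OCRTrace], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("time\tocr\tphase\twell\tcondition\tcell_count\n")
        for t in traces:
            for ti, oi, pi in zip(t.time, t.ocr, t.phase):
                fh.write(
                    f"{ti:.6g}\t{oi:.6g}\t{pi}\t{t.sample}\t{t.condition}\t{t.cell_count}\n"
                )
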