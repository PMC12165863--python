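"""Somatic repeat-instability metrics from fragment-analysis peak data.

A fragment-analysis trace (GeneMapper peak heights, or densitometry of a
long agarose gel for very large GAA tracts) is reduced to a list of
(repeat size, intensity) peaks.  Somatic instability in a tissue is scored
against the modal allele of a stable reference tissue (tail) as the
peak-height-weighted mean signed change in repeat units:

    index = sum(h_i * delta_i) / sum(h_i),  delta_i = size_i - modal_ref

over peaks retained after (1) a relative peak-height threshold (5% of the
tallest peak for capillary traces, 10% for gel densitometry), (2) a
contraction cap discarding delta < -cap (default 40 repeat units, which
removes PCR/fragmentation artifacts far below the main allele), and
(3) a mode filter: expansion index keeps delta >= 0, contraction index
keeps delta <= 0, the plain instability index keeps all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

__all__ = [
    "PeakTrace",
    "Mode",
    "InstabilityResult",
    "modal_allele",
    "qc_trace",
    "instability_index",
    "normalize_allele_frequencies",
]


class Mode(str, Enum):
    BOTH = "both"
    EXPANSION = "expansion"
    CONTRACTION = "contraction"


@dataclass
class PeakTrace:
    """Peaks of one sample's trace, sizes in repeat units (or nt upstream
    of calibration), heights in arbitrary intensity units."""

    peaks: list[tuple[float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("trace must contain at least one peak")
        sizes = [s for s, _ in self.peaks]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("peak sizes must be strictly increasing")
        if any(h < 0 for _, h in self.peaks):
            raise ValueError("peak heights must be >= 0")

    @property
    def sizes(self) -> list[float]:
        return [s for s, _ in self.peaks]

    @property
    def heights(self) -> list[float]:
        return [h for _, h in self.peaks]


@dataclass
class InstabilityResult:
    reference_modal: float
    mode: Mode
    threshold_fraction: float
    contraction_cap: float
    retained_peaks: int
    index: float  # weighted mean repeat-unit change; nan when nothing retained

    @property
    def empty(self) -> bool:
        return self.retained_peaks == 0


def modal_allele(trace: PeakTrace) -> tuple[float, float]:
    """The tallest peak; ties broken toward the smaller size."""
    return max(trace.peaks, key=lambda p: (p[1], -p[0]))


def qc_trace(trace: PeakTrace, min_modal_height: float | None = 1000.0) -> bool:
    """Trace quality control: modal peak height must reach the threshold.

    ``None`` disables QC (gel densitometry has no comparable intensity
    scale, so the capillary default of 1,000 does not apply there).
    """
    if min_modal_height is None:
        return True
    return modal_allele(trace)[1] >= min_modal_height


def instability_index(
    trace: PeakTrace,
    reference_modal: float,
    threshold_fraction: float = 0.05,
    mode: Mode | str = Mode.BOTH,
    contraction_cap: float = 40.0,
) -> InstabilityResult:
    """Peak-height-weighted mean repeat-size change vs. a reference modal.

    The height threshold is relative to the tallest peak of the analyzed
    trace; the size change is relative to the reference tissue's modal
    allele.  A peak exactly at the reference modal (delta = 0) is retained
    by both the expansion (delta >= 0) and contraction (delta <= 0) modes
    and contributes zero to either index.
    """
    mode = Mode(mode)
    if not 0.0 <= threshold_fraction <= 1.0:
        raise ValueError("threshold fraction must be in [0, 1]")
    max_height = max(trace.heights)
    retained: list[tuple[float, float]] = []
    for size, height in trace.peaks:
        if height < threshold_fraction * max_height:
            continue
        delta = size - reference_modal
        if delta < -contraction_cap:
            continue
        if mode is Mode.EXPANSION and delta < 0:
            continue
        if mode is Mode.CONTRACTION and delta > 0:
            continue
        retained.append((delta, height))

    total = sum(h for _, h in retained)
    if not retained or total == 0:
        index = math.nan
    else:
        index = sum(d * h for d, h in retained) / total
    return InstabilityResult(
        reference_modal=reference_modal,
        mode=mode,
        threshold_fraction=threshold_fraction,
        contraction_cap=contraction_cap,
        retained_peaks=len(retained),
        index=index,
    )


def normalize_allele_frequencies(trace: PeakTrace) -> list[tuple[float, float]]:
    """Peak heights relative to the modal allele (modal frequency = 1)."""
    _, modal_height = modal_allele(trace)
    if modal_height == 0:
        raise ValueError("modal peak height is zero; cannot normalize")
    return [(size, height / modal_height) for size, height in trace.peaks]
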