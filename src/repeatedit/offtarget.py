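"""Off-target editing quantification from treated/untreated pileups.

For each nominated locus the per-position edit frequency (alt base count /
depth in the treated sample) is measured at positions that (a) carry the
strategy's editable reference base, (b) exceed the coverage floor in both
samples (loci with any position at <= 30 reads are removed), and (c) show
<= 2.5% alt frequency in the untreated control (higher background marks a
pre-existing polymorphism, not editing).  Per-position frequencies are
combined into the probability that the locus acquired at least one edit
under position independence:

    P(locus edited) = 1 - prod_i (1 - p_i)

Loci are called "detected" when the background-subtracted probability
exceeds 0.5% and "substantial" at >= 5%.  Spacer/target mismatches are
binned by PAM-relative protospacer position (A: 1-5 PAM-proximal,
B: 6-10, C: 11-20 PAM-distal), and codon-level consequences of an edit are
classified with the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "LocusStatus",
    "LocusEditing",
    "MismatchProfile",
    "CodingEffect",
    "position_frequencies",
    "locus_probability",
    "classify_locus",
    "evaluate_locus",
    "classify_mismatches",
    "coding_effect",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class LocusStatus(str, Enum):
    FILTERED_LOW_COVERAGE = "filtered-low-coverage"
    BACKGROUND_EXCLUDED_ALL = "background-excluded-all"
    SUBSTANTIAL = "substantial"
    DETECTED = "detected"
    BELOW_DETECTION = "below-detection"


@dataclass
class LocusEditing:
    locus: str
    evaluable_positions: int
    frequencies: list[float]
    probability: float
    untreated_probability: float
    status: LocusStatus


@dataclass
class MismatchProfile:
    """Spacer/target mismatch counts binned by PAM-relative position."""

    category_a: int  # protospacer positions 1-5, PAM-proximal
    category_b: int  # positions 6-10
    category_c: int  # positions 11-20, PAM-distal

    @property
    def total(self) -> int:
        return self.category_a + self.category_b + self.category_c


class CodingEffect(str, Enum):
    NONE = "none"
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"


def position_frequencies(
    treated: pd.DataFrame,
    untreated: pd.DataFrame,
    edit: tuple[str, str] = ("A", "G"),
    strand: str = "+",
    min_coverage: int = 30,
    background_cutoff: float = 0.025,
) -> tuple[list[float], list[float], LocusStatus | None]:
    """Per-position edit frequencies at one locus, background-filtered.

    ``treated``/``untreated`` are per-position base-count frames
    (columns position, A, C, G, T, depth) covering the same positions.
    ``edit`` is the strategy's conversion on the plus strand (C->T for a
    CBE, A->G for an ABE); it is complemented when the spacer maps to the
    minus strand.  Returns (treated freqs, untreated freqs, early status):
    the status is FILTERED_LOW_COVERAGE when any position is at
    <= min_coverage reads, BACKGROUND_EXCLUDED_ALL when every editable
    position fails the background filter, else None.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    ref, alt = (edit if strand == "+"
                else (_COMPLEMENT[edit[0]], _COMPLEMENT[edit[1]]))

    t = treated.set_index("position")
    u = untreated.set_index("position")
    if set(t.index) != set(u.index):
        raise ValueError("treated and untreated pileups cover different positions")
    u = u.loc[t.index]

    if (t["depth"] <= min_coverage).any() or (u["depth"] <= min_coverage).any():
        return [], [], LocusStatus.FILTERED_LOW_COVERAGE

    # Editable positions: untreated consensus base equals the edit's
    # reference base (the pileup schema carries no reference column).
    consensus = u[["A", "C", "G", "T"]].idxmax(axis=1)
    editable = consensus == ref
    if not editable.any():
        return [], [], LocusStatus.BACKGROUND_EXCLUDED_ALL

    u_freq = (u[alt] / u["depth"])[editable]
    keep = u_freq <= background_cutoff
    if not keep.any():
        return [], [], LocusStatus.BACKGROUND_EXCLUDED_ALL

    positions = u_freq.index[keep]
    t_freqs = (t.loc[positions, alt] / t.loc[positions, "depth"]).tolist()
    u_freqs = u_freq[keep].tolist()
    return t_freqs, u_freqs, None


def locus_probability(frequencies) -> float:
    """P(at least one edit) assuming independent positions."""
    freqs = np.asarray(list(frequencies), dtype=float)
    if freqs.size == 0:
        return 0.0
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("frequencies must be in [0, 1]")
    return float(1.0 - np.prod(1.0 - freqs))


def classify_locus(
    probability: float,
    untreated_probability: float = 0.0,
    detection_threshold: float = 0.005,
    substantial_threshold: float = 0.05,
) -> LocusStatus:
    """Detection calls on the background-subtracted locus probability."""
    excess = probability - untreated_probability
    if excess >= substantial_threshold:
        return LocusStatus.SUBSTANTIAL
    if excess > detection_threshold:
        return LocusStatus.DETECTED
    return LocusStatus.BELOW_DETECTION


def evaluate_locus(
    locus: str,
    treated: pd.DataFrame,
    untreated: pd.DataFrame,
    edit: tuple[str, str] = ("A", "G"),
    strand: str = "+",
    min_coverage: int = 30,
    background_cutoff: float = 0.025,
    detection_threshold: float = 0.005,
    substantial_threshold: float = 0.05,
) -> LocusEditing:
    """Full per-locus evaluation: filter, combine, classify."""
    t_freqs, u_freqs, early = position_frequencies(
        treated, untreated, edit, strand, min_coverage, background_cutoff
    )
    if early is not None:
        return LocusEditing(locus, 0, [], 0.0, 0.0, early)
    prob = locus_probability(t_freqs)
    u_prob = locus_probability(u_freqs)
    status = classify_locus(prob, u_prob, detection_threshold, substantial_threshold)
    return LocusEditing(locus, len(t_freqs), t_freqs, prob, u_prob, status)


def classify_mismatches(spacer: str, target: str) -> MismatchProfile:
    """Bin spacer/target mismatches by protospacer position.

    Both sequences are 20-mers written with the PAM-proximal end first:
    string index 0 is protospacer position 1.
    """
    spacer, target = spacer.upper(), target.upper()
    if len(spacer) != 20 or len(target) != 20:
        raise ValueError("spacer and target must both be 20-mers")
    a = b = c = 0
    for pos0, (s, t) in enumerate(zip(spacer, target)):
        if s == t:
            continue
        position = pos0 + 1
        if position <= 5:
            a += 1
        elif position <= 10:
            b += 1
        else:
            c += 1
    return MismatchProfile(a, b, c)


def coding_effect(reference_codon: str, edited_codon: str) -> CodingEffect:
    """Consequence of a codon change under the standard genetic code."""
    ref, alt = reference_codon.upper(), edited_codon.upper()
    for codon in (ref, alt):
        if len(codon) != 3 or any(b not in "ACGT" for b in codon):
            raise ValueError(f"invalid codon {codon!r}")
    if ref == alt:
        return CodingEffect.NONE
    ref_aa = str(Seq(ref).translate())
    alt_aa = str(Seq(alt).translate())
    if ref_aa == alt_aa:
        return CodingEffect.SYNONYMOUS
    if alt_aa == "*":
        return CodingEffect.NONSENSE
    return CodingEffect.MISSENSE
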