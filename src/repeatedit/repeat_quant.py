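"""Triplet-level quantification of base-editing outcomes in repeat tracts.

Amplicon reads covering a trinucleotide repeat (TNR) locus are anchored at
the repeat flanks, the tract between the anchors is decomposed into in-frame
triplets, and each triplet is classified against an IUPAC degenerate pattern
describing every outcome the base-editing strategy can produce.  For a
cytosine base editor (CBE) acting on a CAG tract through the opposite-strand
CTG spacer the pattern is YAR (C/T, A, A/G): CAG is the pure repeat, CAA the
intended synonymous interruption, and TAG/TAA are opposite-strand byproducts
that create stop codons.  For an adenine base editor (ABE) acting on a GAA
tract the pattern is GRR (G, A/G, A/G): GAA pure, GAG/GGA/GGG intended.

Sample-level summaries expose the quantities the downstream extrapolation
model consumes: the edited-read fraction, the per-triplet interrupted
fraction ``f``, the mean interruption count per edited read ``n_i`` and the
mean interrupted tract fraction ``f_i``.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Iterable, Sequence

__all__ = [
    "AnchorStatus",
    "TripletClass",
    "RepeatSpec",
    "ReadCall",
    "EditingSummary",
    "CAG_CBE",
    "GAA_ABE",
    "expand_iupac",
    "locate_tract",
    "classify_triplet",
    "call_read",
    "summarize",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def expand_iupac(pattern: str) -> frozenset[str]:
    """All concrete DNA k-mers matched by an IUPAC degenerate pattern."""
    try:
        choices = [_IUPAC[b] for b in pattern.upper()]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc} in pattern {pattern!r}") from None
    return frozenset("".join(p) for p in product(*choices))


class AnchorStatus(str, Enum):
    BOTH = "both"
    LEFT_ONLY = "left-only"
    RIGHT_ONLY = "right-only"
    UNANCHORED = "unanchored"


class TripletClass(str, Enum):
    PURE = "pure"
    INTENDED = "intended"
    BYPRODUCT = "byproduct"
    OTHER = "other"


@dataclass(frozen=True)
class RepeatSpec:
    """Definition of a repeat locus and the edited-allele pattern.

    Parameters
    ----------
    name : str
        Label used in reports (e.g. ``"cag-cbe"``).
    pure : str
        The pure repeat triplet (``CAG``, ``GAA``).
    pattern : str
        IUPAC 3-mer describing every triplet the strategy can produce,
        pure included (``YAR``, ``GRR``).
    byproducts : frozenset of str
        Triplets inside the pattern that arise from opposite-strand
        deamination rather than the intended edit (``{TAG, TAA}`` for the
        CAG CBE strategy; empty for the GAA ABE strategy).
    left_flank, right_flank : str
        Genomic sequence flanking the tract; the anchor k-mers are drawn
        from the tract-proximal ends of these.
    anchor_length : int
        Exact-match anchor size in nt (>= 6).
    """

    name: str
    pure: str
    pattern: str
    byproducts: frozenset[str] = frozenset()
    left_flank: str = ""
    right_flank: str = ""
    anchor_length: int = 12

    def __post_init__(self) -> None:
        if len(self.pure) != 3 or len(self.pattern) != 3:
            raise ValueError("pure triplet and pattern must be 3-mers")
        if self.anchor_length < 6:
            raise ValueError("anchor length must be >= 6")
        matches = expand_iupac(self.pattern)
        if self.pure not in matches:
            raise ValueError(
                f"pure triplet {self.pure} does not match pattern {self.pattern}"
            )
        if self.byproducts & {self.pure}:
            raise ValueError("pure triplet cannot be a byproduct")
        intended = matches - {self.pure} - self.byproducts
        if intended & self.byproducts:  # pragma: no cover - disjoint by set algebra
            raise ValueError("intended and byproduct sets overlap")
        object.__setattr__(self, "_intended", frozenset(intended))

    @property
    def intended(self) -> frozenset[str]:
        """Triplets counted as intended interruptions."""
        return self._intended  # type: ignore[attr-defined]

    @property
    def left_anchor(self) -> str:
        return self.left_flank[-self.anchor_length:]

    @property
    def right_anchor(self) -> str:
        return self.right_flank[: self.anchor_length]


# Shipped strategy specs.  The flanks are synthetic amplicon context used
# by the simulator and tests (real runs supply the locus's own flanks);
# they are chosen to contain no pattern-matching triplet in any frame, so
# a flank remnant in a partially anchored read can never masquerade as
# tract signal.
CAG_CBE = RepeatSpec(
    name="cag-cbe",
    pure="CAG",
    pattern="YAR",
    byproducts=frozenset({"TAG", "TAA"}),
    left_flank="TTTACTTGCTGTGTCCACCCCAT",
    right_flank="CGGACTGGCATTTTTATTACACT",
)

GAA_ABE = RepeatSpec(
    name="gaa-abe",
    pure="GAA",
    pattern="GRR",
    byproducts=frozenset(),
    left_flank="CTCTGCCAAACTCCAGCGCGGTC",
    right_flank="AGTTCCATCACCCTAAGTAACCG",
)

SHIPPED_SPECS = {s.name: s for s in (CAG_CBE, GAA_ABE)}


@dataclass
class ReadCall:
    """Per-read triplet classification."""

    read_id: str
    anchor_status: AnchorStatus
    triplet_count: int = 0
    interruption_count: int = 0
    byproduct_count: int = 0
    other_count: int = 0
    pure_count: int = 0
    has_indel_signal: bool = False
    triplet_types: Counter = field(default_factory=Counter)

    @property
    def anchored(self) -> bool:
        return self.anchor_status is not AnchorStatus.UNANCHORED

    @property
    def edited(self) -> bool:
        """Edited means >= 1 intended interruption; byproduct-only reads
        are reported separately."""
        return self.interruption_count > 0


@dataclass
class EditingSummary:
    """Sample-level editing statistics over anchored, length-filtered reads."""

    aligned_reads: int
    edited_reads: int
    edited_fraction: float
    byproduct_read_fraction: float
    interruption_histogram: dict[int, int]
    mean_interruptions: float          # n_i over edited reads
    median_interruptions: float
    triplet_fraction_interrupted: float   # f over all aligned reads
    mean_interrupted_tract_fraction: float  # f_i over edited reads
    purity_ratio: float                # intended : byproduct triplets, X:1
    triplet_type_counts: dict[str, int]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["interruption_histogram"] = {
            str(k): v for k, v in sorted(self.interruption_histogram.items())
        }
        return d


def locate_tract(bases: str, spec: RepeatSpec) -> tuple[AnchorStatus, str, int]:
    """Anchor a read at the repeat flanks and extract the tract.

    Returns ``(status, tract, frame_origin)`` where ``frame_origin`` is 0
    when triplets are counted from the left edge of the tract and
    ``len(tract) % 3`` when only the right anchor was found (triplets are
    then in frame with the right edge).

    Anchoring is an exact-match search for the anchor-length suffix of the
    left flank (first occurrence from the read start) and prefix of the
    right flank (first occurrence from the read end).  Reads with more than
    20% N are treated as unanchored.
    """
    bases = bases.upper()
    if len(bases) < spec.anchor_length:
        return AnchorStatus.UNANCHORED, "", 0
    if bases.count("N") > 0.2 * len(bases):
        return AnchorStatus.UNANCHORED, "", 0

    left = bases.find(spec.left_anchor) if spec.left_flank else -1
    right = bases.rfind(spec.right_anchor) if spec.right_flank else -1
    tract_start = left + spec.anchor_length if left >= 0 else None

    if left >= 0 and right >= 0 and right >= tract_start:
        tract = bases[tract_start:right]
        return AnchorStatus.BOTH, tract, 0
    if left >= 0:
        tract = bases[tract_start:]
        return AnchorStatus.LEFT_ONLY, tract, 0
    if right >= 0:
        tract = bases[:right]
        return AnchorStatus.RIGHT_ONLY, tract, len(tract) % 3
    return AnchorStatus.UNANCHORED, "", 0


def classify_triplet(triplet: str, spec: RepeatSpec) -> TripletClass:
    """Classify one in-frame triplet against the strategy's pattern."""
    if len(triplet) != 3:
        raise ValueError(f"triplet must have length 3, got {triplet!r}")
    triplet = triplet.upper()
    if any(b not in "ACGTN" for b in triplet):
        raise ValueError(f"triplet alphabet must be ACGTN, got {triplet!r}")
    if "N" in triplet:
        return TripletClass.OTHER
    if triplet == spec.pure:
        return TripletClass.PURE
    if triplet in spec.intended:
        return TripletClass.INTENDED
    if triplet in spec.byproducts:
        return TripletClass.BYPRODUCT
    return TripletClass.OTHER


def call_read(read_id: str, bases: str, spec: RepeatSpec) -> ReadCall:
    """Anchor a read, decompose its tract into triplets and count classes.

    The tract is read in frame from the frame origin; a trailing partial
    triplet is dropped.  A both-anchored tract whose length is not a
    multiple of 3 carries an indel signal (repeat slippage or sequencing
    indel) and is flagged.
    """
    status, tract, origin = locate_tract(bases, spec)
    call = ReadCall(read_id=read_id, anchor_status=status)
    if status is AnchorStatus.UNANCHORED:
        return call
    call.has_indel_signal = status is AnchorStatus.BOTH and len(tract) % 3 != 0
    for i in range(origin, len(tract) - 2, 3):
        triplet = tract[i : i + 3]
        cls = classify_triplet(triplet, spec)
        call.triplet_count += 1
        call.triplet_types[triplet] += 1
        if cls is TripletClass.PURE:
            call.pure_count += 1
        elif cls is TripletClass.INTENDED:
            call.interruption_count += 1
        elif cls is TripletClass.BYPRODUCT:
            call.byproduct_count += 1
        else:
            call.other_count += 1
    return call


def summarize(
    calls: Iterable[ReadCall],
    spec: RepeatSpec,
    min_triplets: int = 5,
) -> EditingSummary:
    """Aggregate read calls into sample-level editing statistics.

    Unanchored reads and reads covering fewer than ``min_triplets``
    triplets are excluded from every denominator.

    Raises
    ------
    ValueError
        If no read survives filtering (an empty summary would divide by
        zero and hide a failed run).
    """
    kept = [c for c in calls if c.anchored and c.triplet_count >= min_triplets]
    if not kept:
        raise ValueError("no aligned reads after filtering; cannot summarize")

    aligned = len(kept)
    edited = [c for c in kept if c.edited]
    total_triplets = sum(c.triplet_count for c in kept)
    total_intended = sum(c.interruption_count for c in kept)
    total_byproduct = sum(c.byproduct_count for c in kept)
    byproduct_reads = sum(1 for c in kept if c.byproduct_count > 0)

    histogram = Counter(c.interruption_count for c in edited)
    type_counts: Counter[str] = Counter()
    for c in kept:
        type_counts.update(c.triplet_types)

    if edited:
        n_i = statistics.fmean(c.interruption_count for c in edited)
        med = float(statistics.median(c.interruption_count for c in edited))
        f_i = statistics.fmean(
            c.interruption_count / c.triplet_count for c in edited
        )
    else:
        n_i = med = f_i = 0.0

    purity = (
        total_intended / total_byproduct if total_byproduct else float("inf")
    )

    return EditingSummary(
        aligned_reads=aligned,
        edited_reads=len(edited),
        edited_fraction=len(edited) / aligned,
        byproduct_read_fraction=byproduct_reads / aligned,
        interruption_histogram=dict(histogram),
        mean_interruptions=n_i,
        median_interruptions=med,
        triplet_fraction_interrupted=(
            total_intended / total_triplets if total_triplets else 0.0
        ),
        mean_interrupted_tract_fraction=f_i,
        purity_ratio=purity,
        triplet_type_counts=dict(type_counts),
    )


def quantify_reads(
    reads: Iterable[tuple[str, str, str]],
    spec: RepeatSpec,
    min_triplets: int = 5,
) -> tuple[list[ReadCall], EditingSummary]:
    """Convenience: call every read and summarize in one pass."""
    calls = [call_read(rid, bases, spec) for rid, bases, _ in reads]
    return calls, summarize(calls, spec, min_triplets=min_triplets)
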