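"""Synthetic data with the statistical structure the pipeline assumes.

Every pipeline stage can be exercised end to end without external data:

* :func:`simulate_alleles` draws repeat alleles with a configurable length
  distribution and per-triplet interruption process (i.i.d. per triplet, or
  clustered: a fixed interruption count per edited allele), with a
  transduced fraction mimicking incomplete delivery and opposite-strand
  byproduct edits at a configurable rate.  Ground-truth per-triplet labels
  are emitted alongside the sequences.
* :func:`simulate_reads` turns alleles into amplicon reads (left flank +
  tract, right flank when the read is long enough) with uniform
  substitution errors, so the quantifier's anchoring and triplet calls can
  be checked against truth.
* :func:`simulate_trace` builds fragment-analysis peak traces with
  expansion/contraction mass around a modal allele.
* :func:`simulate_pileups` builds treated/untreated per-position count
  tables with binomial sampling and optional background polymorphisms.

All operations take an explicit seed and use a private NumPy generator;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instability import PeakTrace
from .repeat_quant import RepeatSpec, TripletClass

__all__ = [
    "AlleleModel",
    "TraceModel",
    "SimulatedAllele",
    "simulate_alleles",
    "simulate_reads",
    "simulate_trace",
    "simulate_pileups",
]

_BASES = np.array(list("ACGT"))


@dataclass
class AlleleModel:
    """Editing regime for simulated repeat alleles.

    Defaults emulate an efficiently delivered in vitro editing experiment
    on a mid-length tract: a 20-repeat window, full transduction, a 5%
    per-triplet edit probability and a 2% byproduct share of edits.
    """

    spec: RepeatSpec
    modal_length: int = 20
    length_sd: float = 0.0
    transduced_fraction: float = 1.0
    p_edit: float = 0.05
    byproduct_fraction: float = 0.02
    clustered: bool = False
    interruptions_per_edited: int = 3
    edited_fraction_clustered: float = 0.5

    def __post_init__(self) -> None:
        for name in ("transduced_fraction", "p_edit", "byproduct_fraction",
                     "edited_fraction_clustered"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.modal_length < 1:
            raise ValueError("modal_length must be >= 1")


@dataclass
class TraceModel:
    """Fragment-trace regime: a modal allele plus expansion/contraction mass."""

    reference_modal: int = 100
    expansion_fraction: float = 0.0
    expansion_shift: int = 6
    contraction_fraction: float = 0.0
    contraction_shift: int = 6
    noise_level: float = 0.0
    total_intensity: float = 10000.0

    def __post_init__(self) -> None:
        if self.expansion_fraction + self.contraction_fraction > 1.0:
            raise ValueError("expansion and contraction mass fractions sum above 1")
        if min(self.expansion_fraction, self.contraction_fraction) < 0:
            raise ValueError("mass fractions must be >= 0")
        if self.expansion_shift < 0 or self.contraction_shift < 0:
            raise ValueError("shifts are magnitudes; must be >= 0")


@dataclass
class SimulatedAllele:
    sequence: str                  # tract only, no flanks
    labels: list[TripletClass]     # ground truth per triplet
    transduced: bool

    @property
    def n_interruptions(self) -> int:
        return sum(1 for l in self.labels if l is TripletClass.INTENDED)

    @property
    def edited(self) -> bool:
        return self.n_interruptions > 0


def _draw_lengths(n: int, model: AlleleModel, rng: np.random.Generator) -> np.ndarray:
    if model.length_sd == 0:
        return np.full(n, model.modal_length, dtype=int)
    lengths = np.rint(rng.normal(model.modal_length, model.length_sd, n)).astype(int)
    return np.maximum(lengths, 1)


def simulate_alleles(
    n: int, model: AlleleModel, seed: int = 0
) -> list[SimulatedAllele]:
    """Draw ``n`` alleles with ground-truth per-triplet labels.

    In the i.i.d. regime each triplet of a transduced allele is edited
    independently with probability ``p_edit``; an edited triplet becomes a
    byproduct with probability ``byproduct_fraction``, otherwise an
    intended interruption (drawn uniformly from the spec's intended set).
    In the clustered regime a transduced allele is edited with probability
    ``edited_fraction_clustered`` and an edited allele carries exactly
    ``interruptions_per_edited`` interruptions at uniform positions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    spec = model.spec
    intended = sorted(spec.intended)
    byproducts = sorted(spec.byproducts)
    lengths = _draw_lengths(n, model, rng)
    transduced = rng.random(n) < model.transduced_fraction

    alleles: list[SimulatedAllele] = []
    for length, is_transduced in zip(lengths, transduced):
        labels = [TripletClass.PURE] * int(length)
        triplets = [spec.pure] * int(length)
        if is_transduced:
            if model.clustered:
                if rng.random() < model.edited_fraction_clustered:
                    k = min(model.interruptions_per_edited, int(length))
                    sites = rng.choice(length, size=k, replace=False)
                else:
                    sites = np.array([], dtype=int)
            else:
                sites = np.flatnonzero(rng.random(length) < model.p_edit)
            for site in sites:
                if byproducts and rng.random() < model.byproduct_fraction:
                    labels[site] = TripletClass.BYPRODUCT
                    triplets[site] = byproducts[rng.integers(len(byproducts))]
                else:
                    labels[site] = TripletClass.INTENDED
                    triplets[site] = intended[rng.integers(len(intended))]
        alleles.append(
            SimulatedAllele("".join(triplets), labels, bool(is_transduced))
        )
    return alleles


def simulate_reads(
    alleles: list[SimulatedAllele],
    spec: RepeatSpec,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """One amplicon read per allele, plus a ground-truth table.

    Each read is left flank + tract (+ right flank when it fits),
    truncated to ``read_length``, with uniform substitution errors applied
    at ``error_rate`` per base.  The truth table records each allele's
    tract length and intended-interruption count before errors.
    """
    if read_length < spec.anchor_length:
        raise ValueError("read length shorter than the anchor length")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str, str]] = []
    truth_rows = []
    for i, allele in enumerate(alleles):
        template = spec.left_flank + allele.sequence + spec.right_flank
        bases = np.array(list(template[:read_length]))
        if error_rate > 0:
            hit = rng.random(bases.size) < error_rate
            for j in np.flatnonzero(hit):
                choices = [b for b in "ACGT" if b != bases[j]]
                bases[j] = choices[rng.integers(3)]
        seq = "".join(bases)
        rid = f"sim_{i}"
        reads.append((rid, seq, "I" * len(seq)))
        truth_rows.append(
            {
                "read_id": rid,
                "tract_triplets": len(allele.labels),
                "interruptions": allele.n_interruptions,
                "byproducts": sum(
                    1 for l in allele.labels if l is TripletClass.BYPRODUCT
                ),
                "transduced": allele.transduced,
            }
        )
    return reads, pd.DataFrame(truth_rows)


def simulate_trace(model: TraceModel, seed: int = 0) -> PeakTrace:
    """A fragment-analysis trace with multinomial mass at modal +/- shift."""
    rng = np.random.default_rng(seed)
    sizes = [model.reference_modal]
    probs = [1.0 - model.expansion_fraction - model.contraction_fraction]
    if model.expansion_fraction > 0:
        sizes.append(model.reference_modal + model.expansion_shift)
        probs.append(model.expansion_fraction)
    if model.contraction_fraction > 0:
        sizes.append(model.reference_modal - model.contraction_shift)
        probs.append(model.contraction_fraction)
    if model.noise_level > 0:
        # finite-sampling heights plus proportional gaussian jitter
        heights = rng.multinomial(int(model.total_intensity), probs).astype(float)
        heights = np.maximum(
            heights + rng.normal(0, model.noise_level * heights.max(), heights.size),
            0.0,
        )
    else:
        # noiseless traces carry the exact expected mass so closed-form
        # index identities hold
        heights = model.total_intensity * np.asarray(probs)
    peaks = sorted(
        (float(s), float(h)) for s, h in zip(sizes, heights) if h > 0
    )
    return PeakTrace(peaks=peaks, label=f"sim-trace-{seed}")


def simulate_pileups(
    true_frequencies: dict[str, list[float]],
    coverage: int = 1000,
    background_positions: dict[str, list[int]] | None = None,
    background_frequency: float = 0.05,
    edit: tuple[str, str] = ("A", "G"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treated and untreated per-position count tables for nominated loci.

    ``true_frequencies`` maps locus id -> per-position edit frequency.
    Alt counts are Binomial(coverage, frequency) in the treated sample;
    the untreated sample carries the background polymorphism frequency at
    the flagged positions (1-based within the locus) and zero elsewhere.
    """
    rng = np.random.default_rng(seed)
    ref, alt = edit
    background_positions = background_positions or {}
    rows_t, rows_u = [], []
    for locus, freqs in true_frequencies.items():
        flagged = set(background_positions.get(locus, ()))
        for pos1, freq in enumerate(freqs, start=1):
            t_alt = int(rng.binomial(coverage, freq))
            u_freq = background_frequency if pos1 in flagged else 0.0
            u_alt = int(rng.binomial(coverage, u_freq))
            for rows, alt_count in ((rows_t, t_alt), (rows_u, u_alt)):
                counts = {b: 0 for b in "ACGT"}
                counts[ref] = coverage - alt_count
                counts[alt] += alt_count
                rows.append(
                    {"locus": locus, "position": pos1, **counts, "depth": coverage}
                )
    return pd.DataFrame(rows_t), pd.DataFrame(rows_u)
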