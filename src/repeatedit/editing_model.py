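"""Extrapolation of windowed editing observations to full-length alleles.

Short amplicon reads observe only a window of W triplets of a long repeat
tract (e.g. 70 of >= 109 repeats), so the directly observed edited-allele
fraction underestimates editing of the full allele.  From the windowed
summary statistics

    f    fraction of all sequenced triplets that are interrupted,
    n_i  mean number of interruptions per interrupted allele (>= 1),
    f_i  mean interrupted fraction of the tract among interrupted alleles,

the per-triplet edit probability is p = f / n_i, and for an allele of N
repeat units:

    estimated editing        = 1 - (1 - p)^N     (P(at least one interruption))
    estimated interruptions  = f_i * N           (mean count in edited alleles)

The product form assumes triplets are edited independently; when editing
clusters within alleles the estimate is a stated heuristic, reported side
by side with the observed fraction, never substituted for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EditingEstimate",
    "per_triplet_rate",
    "estimate_editing",
    "estimate_interruptions",
    "estimate_from_summary",
    "bootstrap_ci",
]


@dataclass
class EditingEstimate:
    f: float
    n_i: float
    f_i: float
    N: int
    p: float
    estimated_editing: float
    estimated_interruptions: float


def per_triplet_rate(f: float, n_i: float) -> float:
    """Per-triplet edit probability p = f / n_i.

    ``n_i`` is the mean interruption count among interrupted alleles, so it
    cannot be below 1 (except exactly 0 when nothing is edited, where p=0).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must be in [0, 1], got {f}")
    if f == 0.0:
        return 0.0
    if n_i < 1.0:
        raise ValueError(
            f"n_i must be >= 1 (an interrupted allele has >= 1 interruption), got {n_i}"
        )
    p = f / n_i
    if p > 1.0:
        raise ValueError(f"f/n_i = {p} exceeds 1")
    return p


def estimate_editing(p: float, N: int) -> float:
    """Probability an N-repeat allele carries at least one interruption."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    return 1.0 - (1.0 - p) ** N


def estimate_interruptions(f_i: float, N: int) -> float:
    """Expected interruption count in an edited allele of N repeats."""
    if not 0.0 <= f_i <= 1.0:
        raise ValueError(f"f_i must be in [0, 1], got {f_i}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    return f_i * N


def estimate_from_summary(summary, N: int) -> EditingEstimate:
    """Build the full-allele estimate from a sample EditingSummary.

    ``N`` defaults in the CLI to the genotyped modal repeat length of the
    sample (e.g. 300 or 800 GAA repeats for the two mouse cohorts).
    """
    f = summary.triplet_fraction_interrupted
    n_i = summary.mean_interruptions
    f_i = summary.mean_interrupted_tract_fraction
    p = per_triplet_rate(f, n_i)
    return EditingEstimate(
        f=f,
        n_i=n_i,
        f_i=f_i,
        N=N,
        p=p,
        estimated_editing=estimate_editing(p, N),
        estimated_interruptions=estimate_interruptions(f_i, N),
    )


def bootstrap_ci(
    values,
    statistic=np.mean,
    n_resamples: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Percentile bootstrap confidence interval over per-read values."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    stats = np.array([statistic(values[row]) for row in idx])
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
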