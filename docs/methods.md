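# Methods

`repeatedit` quantifies the outcomes of CRISPR base editing inside
trinucleotide repeat (TNR) tracts — loci such as the *HTT* CAG repeat
(Huntington's disease) or the *FXN* GAA repeat (Friedreich's ataxia) whose
pathogenic expansions are destabilized by naturally occurring triplet
interruptions. The package covers five computations plus a synthetic-data
generator that makes each of them testable without sequencing data.

## Triplet quantification (repeat_quant)

Amplicon reads are anchored by exact k-mer match (default 12 nt) to the
tract-proximal suffix of the left flank and prefix of the right flank; the
left anchor is the first occurrence from the read start, the right anchor
the first from the read end. A both-anchored read yields the tract strictly
between the anchors; a read reaching only one flank yields a partial tract
whose triplet frame is taken from the anchored edge (for right-only reads
the leading partial triplet is dropped, so a tract length divisible by 3
gives identical calls from either side). Reads with more than 20% N are
treated as unanchored. Exact anchoring was chosen over alignment because it
is deterministic, testable, and adequate for amplicon data where the flanks
are fixed; a one-mismatch fallback is deliberately omitted from the default
path.

Each in-frame triplet is classified against an IUPAC degenerate pattern
covering every product of the editing chemistry:

| strategy | pure | pattern | intended | byproducts |
|---|---|---|---|---|
| CAG + cytosine base editor (opposite-strand CTG spacer) | CAG | YAR | CAA | TAG, TAA |
| GAA + adenine base editor | GAA | GRR | GAG, GGA, GGG | — |

The CBE byproducts arise from deamination of the opposite strand and create
stop codons; the ABE strategy has no pattern-internal byproduct, and
opposite-strand T>C products fall outside GRR and are counted as "other".
A read counts as *edited* only if it carries at least one intended
interruption; byproduct-only reads are reported separately, and the product
purity ratio is computed per triplet (total intended : total byproduct),
which is invariant to read depth over the tract. Reads covering fewer than
5 triplets (configurable) are excluded from all denominators, because a
per-read "edited" label over one or two triplets is uninformative. A
both-anchored tract length not divisible by 3 is flagged as an indel
signal rather than force-framed.

Summary quantities: edited fraction (edited / aligned reads); `f`, the
fraction of all sequenced triplets that are interrupted; `n_i`, the mean
interruption count among edited reads; and `f_i`, the mean interrupted
fraction of the tract among edited reads. Whether these should be computed
over reads or deduplicated alleles is an open choice; reads are used.

## Full-allele extrapolation (editing_model)

Short reads observe a window of W triplets of an allele of N repeats. The
per-triplet edit probability is estimated as p = f / n_i and extrapolated
as

    estimated editing        = 1 − (1 − p)^N
    estimated interruptions  = f_i × N

For fixed-width windows f/n_i equals (edited fraction)/W identically, so
the product form reproduces the directly observed edited fraction only to
first order in W·p: it is effectively exact in the sparse-editing regime
the extrapolation exists for (a few percent observed editing), and
systematically *underestimates* at heavy editing (at W·p = 1 the gap is
≈0.16 absolute). Both the observed and the estimated values are therefore
always reported side by side. The model also assumes i.i.d. editing across
triplets; under clustered interruptions it is a stated heuristic. N should
be the genotyped modal repeat length of the sample; a percentile bootstrap
over reads (1,000 resamples) is provided for uncertainty.

## Instability indices (instability)

From a fragment-analysis trace (GeneMapper peak heights, or gel
densitometry for very long GAA tracts), somatic instability in a tissue is
the peak-height-weighted mean signed repeat-size change relative to the
modal allele of the same animal's stable reference tissue (tail):

    index = Σ h_i·Δ_i / Σ h_i,  Δ_i = size_i − modal_ref

after discarding peaks below a relative height threshold (5% of the
trace's tallest peak for capillary data; 10% for gel densitometry, with
the modal-height ≥1,000 QC disabled there) and contractions beyond −40
repeat units (PCR and fragmentation artifacts). The expansion index keeps
Δ ≥ 0, the contraction index Δ ≤ 0; the Δ = 0 peak belongs to both and
contributes zero. The height threshold is anchored to the tallest peak of
the analyzed trace (the natural reading when the reference modal size may
be absent from the analyzed tissue); modal ties break to the smaller size,
a deterministic rule for a degenerate input. The numerators of the
expansion and contraction indices add exactly to the both-mode numerator;
the normalized indices themselves do not add, and no such identity is
claimed. Fragment-size (nt) to repeat-unit calibration is an explicit
linear map `(size − flank_bp)/3` supplied by the user, since amplicon
flank lengths differ between assays.

## Off-target editing (offtarget)

Treated/untreated per-position base counts at nominated loci are reduced
to per-locus editing probabilities. A locus is dropped if any position has
≤ 30 reads (in either sample — the untreated pileup defines both the
editable positions and the background, so it needs the same floor).
Editable positions are those whose untreated consensus base equals the
strategy's reference base (C for CBE, A for ABE; complemented for
minus-strand spacers). Positions with untreated alt frequency > 2.5% are
excluded as pre-existing polymorphisms. The remaining per-position treated
frequencies combine under position independence:

    P(≥1 edit) = 1 − Π(1 − p_i)

Independence is an explicit modelling assumption — the simplest rule that
accounts for every position. The same rule applied to the untreated
frequencies gives the background probability; a locus is "detected" when
the background-subtracted probability exceeds 0.5% and "substantial" at
≥ 5%. Spacer–target mismatches are binned by protospacer position with
position 1 PAM-proximal (A: 1–5, B: 6–10, C: 11–20), and codon changes are
classified as synonymous / missense / nonsense with the standard genetic
code (identical codons are "none").

## KS comparison (stats_ks)

Interruption-count distributions are compared with a from-first-principles
two-sample Kolmogorov–Smirnov test: D is the maximum absolute ECDF
difference over the union of observed values (exact, since the maximum of
a difference of step functions is attained at a jump), and the p-value is
the leading term of the asymptotic Kolmogorov law,
P = 2·exp(−2D²·n_i n_j/(n_i+n_j)), either in closed form or by minimizing
the squared residual of the defining relation with L-BFGS-B on log P
(started at P = 0.5, bounded to (1e-300, 1]; the objective is unimodal in
log P). The two routes agree to ≤1e−6. P is capped at 1 because the raw
formula yields 2 at D = 0. No tie correction is applied. Note that
`scipy.stats.ks_2samp(method="asymp")` applies a finite-n refinement on
top of this law and can differ by >10% on heavily tied count data; the
matching library reference for the asymptotic form is
`scipy.special.kolmogorov`.

## Synthetic data (simdata)

The generator emulates the statistical structure each stage assumes, with
one explicit NumPy generator per operation (same seed → byte-identical
output):

- **Alleles** — repeat length normal around a modal value (default 20
  triplets, the scale of a mid-length tract window), a transduced fraction
  (default 1, an in vitro regime; mouse tissue runs use ~0.3–0.5), i.i.d.
  per-triplet editing (default p = 0.05) or a clustered regime with a
  fixed interruption count per edited allele, and a byproduct share of
  edits (default 2%, the high-purity regime of the CBE chemistry).
  Ground-truth per-triplet labels are emitted with the sequences.
- **Reads** — left flank + tract (+ right flank when the read length
  permits) with uniform substitution errors. The shipped flanks contain no
  pattern-matching triplet in any frame, so flank remnants in partially
  anchored reads cannot masquerade as tract signal.
- **Traces** — point masses at modal, modal+shift and modal−shift sizes.
  Noiseless traces carry the exact expected intensities so closed-form
  index identities hold; noisy traces use multinomial sampling plus
  proportional Gaussian jitter.
- **Pileups** — binomial alt counts at stated coverage, with background
  polymorphisms planted in the untreated sample at flagged positions.

What the generator does not emulate — PCR stutter around fragment peaks,
quality-score-dependent error profiles, repeat-length-dependent
amplification bias, non-triplet indels (whole-triplet slippage only, off
by default) — bounds what passing tests show: they validate the
computations on data that satisfies the pipeline's stated assumptions, not
robustness to those instrument artifacts.

## Problem sizes and tolerances

Stochastic recovery tests use 8,000–10,000 reads (or coverage 10,000) and
assert within 3 binomial standard errors of the closed-form expectation;
exact identities assert at 1e−10 to 1e−12; the KS closed-form/minimization
agreement at 1e−6. The acceptance script runs a 10,000-read sparse-editing
quantification (70-triplet window, extrapolated to N = 300), a
1e6-intensity contraction-shifted trace, a two-position off-target locus
at coverage 10,000, and a 200-vs-200 KS comparison — sizes at which every
Monte-Carlo quantity sits well inside its tolerance while the whole run
completes in seconds.
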