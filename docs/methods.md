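# Methods

This note documents the models, conventions and design choices behind
`acetrna`, in the spirit of a methods section: what each component assumes,
which knobs matter, and what the synthetic-data tests do and do not show.

## tRNA model

A tRNA gene is a BED6 interval on a genome FASTA plus the transcribed body
sequence (coding strand, 5′→3′; minus-strand genes are reverse-complemented
at parse time) and a dot-bracket secondary structure.  Coordinates are
0-based half-open throughout.

The cloverleaf is derived purely from the dot-bracket: pairs come from a
stack-based bracket matcher, maximal stacked runs form helices, and a valid
cloverleaf has exactly four helices in 5′→3′ order (acceptor, D, anticodon,
T) with the acceptor enclosing the other three and a 7-nt anticodon loop.
Sprinzl-style numbers (anticodon 34–36, loop flanks 32/33/37/38, T-stem
pairs 49–65/50–64/51–63) are labels computed from helix order, not from
alignment to a reference tRNA: the annotation sources that supply
structures do not ship alignments, and helix order is unambiguous for any
structure this package accepts.  No folding is performed — the dot-bracket
is required input (from a GtRNAdb-style table or the simulator).  G·T
wobble pairs in stems are accepted and flagged; non-complementary pairs are
logged as mismatches rather than rejected, since the structure string is
treated as data.

## Library design

*Flank extraction* is strand-aware (the 5′ flank of a minus-strand gene is
the genomic window downstream of the gene, reverse-complemented) and
deduplicates by exact string identity — "unique" means unique, with no
clustering.  Provenance (gene, locus) of the first occurrence is kept and
output order is first-occurrence input order, so runs are reproducible.
Genes whose flank would run off a chromosome end are skipped with a logged
warning.  For long (e.g. 850-bp) elements a synthesis-accessibility
predicate is applied; the default rejects homopolymers >15 nt and GC
outside 20–80%, a generic stand-in for vendor rules, and is replaceable.

*Saturation libraries* enumerate all 4^k substitutions of k positions in
lexicographic order of the substituted k-mer, so downstream heat-map
layouts are stable (the layout itself carries no meaning).  The member
equal to the template is labeled "original".

*Sticky-stem libraries* stabilise A–T/T–A stem pairs: a site qualifies when
the pair is not conserved across the target and a family of functional
isoacceptors **and** at least one family member carries a C–G or G–C pair
there that differs from the target's own pair (a licensed pair identical to
the target's would make the substitution a no-op and collapse members).
The pair identity is taken from the first qualifying family member in
input order — the natural deterministic tie-break when several members
license a site.  The library is all 2^k combinations of original versus
licensed pair, both strands substituted jointly, member ids encoding the
site bitmask.

*T-stem libraries* substitute the outer three (optionally five) T-stem
pairs from a user-supplied variant table (name + per-pair nucleotides);
the canonical 28-variant affinity panel is consumed as data, not
hard-coded.  Non-complementary specified pairs are rejected; wobble pairs
are allowed and logged.

*Golden-Gate oligos*: top strand = 5′-overhang + insert; bottom strand =
reverse complement of insert + 3′-overhang, leaving two 4-nt 5′ overhangs
after annealing.  Overhang pairs that are equal or reverse-complementary
would ligate in either orientation and are rejected.  `simulate_assembly`
verifies the duplex core anneals and returns the reconstructed
`oh5+insert+oh3`.

*Terminator scan*: vertebrate RNA polymerase III terminates at ≥4
consecutive T on the coding strand.  The first such run in the 3′ trailer
is the designated terminator (its absence is a hard error); any ≥4-T run
starting upstream of it is reported as a premature-termination warning.

## Screen scoring

The activity statistic is the normalized suppression ratio
`(Nluc/Fluc | +tRNA) / (Nluc/Fluc | no tRNA)`.  Because any per-well
multiplicative factor (transfection efficiency, reagent volume) enters both
channels, it cancels exactly; the simulators verify this to floating-point
tolerance with lognormal efficiency up to σ = 1.

Choices the assay description leaves open:

* **Control aggregation** — the per-plate denominator is the *geometric*
  mean of the control wells' Nluc/Fluc.  Ratios are multiplicative with
  multiplicative noise, so the geometric mean is the natural location
  estimate; it also makes the ratio invariant to rescaling a whole plate.
  Consequently the control wells' ratios have geometric mean exactly 1 on
  every plate (their arithmetic mean is 1 exactly only when control wells
  agree).
* **Control scope** — per-plate by default; a per-experiment pooled control
  is available as `control_policy="per_experiment"`.
* **SEM** uses the sample standard deviation (n−1) over replicate ratios;
  members with <2 replicates are flagged rather than dropped.  No
  background subtraction is applied.

Plates without a control are dropped with an error log rather than
poisoning the run.

## Activity-weighted logos

Member activities are converted to copy counts (ratio 100 → 100 copies)
with banker's rounding floored at 0; zero-count members are retained but
weightless.  Every weighted computation is defined to equal the unweighted
computation on the count-expanded sequence set, and the tests enforce this
equivalence on fuzzed inputs — it is the correctness anchor for the whole
module.

The significance matrix is an exact two-sided binomial test per (position,
base): k = weighted base count, n = total weight, p0 = background.  The
two-sided P sums all outcome probabilities not exceeding the observed
outcome's probability (the conventional minlike definition, with the usual
1 + 1e-7 relative tie tolerance); the reported value is
sign(k/n − p0)·(−log10 P), capped at ±300, and exactly 0 when k/n = p0.
The default background is the per-base frequency pooled over all positions
of the weighted set; `uniform` and explicit 4-vectors are available.
Only single positions are scored (no k-mer mode).  Consensus sequences are
per-position argmax/argmin of either matrix with alphabetical tie-break.

## Dose–response

The model is a rectangular hyperbola with the baseline pinned at the
ratio's no-tRNA value of 1:

    S(D) = 1 + (Sup_max − 1) · D / (DD_50 + D)

so S(0) = 1, S → Sup_max, and S(DD_50) = (1 + Sup_max)/2.  The Hill
exponent is fixed at 1 by default; a free exponent (0.1–10) is available
for sensitivity analysis, and the model function is pluggable.  Fitting is
unweighted least squares on the ratio scale (dose points are typically
shown with SEM bars but without a stated weighting scheme), initialised at
Sup_max = max ratio and DD_50 = dose nearest half-max.  Flat data are
returned with Sup_max at the observed level and DD_50 flagged
unidentifiable instead of a spurious fit.  Bootstrap percentile CIs
resample replicates (rows when replicates are unlabeled) under a seeded
generator; CIs are deterministic given data and seed.

Dose sparing inverts the model analytically,
D(level) = DD_50·(level−1)/(Sup_max−level), and reports
D_b(level)/D_a(level).  At the shared midpoint level the fold reduces
exactly to the DD_50 ratio, which the tests use as an identity.

## Fidelity MS

Digestion cleaves C-terminal to K/R except before P (the classical trypsin
rule; stricter engine-specific exception sets can be expressed by swapping
the site function) and enumerates 0..2 missed cleavages by default.  The
variant inclusion list substitutes each of the 20 amino acids at the site
and keeps the spanning peptide with the fewest missed cleavages (shortest
on ties).  A K/R substitution creates a cleavage at the variant position
itself; the representative peptide must read through it, so K/R variants
carry ≥1 missed cleavage rather than a fragment truncated at the variant
residue.  This yields exactly 20 distinct peptides per site.
Carbamidomethyl-C (+57.02146 Da) is fixed; methionine oxidation
(+15.99491 Da) expands the m/z entries per oxidation count; m/z is reported
for charges 2–5.

Percent incorporation: weights from the equimolar control are
`mean(control)/control_aa` (reweighted control ≡ uniform); the sample's
weighted abundances are normalized to 100%.  The construction is invariant
to rescaling any residue's true ionization efficiency — the entire point of
the control — and the tests verify exact recovery of known incorporation
fractions under arbitrary distortions.

## qPCR

Textbook comparative Ct: ΔCt = mean(target) − mean(reference) per sample,
ΔΔCt relative to a single calibrator, RQ = 2^−ΔΔCt with amplification
efficiency fixed at 2.  No triplicate outlier removal by default; an
optional maximum-spread filter drops the value farthest from the median
until the spread fits, keeping at least two.

## Synthetic data

The generators define the conditions under which the package is validated:

* **Genome** — 30 canonical 73-nt tRNA genes (7/4/5/5-bp stems, no encoded
  CCA) planted on both strands of a random 2-chromosome genome with 120 nt
  of intergenic margin, 3 genes sharing the first gene's 5′ flank to give a
  known duplicate count for dedup tests.
* **Plates** — 6 transfection replicates (the screen's replication level),
  10% per-channel lognormal CV, per-well lognormal transfection efficiency
  with σ = 0.5 (a realistic well-to-well spread for lipofection; the
  invariance tests push it to 1.0), 4 control wells per 96-well plate.
  Efficiency and channel noise come from separate seeded streams so the
  efficiency can be switched off without changing the channel draws —
  that is what makes the exact-cancellation test possible.
* **Dose** — truth Sup_max = 40, DD_50 = 8 ng/µl on an 8-point
  two-fold dose grid (1–128 ng/µl) spanning both sides of DD_50, 6
  replicates, 10% CV.
* **MS** — 98% cognate incorporation with the remainder spread uniformly,
  per-residue ionization factors lognormal with σ = 0.5, 5% measurement
  CV.
* **qPCR** — additive Gaussian Ct noise (σ = 0.1 cycles) around means
  realising configured ΔΔCt truths.

Every simulator is a pure function of (config, seed); identical seeds give
byte-identical files.  The generative models deliberately match the
fitting models plus the stated noise, so recovery tests demonstrate
*correctness of the implementations*, not robustness to
model misspecification: real screens add plate-edge effects, saturating
detectors, heteroscedastic low-count wells, chromatographic and charging
artefacts, and qPCR efficiency below 2, none of which are simulated.

## Problem sizes and tolerances

The test and acceptance workloads use ~10^4 simulated wells for the
ratio-invariance check, 100 fuzzed sets for weighted/unweighted logo
equivalence, 50 seeds for dose recovery (median relative error < 10% at
10% CV), 20 seeds for MS recovery (median deviation < 0.5 points at 5%
CV), and 200 fuzzed 50-mers against the brute-force digest oracle — sizes
chosen to make the stochastic assertions stable while keeping a full run
in seconds.  Exact identities (noiseless recovery, analytic inversion,
weighted/expanded equality) are asserted at 1e-6 relative or tighter;
binomial P-values agree with an independent exhaustive summation to 1e-9.

## Known limitations

* Structures must be supplied; there is no folding or covariance-model
  inference, and modified nucleotides are out of scope.
* The cloverleaf parser requires a bulge-free four-helix structure; tRNAs
  with introns or expanded variable arms that pair are rejected.
* The dose model's true functional form at high DNA loads (toxicity,
  promoter competition) is not modeled; the free-exponent option is a
  sensitivity probe, not a mechanistic claim.
* kpLogo-style k-mer/degenerate motif search is not implemented; logos are
  single-position.
* MS fidelity consumes per-residue abundance tables; database search, FDR
  control and feature detection live upstream.
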