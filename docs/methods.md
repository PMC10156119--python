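# Methods

This note documents the models and procedures implemented in `sbaval`, the
assumptions behind them, and the design choices made where the design was
genuinely open.

## The assay and its data

A suspension-bead-array (SBA) screen couples each antibody to a distinct
colour-coded magnetic bead population; beads for antibodies targeting one
receptor subfamily are pooled into a subfamily-specific array.  Each well
exposes the array to a lysate overexpressing a single epitope-tagged
receptor construct (or an empty-vector mock), and a flow-based reader
reports, per bead population and well, the median fluorescence intensity
(MFI) of the detection channel and the number of bead events behind it.
The analysis therefore consumes a samples × beads MFI matrix with a
parallel bead-count matrix, plus three manifests: antibodies (bead id,
intended target, antigen span), samples (construct, replicates, panel), and
the construct library (sequences, tags, subfamily).

Two QC gates precede all scoring.  Cells supported by fewer than
`min_events = 32` bead events are masked and treated as missing everywhere
downstream — never imputed.  Antibody beads whose signal in a dedicated
coupling-efficiency run (anti-IgG detection of the bead-bound antibody)
falls below a floor (default 1000 MFI units) are excluded from scoring
entirely; the coupling run is modelled as its own small matrix rather than
as extra columns of the sample assay, since it is a separate physical
measurement.

## Expression testing

Construct abundance is read from the panel's epitope-tag capture bead
(anti-FLAG capture with 1D4 detection; anti-HA for frizzled constructs,
which carry an HA tag instead).  MFI is floored at 1 unit and
log2-transformed (the floor keeps zeros finite while preserving order).
Within each panel, constructs sharing a capture tag form one stratum: the
stratum is first gated by an ordinary one-way ANOVA across constructs plus
mock (α = 0.05), then each construct is contrasted against mock with
Dunnett's multiple-comparison test.  A construct is *supported* iff the
ANOVA gate fires, its Dunnett p-value is below α, **and** its mean log2
level exceeds the mock mean — the explicit one-sided direction prevents a
significantly *low* signal from counting as expression.  Constructs with
fewer than two QC-passing replicates are *uncertain* with an NA p-value and
stay in summary denominators.  Dunnett contrasts use the multivariate-t
implementation in scipy; tests verify agreement with a 100,000-permutation
oracle to within 0.01 in p on single-contrast fixtures (where Dunnett
reduces exactly to a two-sample t test).

## Robust Z-scores and the selectivity threshold

Each antibody's MFI vector **x** over its panel's QC-passing samples is
rescaled to robust Z-scores

    rz_i = (x_i - median(x)) / (1.4826 * MAD(x)),

computed separately per antibody.  Median/MAD resist the minority of true
binding events the scaling is meant to expose; a zero MAD raises an error
naming the antibody rather than silently substituting another scale.

The selectivity threshold is antibody-specific: `t = peak + k * sigma_neg`
with default `k = 12`.

* **peak** is the mode of a Gaussian KDE of the R.Z values, evaluated on a
  fixed 512-point grid spanning [min, max].  Bandwidth is Silverman's
  practical rule, `0.9 * min(sd, IQR/1.349) * n^(-1/5)` — the IQR guard
  matters because binding outliers inflate the plain SD by orders of
  magnitude.
* **sigma_neg** estimates the SD of the negative (non-binding) population.
  Since true binding inflates only the upper tail, it uses the lower half
  mirrored around the peak: `1.4826 * median(|r - peak|)` over `r <= peak`.
  This reflected-tail estimator is the module's central free choice: the
  estimator behind the published threshold procedure is not specified in
  detail anywhere we could reproduce, and only its qualitative property
  (antibody-specific thresholds well above the background bulk) is
  recoverable.  On standard-normal data the estimator is consistent for σ
  (tests check it lands in [0.9, 1.1] at n = 10,000 and agrees with the
  mirrored upper-tail estimate within 5% in expectation).
* **Stability guard.** A median over very few tail distances is dominated
  by peak-location noise; with fewer than 10 points at or below the peak
  (including the degenerate < 3 case) the estimator falls back, with a
  warning, to the full-vector MAD-based SD — which for R.Z data is ≈ 1 by
  construction.  Without this guard, small panels (tens of samples)
  occasionally produce collapsed thresholds and spurious off-target calls.

`k = 12` is the screen's published operating point; the threshold-sweep
table (counts per category as a function of k) reproduces the reasoning —
on-target counts plateau near k = 12 while small k flags everything as
cross-reactive.  All thresholds are configuration, never hard-coded.

## Classification

With threshold t: `on` = mean R.Z over samples containing the intended
target > t; `cross` = **any single** QC-passing sample containing a
different construct above t.  Categories: on ∧ ¬cross → *on-target*;
on ∧ cross → *co-target*; ¬on ∧ cross → *off-target*; neither →
*no-target*.  Mock wells are part of the background population (they enter
median/MAD and the KDE) but can never trigger a cross-reactivity event.  A
panel with no samples containing an antibody's target is a design error,
not a no-target call.  Technical duplicates are retained as separate
samples, since the rule is stated over samples; averaging them first is a
configuration option.  Summary tables report percentages to one decimal;
the narrative breakdown of non-on-target antibodies uses integers, rounded
half-up from the one-decimal value (so 19.497% → 19.5 → 20%, matching how
such counts are conventionally printed).

## Cross-reactivity deconvolution

Each (antibody, off-target) event is annotated with candidate causes:

* **abundance** — the off/on expression ratio (means of *linear*-scale
  tag-capture levels over QC-passing samples, off ÷ on) is ≥ 2; the linear
  scale keeps the "twofold" line literal.  If the on-target's expression is
  unsupported or zero, the ratio is flagged not-computable (NaN) and the
  abundance cause cannot fire.
* **homology** — the Smith–Waterman local alignment of the antibody's
  *antigen* sequence (the immunogen fragment, not the whole target protein)
  against the full off-target sequence has Karlin–Altschul E-value
  `E = K·m·n·exp(-λS) < 1`.  The aligner uses BLOSUM62 with affine gap cost
  `11 + L` (protein-search convention); `(λ, K) = (0.267, 0.041)` are fixed
  configuration constants for that scoring system, not estimated from data.
  Note the boundary is *permissive*: for a correctly calibrated E-value the
  best chance alignment of unrelated sequences sits near E ≈ 1, so the
  homology flag carries weak evidence on its own and may co-occur with
  abundance; genuinely homologous pairs in the synthetic data score
  E ≤ 10⁻²⁰.  Exact parity with any specific BLAST release is a non-goal.
* **promiscuous** — neither flag fired.

Replicate consistency is recorded per event: true iff every QC-passing
sample containing the off-target exceeds the antibody's threshold.

## Paired antibodies

All unordered antibody pairs sharing a target are correlated (Pearson r) on
their R.Z vectors over the intersection of QC-passing samples; pairs with
fewer than 3 shared samples are skipped with a warning.  R.Z rather than
raw MFI is correlated because each antibody's own scaling removes its
arbitrary intensity level; a config switch allows raw-MFI correlation.  The
summary counts targets with ≥ 2 antibodies and, among those, targets
*recognised* by ≥ 2 antibodies, where recognition means an on-target or
co-target call (both detect the intended receptor above threshold).

## Antigen structural features

Per-residue features are extracted from single-chain predicted-structure
models (PDB or mmCIF; multi-model files use the first model with a
warning):

* **pLDDT** read from the B-factor field (CA atom per residue); low values
  indicate disorder.  No binary disorder cutoff is imposed.
* **SASA** via an in-package Shrake–Rupley implementation (golden-spiral
  sphere sampling, probe 1.4 Å, 960 points per atom by default; per-atom
  areas verified against the analytic sphere, the two-sphere closed form,
  and an independent implementation).  Relative SASA divides by the
  residue-type theoretical maxima of Tien et al. (2013), clipped to [0, 1].
* **Secondary structure** from backbone dihedrals: helix for φ ∈ (−100°,
  −30°) ∧ ψ ∈ (−80°, −5°) in runs of ≥ 4, sheet for φ ∈ (−170°, −70°) ∧
  ψ ∈ (90°, 180°) in runs of ≥ 3, coil otherwise.  This deliberately
  replaces hydrogen-bond (DSSP-style) logic: only three-state fractions
  feed the statistics, and the interface accepts precomputed per-residue
  assignments for users who prefer an external DSSP run.

Features are averaged over each antibody's antigen span (1-based inclusive
on the untagged native sequence); spans not fully covered by resolved
residues are flagged incomplete and excluded from group statistics.  Group
comparisons between selectivity classes use Kruskal–Wallis plus pairwise
two-sided rank-sum tests for antigen length, and independent two-sample t
tests for the structural metrics.

## The synthetic-data generator

The generator defines the study conditions everything is tested under.

* **Library**: 34 constructs across six subfamily panels (8/5/7/6/5/3),
  each a random 400-residue sequence whose middle 80 residues descend from
  a per-subfamily ancestral segment mutated at rate 0.08 per position —
  within-subfamily homology exists by construction, cross-subfamily
  homology does not.  Two GSAF constructs are HA-tagged (frizzled-like);
  the rest carry FLAG; all carry 1D4.
* **Samples**: four biological replicates per construct, four mocks per
  panel (one technical replicate, as in the screen's main design).
* **Expression**: lognormal. Expressed constructs have mean 50× the mock
  residual level (log-sd 0.35); constructs fail with subfamily-dependent
  probabilities (0.07–0.33) patterned on the per-subfamily success rates
  typical of heterologous GPCR expression, and failed constructs draw from
  the mock distribution — indistinguishable from mock in expectation.
* **Signal**: `MFI = min(S, b + Σ_g affinity·level) · exp(ε)` with
  background b = 60, saturation S = 60,000 (the order of magnitude of a
  bead reader's dynamic range) and multiplicative lognormal noise σ_n =
  0.12.  No quantitative noise model is published for the assay; σ_n is a
  free choice set so that background R.Z values have spread ≈ 1.  The
  tag-capture affinity is kept low (3 units) so tag MFI stays in the linear
  range even for abundance-boosted constructs; on-target affinity is 20.
* **Planted classes**: {on 0.61, co 0.04, off 0.08, none 0.27}, matching
  the marginal outcome distribution typical of large polyclonal screens so
  summary tables look realistic.  Cross-reactivity is planted through two
  mechanisms: *homology* (antigen inside the shared segment; the partner's
  homologous segment binds at affinity 12) and *abundance* (antigen in a
  unique region; a dissimilar partner overexpressed 4× binds weakly at
  affinity 3).  Partners of planted cross-reactive antibodies are forced to
  express (the planted event must be observable), and boosted partners are
  never themselves the on-target of a planted cross-reactive antibody
  (ratios would be confounded).  Planted-class recovery for on-target
  antibodies is accordingly measured among antibodies whose target truly
  expressed — an antibody whose construct failed is observably no-target,
  which is correct behaviour, not a classifier error.
* **Bead counts**: floor 35 + Poisson, with 1% of wells dropped below 32
  events to exercise the masking path; 2% of beads fail coupling.
* **Antigen structures**: synthetic 3D peptides built with ideal backbone
  geometry (NeRF chain construction).  "Successful" antigens are long
  (length ~ N(54, 26)), coil-like, surface-exposed, low-confidence;
  "failed" antigens are shorter (~ N(37, 19)) ideal helices buried inside
  an occluding atom cage, high-confidence.  These are labelled synthetic
  stand-ins for predicted models: they reproduce the direction of the
  structural contrasts, not the absolute feature values of real receptors.

What the generator does **not** emulate: plate positional effects, binding
kinetics and washing, detergent chemistry, epitope conformational state,
and antibody polyclonality (each antibody is a single affinity map).
Passing recovery tests therefore demonstrates that the statistical pipeline
recovers planted truth under the stated signal model — not that the assay
itself is free of those physical confounders.

## Problem sizes and numerical choices

Default simulations use 64 antibodies × 160 samples; recovery statistics
aggregate 20 independent simulations (seeds derived from one base seed), a
size chosen so the full suite and the acceptance script each run in minutes
on one CPU while recovery proportions have denominators of several hundred.
Structural group comparisons use 50 antigens per class at 240 SASA points
per atom (per-atom areas change < 3% between 240 and 960 points; the
convergence is itself tested).  Ties in rank tests use the asymptotic
tie-corrected statistic (identical groups give p = 1).  Degenerate inputs
fail loudly: zero MAD, missing target samples, multi-chain structure files
and mismatched manifests all raise errors naming the offender, while
recoverable conditions (few tail points, incomplete antigen spans, skipped
pairs) warn and are recorded in the run log.

## Known limitations

* The reflected-tail σ_neg estimator is one of several defensible readings
  of "SD of the expected negative proportion"; antibody-specific thresholds
  shift accordingly (their *ranking* of samples does not).
* E < 1 is a weak homology boundary (see above); cause flags are
  explanatory annotations, not hypothesis tests.
* The dihedral secondary-structure assignment diverges from DSSP at helix
  termini, bulges and irregular strands; only class fractions are consumed
  downstream.
* Expression ratios use tag-capture MFI as the abundance proxy; any
  tag-accessibility differences between constructs propagate into the
  abundance flag.
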