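# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Guide geometry

Coordinates are 1-based and fully closed throughout; every writer states
this in its header. A protospacer hit requires an exact match (N in a
query pattern is a wildcard; N in a reference matches nothing — the
conservative direction against false hits) with the PAM immediately 3′ on
the matched strand. The predicted SpCas9 blunt cut is reported as the base
3 bp upstream of the PAM start along the protospacer-carrying strand,
converted to sense coordinates; under reference reverse-complementation
the cut coordinate maps to L − c + 1, which the suite verifies on random
references. Guides of non-standard length (e.g. a printed 23-mer) are
matched as given, never truncated. In-silico PCR reports the span from the
forward primer's 5′ base through the downstream edge of the
reverse-primer binding site; multiple productive pairings are flagged
ambiguous and all are listed.

The reference sequences shipped for the worked examples are **synthetic**:
the real accessions are not deposited with desk-scale studies of this
kind, so `synthetic_data` builds random sequences with the published guide
and primer sequences planted at coordinates that reproduce the published
cut sites (115, 162) and amplicon sizes (990, 108, 65 bp). They exercise
the coordinate arithmetic, not the real genome.

## Trace decomposition

The edited chromatogram window is modelled as a non-negative linear
combination of templates T_d, where T_d at window position p equals the
control signal at p − d, for every shift d ∈ [−max_indel, +max_indel]
(default 27). All four dye channels are stacked into one observation
vector. Before fitting, the edited trace is rigidly aligned to the control
by the integer lag maximising the flattened-signal correlation over
[1, left_boundary] (default 100); alignment below 0.9 correlation is an
error rather than a silent bad fit.

Defaults mirror common practice for this assay: decomposition window
115–560, indel reporting threshold |d| ≥ 2, per-coefficient significance
threshold p < 0.001, and an interpretability gate R² ≥ 0.90. The full
shift range including |d| ∈ {0, 1} is always fitted — a fit that omitted
them could not estimate the unedited fraction — while reporting of
significant indels applies the |d| ≥ 2 filter.

Numerical choices:

* **Prune-and-refit.** Plain NNLS scatters small positive mass over many
  templates under channel noise (the non-negativity constraint rectifies
  zero-mean noise), inflating the apparent edited fraction by several
  points at 5% noise. Components below 0.5% of the total are therefore
  dropped and the fit repeated until the active set is stable; the
  zero-shift template is never pruned. This is a standard sparse-NNLS
  post-process and leaves noise-free fits untouched.
* **Significance.** Each retained coefficient is tested two-sided against
  residual noise using the standard errors of an ordinary-least-squares
  refit restricted to the active set. This approximates the behaviour of
  the original web tool, which does not publish its exact test.
* **Efficiency.** The primary estimate is 100 × (1 − c₀) with c₀ the
  normalized zero-shift coefficient; the sum of individually significant
  indel fractions is reported alongside. The former is robust when many
  small alleles are individually non-significant.
* R² = 1 − SS_res/SS_tot over the (grand-mean-centred) window; fits below
  the gate are flagged `interpretable = False`, never suppressed.

## ΔΔCt expression

Technical replicates are averaged within biological replicate; ΔCt is
target minus normalizer per biological replicate; ΔΔCt is the mean ΔCt
difference against the calibrator group; the expression ratio is
E^−ΔΔCt with amplification efficiency E fixed at 2.0 (perfect doubling —
configurable, as real efficiencies are rarely reported). Fold change uses
the signed convention (−1/r below unity) so a 40% reduction prints as
−1.67. The "nested" test averages technical replicates and applies a
two-sided Welch t test to biological-replicate ΔCt means — the
summary-statistic equivalent of a two-level nested model, approximating
the commercial implementation of that name. Groups with fewer than three
biological replicates run with a warning (such designs occur in practice);
fewer than two in both groups is an error.

## CMC RT-stop pseudouridylation index

R divides the CMC-induced amplification delay of the Ψ-spanning long
amplicon by that of the downstream short amplicon, each as
2^(C̄t_untreated − C̄t_CMC) with means over replicates; the short fragment
is itself the internal control, so no further normalizer is applied.
%Ψ = 100 × (1 − R) is strictly decreasing in R; values below zero (R > 1)
are reported with a flag, not clamped — clamping would bias the group
comparison. Group tests are two-sided Welch t tests on one %Ψ value per
biological replicate (technical replicates averaged first), requiring
n ≥ 2 per group.

## Isoform switches

TMM normalization follows the trimmed-mean-of-M-values recipe: reference
sample by upper-quartile count fraction closest to the mean; M/A statistics
on transcripts expressed in both members of each pair; symmetric rank
trimming (30% on M, 5% on A); factor = 2 to the precision-weighted mean of
retained M values (inverse asymptotic binomial variance weights); factors
rescaled to geometric mean 1. The implementation agrees with
edgeR::calcNormFactors to ~1e-6 on test matrices, and the suite keeps that
cross-check.

Differential transcript expression is a per-transcript Poisson GLM with
log link, offset log(library size × TMM factor) and a two-group indicator,
tested by a 1-df likelihood-ratio against the intercept-only model. The
baseline level is the group named `control`/`WT` when present. Transcripts
with zero counts everywhere are excluded and logged. With one sample per
group the model remains defined but p-values reflect counting noise only;
a prominent warning says so. Adjusted p-values use Benjamini–Hochberg
step-up; significant transcripts (q < 0.05) split at signed fold change
±1.5, and a gene is a switch call iff both directions are present among
its transcripts. Protein-coding filtering is a biotype column applied
before testing when available.

## Over-representation

The p-value is the hypergeometric upper tail P(X ≥ k) for overlap k,
category size K, query size n, universe size N — equivalent to a one-sided
Fisher exact test. The enrichment score is −ln(p), the convention of the
common commercial analysis platforms (both published score/p anchor pairs
check out under it to 2 d.p.). The default universe is the genes that
entered testing, not the whole annotation; annotations are local
two-column files — no live ontology downloads.

## Synthetic data

One seed expands into independent substreams per generator, so modules
regenerate independently and byte-identically. Defaults are the study
conditions: a clone-like allele spectrum (34% unedited; deletions −20,
−15, −10, −5), expression ratios 0.60/0.53, stop fractions 0.93/0.88/0.70
with 9/5/6 replicates, 0.15-cycle qPCR noise, 1000 genes × 2 transcripts
with 40 reciprocal 3-fold switch genes in a 3 vs 3 design, and a 10×-odds
planted annotation category.

* **Traces** render one Gaussian peak per base on the base's channel
  (width 0.35 positions — peak-height tables carry little neighbour
  cross-talk) and mix allele traces at the planted fractions plus additive
  Gaussian channel noise on the mixture; the control trace is the clean
  peak sum. Insertions duplicate the bases immediately upstream of the
  cut, the dominant templated repair outcome at Cas9 blunt cuts; this also
  keeps the shifted-template model exact, so decomposition of
  **non-templated** insertions (not generated) would show lower R². The
  default cut (position 111) sits just upstream of the default window
  start (115), as in real use, so the repair junction — where peak bleed
  mixes shifted and unshifted contexts — lies outside the fitted window.
  Dye blobs, mobility shifts and base-caller artifacts are not modelled;
  passing recovery tests demonstrate estimator correctness under the
  assumed signal model, not robustness to raw-electropherogram pathology.
* **Ct tables** draw Ct = baseline − log2(relative template) + N(0, σ) per
  technical replicate; the CMC-treated long amplicon's template is scaled
  by (1 − ψ). Between-biological-replicate variance components beyond the
  technical draw are not modelled.
* **Counts** are Poisson around log-normal baseline means (log-mean 3.5,
  log-sd 1.0 — tens to hundreds of counts per transcript, a desk-scale
  stand-in for bulk quantification), with reciprocal ×m / ÷m swaps in
  switch genes. An over-dispersion knob (gamma mixing) exists, off by
  default, to demonstrate the Poisson test's anti-conservatism on real
  data; planted-recovery results under pure Poisson say nothing about
  negative-binomial robustness.
* **Annotations** are random memberships with one planted category whose
  members enter the query at elevated odds.

## Problem sizes and degenerate inputs

Simulation-based tests use 200 tables per condition for qPCR/Ψ recovery,
50 random spectra for decomposition recovery, 500 tables for type-I-error
checks, and one 1000-gene matrix per switch-recovery scenario — sizes at
which the targeted tolerances (±1 percentage point on %Ψ, ±3 points on
efficiency, ±0.02 on type-I error) are stable across seeds. Degenerate
inputs fail loudly and specifically: empty decomposition windows,
misaligned traces, missing normalizers or design cells, single-replicate
groups, all-zero transcripts, inconsistent hypergeometric margins.

## Known limitations

The decomposition models a single cut; dual-guide excision junctions and
knock-in alleles are out of scope. The Poisson DE model ignores biological
over-dispersion by design (matching the emulated procedure) and its
p-values with n = 1 per group are counting-noise statements. The
enrichment stage does no ontology-graph propagation. AB1 base-calling is
not implemented; the trace interchange format is a per-position channel
intensity table.
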