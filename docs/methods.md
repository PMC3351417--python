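# Methods

This note documents the statistical procedures, parameter defaults, and
design choices behind `retseq`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Study design and data model

The toolkit targets a four-group bulk RNA-seq design: nondiabetic
controls (N), streptozotocin-diabetic mice (D), and diabetic mice
treated with a RAGE inhibitor (D_T1) or a p38 MAPK inhibitor (D_T2),
with three biological replicates per group.  Inputs are
alignment-derived count tables (transcript, exon, junction), a refFlat
or GTF gene-model annotation, and a sample design table.  Coordinates
are 0-based half-open internally (refFlat native); 1-based inclusive
coordinates exist only at display/export.  Junctions are identified by
`(chrom, donor_end, acceptor_start)` without strand, since junction
tables merged across samples carry no reconciled strand.  Duplicate
features in any input are an error, never silently merged: aggregation
hides upstream mistakes.

## Quantification

RPKM_fs = 10⁹ · C_fs / (N_s · L_f), where N_s is the per-sample total
of aligned reads supplied in the count table's `library_sizes` — not the
column sum of a filtered table — and L_f is the exon-model length.  The
log transform is log2(RPKM + offset) with offset 1.0, strictly monotone
and invertible given the stored offset.  Expression filters compare
inclusively (≥ cutoff) under one of three rules: `any_sample` (default),
`all_samples`, or `group_mean`.  Inclusive comparison is deliberate: a
transcript printed at exactly a threshold fold belongs in the
above-threshold set by the conventions of the fold tables this package
ships.  Canonical cutoffs, all config-exposed: 1.0 RPKM (stringent,
ANOVA route), 0.5 (lenient, SAM route), 3.0 (splicing gate).

## Differential expression

**ANOVA route.** One-way fixed-effects ANOVA per feature on
log2(RPKM+1), by default across the two groups of the named contrast
(an all-four-groups F-test is available).  Selection combines fold ≥ 1.5
and p ≤ 0.05 with AND by default (OR available); the stricter rule is
the default because the two criteria guard against different failure
modes (large noisy folds at low expression; tiny but consistent shifts).
Features with zero within-group variance everywhere are flagged, not
scored.  The F statistic reduces exactly to the squared pooled-variance
t statistic for two groups; the test suite asserts this identity to
1e-10.

**SAM route.** d_i = (x̄₁ᵢ − x̄₂ᵢ)/(sᵢ + s₀) with sᵢ the pooled standard
error.  The statistic is computed on log2(RPKM+1): the moderated-d
construction assumes roughly scale-free noise, and on raw RPKM the
median fudge factor dominates every low-abundance feature, making the
ranking follow abundance rather than evidence.  Fold changes and the
fold cutoff remain on RPKM-scale group means to match the reporting
convention (magnitude + up/down flag).  s₀ defaults to the median of
sᵢ — robust, and exactly reproducible by an independent oracle — with
the original coefficient-of-variation percentile search available.
Permutations shuffle group labels across the contrast's samples only; a
3v3 contrast has C(6,3) = 20 assignments and is enumerated exhaustively
(requests exceeding the distinct count fall back to exhaustive with a
log notice).  The FDR at threshold t is the median over permutations of
the false-call count at t divided by the observed call count; the
reported curve takes the running minimum over thresholds ≤ t (the
thresholds at which a feature with |d| = t is actually called), which
makes it non-increasing in t, and a feature's q-value is this curve at
its own |d|.  Selection: q ≤ 0.25 AND fold ≥ 1.5.

**Route concordance.** `top_n_overlap` ranks both routes' outputs by
|signed log2 fold| (or the statistic) and reports shared/unique ids
among the top n (default 100).  Ties break lexicographically on feature
id so outputs are stable across reruns.

## Alternative splicing (reciprocal isoform pairs)

For each gene the junction fraction is f_j = c_j divided by the mean
count over all junction and exon features of the gene in that sample.
For a cassette event the per-sample inclusion ratio is
I = f_incl/(f_incl + f_excl); multiple inclusion junctions combine by
the mean of their fractions before the ratio (sum available), which
keeps the two-junction inclusion side on the same footing as the single
skip junction.  Because both sides share the gene-mean normalizer, it
cancels: I from fractions equals I from raw counts to machine precision
(asserted in tests).

ΔI for a contrast is the mean of per-sample I in the case group minus
the control group — per-sample-then-average rather than pooled-count,
so the permutation test resamples the same unit as the estimator (a
pooled mode is available).  Samples with undefined I (zero coverage) are
dropped from the mean; events undefined in more than half the samples
of either group are excluded rather than imputed.  The permutation null
shuffles group labels with |ΔI| as the statistic, exhaustively whenever
at most 500 assignments exist.  FDR across events is Benjamini–Hochberg.
An event passes at |ΔI| ≥ 0.2 (a 20% inclusion change) and BH FDR ≤ the
configured level (default 0.25).

A structural note: with three replicates per group the exhaustive
permutation p has a floor of 2/20 = 0.1 (the identity assignment and
its complement always reproduce the observed |ΔI|), so the BH gate at
n = 3 can only admit events when a sizable fraction of tested events
carry signal.  This is a property of the replication level, not of the
implementation; power statements in the tests therefore address the
ΔI cutoff at adequate coverage.

## Drug-response taxonomy

With d, t the signed log2 folds of D-vs-N and treated-vs-N,
θ = log2(τ) (τ default 1.5, matching the DE fold cutoff) and margin m
(default 0):

* |d| ≥ θ: **positive** if |t| < |d| − m; **negative** if |t| > |d| + m;
  otherwise **unresponsive**;
* |d| < θ: **side_effect** if |t| ≥ θ; otherwise **unaffected**.

"Toward normalcy" is strict shrinkage of |log2 fold| regardless of
sign: an overshoot past normal still counts as positive unless it
exceeds the diabetic displacement itself, in which case it is negative —
the simplest rule consistent with every printed example in the shipped
tables; the margin parameter exposes the fuzziness of the boundary.
The five categories are mutually exclusive and exhaustive for any
finite (d, t) (property-tested), and the rule is symmetric under a
joint sign flip.  Splice events are partitioned across contrasts:
responsive to a treatment (passes in D:N, not in the treated contrast),
unresponsive (passes everywhere), exacerbated (passes only under
treatment), jointly and per treatment — seven categories that partition
the union of all passing events.

## Synthetic data: what it emulates, and its semantics

Defaults: 2000 transcripts, 4 groups × 3 replicates, nominal library
1 × 10⁶ reads per sample (a scaled stand-in for real retinal libraries
in the tens of millions), 10% of transcripts differentially expressed
with |log2 fold| drawn from {0.585, 1, 2, 4.3} (1.5- to ~20-fold, the
span of the shipped tables), NB dispersion 0.05 (a conventional value
for biological replicates; the real study's replicate variance is
unknown), 100 cassette events with planted ΔI from {0.2, 0.3, 0.4}
(half the events null), and 5% side-effect-only transcripts.  Treatment
patterns act multiplicatively on the disease log2 fold: full reversal
(×0), partial reversal (×0.4), exacerbation (×1.6), none (×1), and
side-effect-only (disease 0, treated effect from the grid) — spanning
every category of the response taxonomy so recovery is testable.

Base expression is lognormal (log2 sd 1.7) and normalized so that the
counts it implies through the RPKM definition sum to the nominal
library in the baseline state: the ledger's `base_expression` *is* the
expected baseline RPKM, with no hidden scale between truth and
simulation.  Expected counts are C = RPKM · L_kb · N/10⁶ per the RPKM
definition, with the same nominal depth N for every group.  This is a
deliberate choice of semantics: renormalizing each group's realized
total to one fixed depth (what a sequencer does) would impose a
composition shift on every null transcript, contradicting the ledger
that declares them null and poisoning any false-discovery measurement.
The cost is that treated groups' realized column sums run above the
nominal depth by the planted multiplicative mass; baseline column sums
match the target within sampling noise.  Planted effects are restricted
to transcripts below the 98th abundance percentile so that a 20-fold
change on a dominant transcript cannot swamp the library.  Real
RNA-seq, by contrast, has fixed depth and real composition bias — the
simulator tests the statistics, not RPKM's robustness to composition.

Exon counts are an exact multinomial split of each transcript count by
exon length (conservation holds exactly, asserted in tests).  Junction
counts are Poisson with mean count · span/L, where the effective
junction span (50 bp) plays the role of an exon length, keeping
junction and exon features on one RPKM-like scale; cassette-event
junctions are thinned by the group's planted inclusion fraction (the
two inclusion junctions) or its complement (the skip junction).  Not
modeled: read-level simulation, alignment error, multimapping, GC bias,
isoform-level ambiguity (each gene carries one transcript model).

Every stochastic call takes a seed; a dataset is byte-identical across
reruns of the same config and seed.  The pipeline derives per-stage
seeds from a single master seed by hashing the stage name.

## Evaluation strata in the recovery tests

Recovery assertions run at the default conditions (seed 1) and are
stratified by detectability, because several planted effect sizes sit
*on* the decision boundaries by construction: a 1.5-fold planted change
equals the fold cutoff itself, and with n = 3 and dispersion 0.05 the
fold estimate's noise (log2 sd ≈ 0.27) makes such features coin flips
for any threshold rule.  The tests therefore assert:

* DE: ≥ 90% of planted 4-fold transcripts pass the SAM route, with
  realized false-discovery proportion ≤ 0.35 over all calls;
* splicing: ≥ 95% of planted ΔI = 0.4 events clear the 0.2 cutoff among
  tested events with coverage ≥ 100 (total event-informative junction
  reads across the contrast's samples);
* response: ≥ 95% category agreement with planted patterns on features
  with planted |log2 effect| ≥ 2 and mean transcript count ≥ 100
  (the "none" pattern maps to a measure-zero category at margin 0 and
  is not scored).

Passing these says the estimators and decision rules work where the
signal is identifiable at this replication level; it says nothing about
boundary-sized effects, which are genuinely undecidable at n = 3, nor
about real-data artifacts the simulator omits.

## Numerical choices and degenerate inputs

Fold changes use pseudocount 0 on RPKM-scale means; features with both
group means zero are flagged undefined and excluded from selection, and
a zero mean on one side yields an infinite ratio that sorts first and
classifies as changed.  Permutation p-values compare with a 1e-12
tolerance so ties at the observed statistic count as hits.  BH is
applied only across tested events.  The SAM permutation matrix, s₀, and
all cutoffs are recorded in each result's params; `passes` is always a
pure function of stored columns and recorded cutoffs (asserted in
tests).  Top-N ties break lexicographically.  Manifest files exclude
wall-clock time so reruns are byte-identical.

## Known limitations

* No multi-isoform deconvolution: transcript counts are taken as given,
  and the simulator plants one transcript per gene.
* No TMM/quantile/upper-quartile normalization — the pipeline is raw
  RPKM by design, and inherits RPKM's composition sensitivity on real
  data.
* Only cassette-style reciprocal pairs are scored; alt-5'/alt-3' and
  intron retention are out of scope.
* The response taxonomy classifies point estimates of fold changes; it
  propagates no uncertainty, so boundary-sized effects are unstable
  calls at small n.
* With three replicates the exhaustive permutation floor (p = 0.1)
  limits FDR-based selection, as discussed above.
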