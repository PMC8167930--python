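# Methods

This note records the models, the parameter choices that matter, what the
synthetic generators do and do not emulate, and the numerical decisions a
maintainer would want to know. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Structural-variant layer

An SV catalog is a per-sample list of breakpoint pairs typed DEL/DUP/INV/TRA.
Intra-chromosomal records carry `size = |pos2 − pos1|`; translocations are
sizeless and are excluded from all size medians. Medians use the standard
convention (mean of the two central values for even cardinality), so a
[2, 4, 6, 8] kb deletion list has median 5 kb.

### HRD test

The five positivity criteria are strict inequalities (count > 50,
qualifying fraction > 0.70, median DEL < 10 kb, median DUP < 50 kb); the
boundary cases therefore test negative, and the test suite pins each
boundary exactly. Interpretive choices:

* **Criterion-2 denominator** includes inversions (they count toward total
  SVs but never toward the qualifying numerator). The source rule does not
  say; this is the natural reading of "70% of the structural variants".
* **Predominant type** is the single most frequent among DEL/DUP/TRA. A tie
  between DUP and DEL/TRA evaluates both branch criteria and accepts either,
  mirroring the OR that already joins criteria 4 and 5. This is the most
  permissive reading consistent with the rule text.
* A branch criterion that cannot be evaluated (no sized records of the
  needed type) is false and flagged `insufficient`.

### Focality

No published detector accompanies the rule "the SV pattern was not focal",
so the detector here is this package's own: breakpoints are pooled per
chromosome (translocations contribute one breakpoint to each partner;
intra-chromosomal records contribute both ends), sorted, and merged into
clusters while consecutive gaps are ≤ `gap_bp` (default 1 Mb). A cluster
qualifies when its span is ≤ `max_cluster_span_bp` (default 10 Mb) and holds
≥ 10 breakpoints; the catalog is focal when the fraction of breakpoints in
qualifying clusters reaches `focal_fraction` (default 0.5). All four knobs
are exposed. Amplification-driven focality is approximated by the same
clustering (copy-number input is out of scope); a DUP-dominated cluster
looks identical to the detector.

### Genome stability

Focal catalogs are *locally rearranged*; otherwise > 200 SVs is *unstable*,
≤ 50 *stable*, 51–200 *scattered*. The 50-SV boundary of the stability
ladder and criterion 1 of the HRD test coincide numerically but are
independent outputs.

## Mutational-signature layer

Substitutions are binned into the canonical 96 channels (six
pyrimidine-centred classes × 16 flank pairs, class-major order). Purine-
reference records are reverse-complemented, making counting strand-
symmetric; flanking bases come from the input table, so no reference genome
is needed. Ambiguous bases skip the record and are tallied.

Exposures are fitted by nonnegative least squares against a user-supplied
reference matrix whose columns are probability vectors — a single
deterministic solve, deliberately *not* a de-novo extraction: the biomarker
consumed downstream is only the cohort ranking of the signature-3 fraction.
"High BRCA signature" means the top ⌈n/5⌉ samples by **normalized** exposure
fraction (raw exposure would conflate mutation burden with signature
composition); ties break by sample id. Cohorts under 5 samples have the flag
withheld, since a quintile is not meaningful.

## DDR composite and hierarchical rank

The composite call is the OR of the four biomarker flags; unknown inputs
propagate (a sample with an unknown flag and no positive flag has an unknown
call and is excluded from downstream tests with a reason). The gene-panel
flag takes its deleteriousness adjudication from the input annotation —
nonsense/frameshift/splice/deleterious-missense qualify, biallelic
loss-of-function is tiered "strong" — with no variant-effect predictor
dependency; germline and somatic hits both count.

The hierarchical rank score is lexicographic — HRD positives above
negatives, then descending SV count, then descending signature-3 fraction,
then sample id — mapped to [0, 1] as `1 − (rank − 1)/(n − 1)`. The source
figure lists the three components without coefficients, so an ordering
rather than a weighted sum is the honest choice; the therapeutic quadrant
depends only on the binary call, not on this score.

## Replication-stress layer

Scores operate on any variance-stabilised log-scale matrix. For raw counts a
`log2(1 + CPM)` normaliser is provided in place of a dispersion-fitted
transform (rlog-like machinery would drag in a differential-expression
stack for what the z-scoring removes anyway: per-gene location and scale).
The per-term sig-score is the weighted mean of per-gene z-scores
(mean/SD across samples, SD with one delta degree of freedom); zero-variance
genes score z = 0 but stay in the weight normaliser, missing genes are
dropped with a log line. Direction weights (±1) travel in the GMT
description field (`weights=+1,−1,…`); a plain GMT defaults to all +1. The
composite is the unweighted sum over terms ("totaling" read literally), so
duplicating a term doubles its contribution — a documented property, not a
bug. Term choice is upstream of this package: the nine bundled synthetic
sets are illustrative stand-ins, not curated pathway memberships.

Stratification is pure ranking: top ⌈n/5⌉, ⌈n/4⌉, or ⌈n/2⌉ labelled high,
ties broken by sample id. Source cohorts alternate between quintile and
quartile cut points without a rule, so both are first-class and the pipeline
asks the caller to pick (`median` is used in the bundled runs). The
squamous/classical subtype call is a plumbing centroid classifier (argmax of
two marker-set sig-scores, ties to classical) standing in for consensus
clustering, so association tests can run on synthetic cohorts.

## Pharmacotyping

Normalisation anchors each (sample, compound) group at its own controls:
media-blank mean subtracted everywhere, then 0% at the actinomycin-D kill
mean and 100% at the vehicle mean. Inverted controls (vehicle ≤ kill) are a
hard error. Values outside [0, 100] are kept — clipping would bias the
fitted plateaus.

The dose-response model is the four-parameter logistic in log-dose space;
the reported EC50 is the *relative* EC50 (curve inflection). Fitting is
bounded least squares (hill ∈ [0.01, 20], log-EC50 within ±4 decades of the
dosed range) from a fixed 3 × 3 grid of starts (log-dose quartiles × hill
{0.5, 1, 2}); the best converged start wins, so fits are deterministic.
Status is `no_response` when the fitted span is < 20 percentage points or
the EC50 falls more than two decades outside the dosed range, `ambiguous`
when no start converges; a perfectly flat response short-circuits to
`no_response` with the data span reported. The platinum sensitivity call is
strict: EC50 < 10 µmol/L (threshold configurable per compound).

Group comparisons are two-sided. Mann-Whitney uses the exact null when both
groups have n ≤ 8 and the pooled values are tie-free, otherwise the normal
approximation with tie correction; the test suite checks the exact path
against full permutation enumeration for all group sizes up to 6 vs 6.
Fisher's exact test is two-sided by hypergeometric enumeration; chi-square
is Pearson's without continuity correction (Yates available via a switch).
The 2×2 quadrant maps (DDR-deficient, high-stress) → both drug classes,
single positives → their one class, double negatives → neither; an unknown
flag yields `unassessable`.

## Synthetic generators: what they emulate, and what they do not

All generators draw from child generators of one integer seed; equal seeds
give byte-identical bundles. The model genome is 22 autosomes with
hg19-like lengths embedded as constants (no reference download); breakpoint
positions are length-weighted uniform.

* **SV catalogs.** Sizes are log-normal with σ = 0.5 in log space around the
  requested median (`exact_median` rescales the draw so the sample median is
  exact — used by the boundary sweeps); translocations are sizeless. The
  chromothripsis profile confines ~90% of records to one 5-Mb window so the
  clustering detector fires. Real rearrangement processes (replication-based
  mechanisms, clustered templated insertions, copy-number coupling) are not
  modelled: passing tests show the *rules* behave as printed, not that the
  profiles are biologically realistic.
* **Mutation catalogs** are multinomial draws from the signature mixture;
  the synthetic reference signatures are Dirichlet(0.1) columns — sparse and
  nearly mutually orthogonal like real substitution signatures, which makes
  exposure recovery easier than for strongly collinear real references
  (flat-profile signatures would degrade NNLS identifiability).
* **Expression cohorts** plant a latent stress level per sample (unit-normal
  spread; squamous mean +1, classical −1, which plants the subtype
  association) and shift stress-set genes by `w · rs_effect · rs_level`,
  subtype markers by +2, with Gaussian noise on the log scale. Library-size
  effects, batch structure and count overdispersion are not simulated.
* **Viability plates** put the 4PL curve on a raw-signal scale with blank /
  vehicle / kill anchor wells and multiplicative log-normal noise of the
  requested CV (unit-mean), exercising normalisation end to end.
* **Cohort bundles** cycle samples through the four quadrants, couple EC50s
  to the planted biology at a default 10× sensitive:resistant ratio (the
  source reports only a ~15× spread between extreme samples, not a group
  effect size, so the ratio is this package's configurable choice), and give
  DDR-deficient samples high-burden scar catalogs, high signature-3
  fractions and (every other one) a biallelic BRCA2 frameshift. Default
  conditions are expression noise SD 1.0, stress effect 2.0, viability
  CV 0.1, n = 40; `CohortDesign.noiseless()` zeroes the noise for the exact
  recovery contracts. One dose series per compound brackets both planted
  EC50s (8-point half-log).

## Problem sizes in the bundled runs

The test suite runs the rule-oracle equivalence on 1,000 random ≤ 20-record
catalogs, exposure recovery on 100 catalogs of 5,000 mutations, EC50
recovery on 100 seeded plates, stress-score recovery at n = 50, the
Monte-Carlo profile-fidelity check over 100 seeds per profile, and the
end-to-end quadrant check at n = 40 with the association property over 40
expression cohorts — sizes chosen so the full suite completes in well under
a minute per property while keeping the Monte-Carlo assertions
well-powered. The acceptance script's sweeps use 80–301-record catalogs per
step, one step per unit of the swept quantity.

## Known limitations

* The HRD test consumes an SV catalog as given; caller quality (the
  upstream variant caller) dominates real-world behaviour and is out of
  scope here.
* The focality detector is a heuristic stand-in for proper chromothripsis
  scoring (no oscillating copy-number evidence, no randomness test on
  breakpoint spacing).
* Signature exposures are supervised; samples carrying signatures absent
  from the reference will smear onto the nearest available columns.
* The hierarchical DDR score is an ordering, not a calibrated quantity;
  downstream use should treat it as a rank.
* EC50s from curves with poorly bracketed inflections are flagged rather
  than extrapolated; repeated-dosing schedules are metadata only — the
  curve model is shared across assay formats.
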