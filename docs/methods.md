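# Methods

## Problem and protocol

The package classifies individual heartbeats of two-lead ambulatory ECG
into NORM (normal sinus), LBBB and RBBB (left/right bundle branch block)
under the inter-patient protocol: the training records (DS1) and test
records (DS2) come from disjoint patients. For the canonical corpus (the
MIT-BIH Arrhythmia Database) the shipped division
(`src/bbbdetect/data/mitdb_split.yaml`) is the widely used 22/22 record
split of de Chazal et al. (2004), with the four paced records excluded per
the AAMI recommendation. The lists are data, not code: a YAML file a user
can replace for another corpus.

QRS detection is out of scope; the annotated R positions are used
directly. Annotation symbols other than N/L/R are kept as OTHER at load
time and dropped during beat construction, so the classified beat stream
matches the annotation stream minus non-studied beats.

## Preprocessing

* Window: samples [r − 100, r + 100) around the annotated R peak — 0.278 s
  per side at 360 Hz, 200 samples total, the R sample at offset 100.
* Normalization: per beat, per lead, to zero mean and unit *population*
  standard deviation. Per-lead (rather than joint two-lead) normalization
  is chosen so each lead independently satisfies the zero-mean/unit-SD
  property; a flatline lead is a hard error and the beat is skipped with a
  logged reason.
* No filtering or denoising anywhere: raw morphology is the feature.
* RR interval: time since the previous *studied* beat's R peak, in
  seconds, unscaled; the first beat of a record copies the following
  interval so beat and RR streams stay aligned. Records with fewer than
  two studied beats yield no beats (RR undefined).
* Edge policy: windows crossing a record boundary are edge-replicated by
  default (keeps beat counts aligned with annotation counts); a `skip`
  mode drops them instead, reporting which.

## Feature representations

* Morphology: lead-A samples ‖ lead-B samples ‖ RR (401-dim; 201-dim for a
  single-lead configuration).
* ICA: one basis per lead, fitted on the designated basis subset — per
  training record, the first k beats of each class in temporal order
  (k = 10 NORM, 100 LBBB, 80 RBBB by default; 620 beats on the canonical
  corpus). Choosing the *first* k beats is a deterministic reading of an
  unspecified choice; a seeded random selection would be an easy variant.
* FastICA settings: deflation (one-by-one) extraction, log-cosh (tanh)
  contrast, PCA whitening to the component count, tolerance 1e-4, at most
  1000 iterations, seeded. The basis rows are the *mixing* waveforms (the
  directions beats are composed of), so projecting a beat through the
  pseudo-inverse of the component matrix yields its least-squares
  coordinates — equivalently its source activations. Projection applies no
  mean subtraction: beats are already per-beat zero-mean.
* Non-convergence of some deflation components within the iteration cap is
  logged (with iteration diagnostics) rather than fatal by default — a few
  unconverged components out of 100 do not harm the basis as a feature
  space — and a `strict=True` switch turns it into an error.

## Classifiers

* Centroid (NORM vs LBBB): class-mean vectors, Euclidean distance. No
  tunable parameters.
* WLDA (NORM vs RBBB): the weighted pooled scatter
  Σ = Σᵢ wᵢ Σₖ (xᵢₖ−mᵢ)(xᵢₖ−mᵢ)ᵀ is used exactly as written — a weighted
  *sum* of outer products with no division by class size. The weights
  absorb the scale, and with equal priors the decision is invariant to
  uniform scaling of (w₁, w₂) anyway (Σ → cΣ scales both discriminant
  differences by 1/c). Posteriors are softmax over the linear
  discriminants with a max-subtraction overflow guard. If Σ is numerically
  singular (condition number > 1e12), a ridge ε = 1e-6 · trace(Σ)/d is
  added to the diagonal and logged (with an absolute floor of 1e-6 for the
  zero-trace degenerate case); this is needed for tiny synthetic fits, not
  for corpus-scale ones. Priors are fixed at 0.5/0.5.
* Linear SVM (LBBB vs RBBB): scikit-learn's `LinearSVC` (liblinear), L2
  regularization, per-class penalty C·class_weight, fixed random state for
  determinism. The weighted-SVM variant used in classifier-comparison
  experiments exposes the class weights; its grid (minority weight
  ∈ {1, 2, 5, 10} × the C grid) is a reconstruction, since only "
  experimentally determined" is documented.
* Tie rules: any exact tie (equidistant centroids, posterior exactly 0.5,
  decision value exactly 0) resolves to NORM when NORM is one of the
  pair's labels, else to the pair's first label — the same rationale as the
  ensemble's NORM default. Exact ties are measure-zero in floating point;
  the rule matters for the ensemble's three-way disagreement case, which is
  common.

## Ensemble

Votes: v1 ∈ {NORM, LBBB} (centroid), v2 ∈ {NORM, RBBB} (WLDA),
v3 ∈ {LBBB, RBBB} (SVM). A label with ≥ 2 votes wins; the three-distinct
case (v1=LBBB, v2=RBBB, v3 arbitrary cannot agree) returns NORM. The
per-beat vote triple is always retained in the prediction audit table,
since per-classifier breakdowns are needed for comparison reports.

Single-lead configurations use 201-dim morphology and 101-dim ICA vectors
(half the two-lead sizes plus RR), by construction.

## Parameter selection

Beat-level stratified 10-fold CV on the training set, hand-rolled
round-robin within each shuffled stratum so per-class fold sizes differ by
at most one and strata smaller than k degrade to empty per-fold strata
with a warning (rather than erroring). The ten held-out confusion matrices
are summed before metrics are computed; summing avoids the distortion of
averaging per-fold rates when a fold lacks a minority class (an effect the
test suite demonstrates on a rigged fold assignment). Folding is
beat-level, which mixes patients *within* the training set; this matches
the stated protocol, and a record-level alternative would be stricter but
differently sized. The ICA basis is fitted once on the full training-set
selection, not refit per fold — refitting would be stricter but is not
indicated; the basis is unsupervised and fitted on a small designated
subset.

The WLDA grid is w₁ ∈ {0.01, …, 0.10} × w₂ ∈ {0.4, 0.5, 0.6} (30 pairs),
maximizing RBBB sensitivity with RBBB positive predictive value as the
tie-break; a full tie keeps the first pair in grid order. The SVM grid is
C ∈ {0.001, 0.01, 0.1, 1, 10, 100}, maximizing the mean of the two class
sensitivities with the smallest C winning ties. Tie comparisons are exact
(count ratios), and undefined metrics compare below everything.

## Evaluation

Confusion matrices are rows = reference, columns = algorithm. Per class:
Se = diag/row, PP = diag/column; NORM's values are reported as Sp and NP.
Undefined values (zero denominator) are NaN internally and rendered "-",
never 0 or 100. Report tables round half-up to one decimal in percent —
the convention of printed clinical tables, distinct from banker's
rounding — while machine outputs keep raw fractions. Per-record tables and
a lead-configuration comparison table mirror the standard report layouts.

## Synthetic data

The generator exists so the entire pipeline — including the WFDB-format
loader — runs and is tested without any download. Templates are sums of
Gaussian bumps sketching the qualitative morphologies (NORM: narrow
central QRS with P and T; LBBB: widened notched complex with discordant T;
RBBB: rSR'-like late deflection in lead A, wide slurred S in lead B).
These are controllable class geometries, not physiological ECG models.

Defaults, chosen once as the package's study conditions: 3000/300/300
NORM/LBBB/RBBB beats per subset (the corpus' ~10:1:1 imbalance at roughly
one-twelfth of corpus scale, keeping the default test run and the
acceptance script fast on one CPU) over 18/2/3 virtual patients per
subset, mirroring the record structure the 10/100/80 basis plan expects;
white noise SD 0.15 and per-beat amplitude jitter SD 0.10 relative to
bump amplitudes of order 1; patient-level perturbation of bump amplitudes
(SD 10%) and centers (SD 1.5 samples), fixed per patient, emulating
inter-individual variation; class RR means 0.80/0.85/0.75 s with SDs
0.05/0.06/0.05 s, truncated positive.

What passing on this data shows — and does not: the defaults are separable
by construction, so the pipeline recovers every class nearly perfectly and
both CV searches tie at perfect performance, exercising the documented
tie rules rather than a non-trivial selection. That validates the
machinery (feature flow, CV protocol, fusion, reporting), not real-data
performance: real beats overlap heavily between NORM and LBBB, are
non-Gaussian, and carry artifacts the generator does not model (baseline
wander, electrode noise, rhythm context). Real-corpus performance must be
measured with `bbbdetect reproduce` against a local copy of the database.

## Numerical and degenerate-input choices

* 0-based sample indexing throughout.
* Population (divide-by-N) standard deviation in normalization.
* ICABasis caches the pseudo-inverse and validates it on construction
  (residual ‖C·C⁺·C − C‖ < 1e-6‖C‖).
* Models and bases serialize to versioned JSON; round-trips are tested.
* Fewer than two studied beats in a record: no beats emitted (RR
  undefined), all skipped with reasons.
* Seeds: every stochastic step (generator, FastICA, fold shuffling, SVM
  shuffling) takes an explicit seed; the pipeline derives sub-seeds by
  small fixed offsets from one run seed.

## Known limitations

* The AAMI five-class problem (S/V/F/Q beats) is out of scope; only
  N-class beats (NORM, LBBB, RBBB) are classified, and a deployed system
  would need an upstream N-class filter.
* The MIT-format reader covers the dialect the study corpus uses (single
  multiplexed signal file, formats 212/16); it is not a general WFDB
  implementation.
* No kernel SVM, no probability calibration, no stacked or weighted
  fusion — majority voting only, as specified.
* Metrics carry no confidence intervals; per-record tables expose
  between-patient variability instead.
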