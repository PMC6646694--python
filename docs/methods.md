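# Methods

## Connectivity estimation

Region time series (frames × 116 regions, TR = 2 s by default) are
band-pass filtered with a Chebyshev type-I filter, order 4, 0.5 dB
pass-band ripple, 0.01–0.08 Hz, applied forward–backward
(`sosfiltfilt`) so no phase shift distorts inter-regional correlations.
The filter design beyond the band edges is a package choice exposed as
configuration (`filter_order`, `filter_ripple_db`); with the default
design the effective (squared) magnitude response retains ≥ 90 % of a
0.04 Hz sinusoid and passes < 1 % of a 0.2 Hz sinusoid.  Nuisance
regression follows filtering by default (a config switch reverses the
order): region series are OLS-residualised against an intercept plus
the supplied confounds — typically mean white-matter, CSF and global
signals and six motion parameters — optionally augmented with their
first-order backward differences (first element padded with zero so the
frame count is preserved).  Collinear confound columns are pruned with
a warning rather than failing, since motion parameters are often
near-duplicated in short runs.

Connectivity is the Pearson correlation between region series, mapped
through z = atanh(r) with |r| clipped at 1 − 10⁻⁷ so duplicate series
stay finite.  The diagonal is zero and excluded from all statistics;
zero-variance regions get zero rows/columns with a warning.  Discarding
initial saturation frames (10 in the reference acquisition) is the
caller's responsibility (`discard_frames`); head-motion subject
exclusion happens at acquisition time and is only documented here as
the conventional 2 mm / 2° thresholds.

## Network-based statistics

The two-group comparison is the component-based permutation procedure
described in the README.  Numerical and design choices:

* **Primary threshold.**  Accepted as a t value or a one-tailed p (the
  p form is converted through the t distribution at the pooled df).
  The reference configuration is t = 3.  Raising the threshold can
  only shrink components (tested property).
* **Sign-test mask.**  Exact binomial, success probability ½, zeros
  dropped, one tail toward the observed majority sign, α = 0.05,
  union over the two groups.
* **Tails.**  Edge t-tests are one-tailed; each direction
  (patient > control, control > patient) runs as a separate NBS pass
  with its own null distribution, and the default report is the union
  of both passes.
* **Permutations re-run the whole pipeline, mask included.**  The mask
  is selected from the data, and the union rule favours edges where a
  chance group split looks coherently nonzero — which correlates with
  a large between-group t.  Holding the observed mask fixed inside the
  permutations hides that selection from the null and inflates the
  familywise error severalfold on dependent connectomes (we measured
  ≈ 0.25 against a nominal 0.05 on structured synthetic nulls).
  Recomputing the sign-test mask from each permuted labelling restores
  calibration; `recompute_mask=False` retains the fixed-mask variant
  for comparison.
* **P-value estimator.**  p_FWE = (1 + #{null max ≥ size}) /
  (1 + n_perm); ties count against the observed component and p is
  never zero.
* **Implementation.**  All edge-level arithmetic is vectorised over
  the upper triangle; per-permutation group sums, sums of squares and
  sign counts are single matrix products, and the binomial tail is a
  lookup table, so a 116-region study with 5 000 permutations runs in
  seconds.  Components come from `scipy.sparse.csgraph`; the test
  suite checks their sizes against an independent breadth-first-search
  oracle.

## Edge patterns and network level

Pattern classification is a total function of the two signed group
means: control < 0 < patient → pathological positive; 0 < control <
patient → hyperconnectivity; control < patient < 0 (both negative) →
hypoconnectivity.  The remaining sign configurations (a positive edge
that weakens or flips negative) are labelled *indeterminate* rather
than silently binned — no such edge occurs in the bundled published
set.  Region counting de-duplicates by label; the bundled table keeps
one region pair that is printed twice.

Network strengths use the pair-count definitions W_X and W_XY given in
the README; the pair-count-weighted mean of all 28 strengths equals
the global off-diagonal mean exactly (asserted to machine precision),
and the between-strength is made exactly symmetric in its arguments by
canonicalising the block orientation before averaging.  Group
comparison is a two-sided pooled t per measure with Benjamini–Hochberg
correction across the 28-measure family; degenerate-variance rows are
excluded from the family with a flag.  The bundled region→network
partition is a reconstruction of the usual AAL-based seven-network
grouping (sensory-motor, auditory, visual, attention, default-mode,
subcortical, plus the 26 cerebellar regions as one network); studies
with their own assignment should supply a two-column (region, network)
table, and network-level numbers reported elsewhere are reproducible
in structure, not value, unless the original partition is used.

## Clinical statistics

Summary-table group tests use the pooled-variance (Student) t — which
reproduces the printed p-values of the bundled demographic table from
its printed mean ± sd, unlike Welch — with df = n₁ + n₂ − 2, and the
Pearson chi-square without continuity correction for the 2 × 2 sex
table.  Two printed values are not reproducible from the printed
summaries by any standard form (the MoCA p of 0.058 and the sex
chi-square p of 0.970); they are carried in the fixture for reference
but never asserted.

The adjusted association fits edge_z ~ 1 + variable + age + sex +
education by OLS within the patient group (sex coded 0/1; any
consistent coding leaves the other slope tests unchanged), reporting
the variable's slope, standard error, t and p.  Zero-variance
covariates are dropped, which reduces the model to a simple regression
in the limit; remaining collinearity is an error naming the columns.
P-values are uncorrected by default, matching the exploratory use of
the model; `associate_edges(..., fdr=True)` applies BH.

## Synthetic-data generator

Studies are drawn frame-by-frame from a multivariate Gaussian whose
correlation matrix encodes the structure the analysis assumes: within
each of the seven networks a constant r = 0.3; an anticorrelated
sensory-motor ↔ auditory block at r = −0.15 (the "healthy antagonism");
and per-group target correlations on a planted edge set — by default
30 sensory-motor/auditory edges forming one connected bipartite
component, anticorrelated (−0.15) in controls and flipped positive
(+0.15) in patients.  Defaults of 33 patients vs 24 controls, 243
frames at TR = 2 s mirror a retained-frame count of a ~8.5-minute
acquisition after discarding 10 saturation frames; planted magnitudes
sit in the |z| ≲ 0.34 range of the published group means.  A per-edge
effect size d is converted to a z offset via the large-sample standard
deviation 1/√(frames − 3).  Arbitrary overrides can break positive
semi-definiteness, so the implied matrix is repaired by eigenvalue
flooring at 10⁻⁶ and rescaling to unit diagonal.  Clinical covariates
are drawn around realistic early-T2D group summaries; `clinical_effect`
adds a per-subject z offset on the planted edges proportional to the
subject's centred clinical value, coupling edge strength to (say) FPG.

What the generator does *not* emulate: haemodynamic response,
autocorrelated or non-Gaussian noise, motion artefacts, scanner drift,
or spatial smoothness.  Frames are i.i.d., so passing calibration and
power checks demonstrate the statistics under the model's assumptions,
not robustness to realistic fMRI noise; with temporally autocorrelated
series the subject-level z variance would be larger and per-edge
effect sizes correspondingly smaller.

## Validation experiments and problem sizes

The self-checks in `fconn.validation` (run by the test suite and by
`scripts/acceptance.py`) use: 200 null studies × 500 permutations for
familywise calibration of a one-tailed pass (a union of two
independent 0.05-level tails would be expected to reject at up to
twice the single-tail level, so calibration targets one pass); 100
studies × 1 000 permutations for power at per-edge d = 1, where
detection means an FWE-significant component overlapping the planted
edges; 500 random 20-node graphs for the component-size oracle; 100
random 116-region matrices for the decomposition identity; 1 000
simulations at n = 33 for association CI coverage and type-I rate; and
two full-pipeline runs at reduced size (8 vs 6 subjects, 80 frames,
200 permutations) compared byte for byte for determinism.  These sizes
keep the whole battery within a few minutes on one CPU while leaving
the binomial acceptance bounds meaningful.

## Known limitations

* The NBS familywise guarantee is for the component null; edge-level
  p-values inside a significant component are descriptive only.
* The sign-test mask at α = 0.05 is itself uncorrected; it is a
  screening device, not an inference.
* The bundled partition is a reconstruction; faithful reruns of any
  particular published network-level analysis require that study's own
  region→network table.
* Image-space preprocessing (slice timing, realignment, normalisation,
  smoothing) is out of scope; the pipeline starts from region (or
  labelled-voxel) time series.
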