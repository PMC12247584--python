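# Methods

This note documents the models, defaults, and design choices behind
`memconn`, and what the synthetic-data checks do and do not establish.

## Data model

A cohort consists of per-subject, per-run ROI time series (T timepoints ×
R ROIs with a sampling interval and a run type in {rest, movie,
sensorimotor}), a matching confound table per run (six rigid-body motion
parameters, their temporal derivatives and quadratics, up to six aCompCor
components, framewise displacement in mm, standardized DVARS, global
signal), an optional stimulus-onset table for task runs, an atlas label
table (ROI id, name, hemisphere, network), and a subject table (behavior
scores, age, sex, mean FD, fluid intelligence, cognitive screen). The
default atlas preset has 400 cortical parcels in 17 networks plus 6
hippocampal ROIs (head/body/tail × hemisphere), with 13 parcels in the
DMN-C role (7 left / 6 right) and 34 in DMN-A; the remaining 353 parcels
are spread as evenly as possible over the other 15 networks, since only
the role sets' sizes matter to any downstream computation.

## Denoising and connectome estimation

Per run, in a fixed order:

1. **Nuisance regression.** One OLS design concatenates the confound
   columns (global signal included by default; it is a config switch
   because results are known to be sensitive to it), spike indicator
   columns (one per timepoint with FD > 0.6 mm or standardized DVARS > 2 —
   strict inequalities), and, for sensorimotor runs only, a stimulus
   regressor built by convolving onset stick functions with a canonical
   double-gamma HRF (gamma shapes 6 and 16, unit scale, undershoot ratio
   1/6; response peaks near 5 s). Constant and duplicate columns are
   pruned with a warning; a rank-deficient design after pruning is an
   error naming the columns.
2. **Band-pass.** 0.008–0.1 Hz, realized as an order-2 Butterworth applied
   forward-backward (zero phase). The filter is specified spectrally, not
   bit-wise: the conformance surface is ≤ 5% passband amplitude error and
   ≥ 80% stopband attenuation, which the tests check by projection onto
   sinusoids.
3. **Correlation.** Pearson r between all ROI pairs; a zero-variance
   residual column aborts the run with the ROI named.

Cross-run averaging happens on the Fisher-z scale
(`tanh(mean(atanh r))`), the variance-stabilizing scale on which
correlation averages behave additively; raw-r averaging is available
behind a flag for sensitivity checks. Per-edge values are sorted before
the reduction so the mean is exactly invariant to run order despite
floating-point non-associativity.

**QC.** A run is bad when its mean FD exceeds 0.3 mm (strict). A subject
is excluded with ≥ 2 bad runs, age outside 18–50 (boundaries pass), or
missing age (listwise deletion). A retained subject's single bad run is
dropped from the generalized average by default (`drop_bad_runs`); whether
such runs should instead be kept is genuinely ambiguous, so both behaviors
are implemented.

## Network summaries

Edges are enumerated in lower-triangle row-major order (the order of
`numpy.tril_indices(R, -1)`); `vectorize`/`devectorize` round-trip
exactly. Edge classes by endpoint roles, with precedence
within > between > hipp_any > extra: *within* = both DMN-C, *between* =
DMN-C with DMN-A, *hipp_any* = at least one hippocampal ROI, *extra* =
DMN-C with a plain cortical ROI. Hippocampal edges are excluded from
*extra* by default because the extra-network summary is defined over the
cortical atlas and the hippocampi are a supplement (a flag includes them).
The hippocampal summary averages all edges incident to hippocampal ROIs;
hippocampus-internal edges are excluded by default — their membership in
"all hippocampal connections" is underdetermined — and a flag includes
them. Summaries are plain means of Pearson r over the generalized
connectome.

## Brain–behavior models

Narrative recall is the mean of immediate and delayed story-detail counts;
the composite score is the mean of z-scored narrative and emotional-memory
scores over subjects holding both. OLS relates each summary to behavior
under covariate sets: none; {age, sex, FD}; plus {fluid intelligence,
cognitive screen}. All variables are z-scored with the sample SD (n−1)
before fitting, so the one-covariate-free beta equals Pearson r. Binary
sex is z-scored along with everything else by default (the convention most
software uses when asked for standardized betas); `zscore_sex=False` keeps
the 0/1 coding, and the raw-scale coefficient is always reported
alongside. p-values are two-sided t tests; models use listwise-complete
rows only, and no multiple-comparison correction is applied across the
four summaries.

## CBPM

For each left-out subject: partial correlation (edge, behavior |
covariates) on the n−1 training subjects, two-sided p from the exact t
transform with df = n − 2 − c; selection at p < α (default 0.01) split by
sign; per-subject positive/negative summed strengths; OLS
`y ~ 1 + pos + neg` on the training set; held-out prediction. Performance
is r(observed, predicted) over all folds. Folds with no selected edges
predict the training mean (logged), which keeps LOOCV total without
discarding subjects; a constant prediction vector yields r = NaN with
status `degenerate` rather than an exception.

The permutation null re-pairs behavior with connectomes and reruns the
entire procedure, per-fold reselection included — reusing the observed
selection would understate the null. Covariates stay attached to the
connectome side under permutation (a flag permutes them jointly with
behavior instead). `p_perm` is the plain proportion of null runs with
r ≥ observed, so 0.000 is attainable; the conservative (b+1)/(m+1)
estimator is reported alongside. Strength sums are used raw by default; a
flag normalizes them by selected-edge count.

Selection inside LOOCV is algebraically identical to calling
`select_edges` on each training set but is vectorized: per-fold QR factors
of the covariate design and per-fold residual edge norms are precomputed
from training rows only (so a fold's selection is bitwise independent of
its held-out subject — the no-leakage tests assert this exactly), and the
per-fold correlation numerators for any behavior vector collapse to a
single matrix product. This makes the 100-fold × 100-permutation runs in
the test suite take seconds rather than hours. The threshold sweep
(defaults 0.001/0.005/0.01/0.05/0.1) and the lesion analysis — removing
every edge incident to one network at a time, then rerunning LOOCV +
permutation on the reduced edge matrix — reuse the same machinery.

## Synthetic cohorts

Subject *s*'s connectome is built on the Fisher-z scale:
`Z_s = M + Σ_e β_e·b_s·1_e + (Σ_j λ_j·c_js)·1 + ε_s`, where `M` is a
block matrix (within-network z = 0.35, between = 0.05 — plausible resting
magnitudes, configurable, not claims), `b_s` ~ N(0,1) is the latent
behavior, `β_e` the planted effect per SD of behavior on edge set `1_e`,
`c_js` standardized covariates with edge loadings `λ_j`, and `ε_s`
i.i.d. N(0, 0.2) edge noise (0.2 ≈ the between-subject SD of resting FC
on the z scale). Entries are back-transformed with `tanh`, which keeps
correlations in (−1, 1) and puts the planted effect on the same scale the
averaging uses. The stored behavior score is `b_s` plus optional
measurement noise (default 0). Covariates are drawn from Gaussians with
the requested behavior correlation pushed through their marginals — age
uniform on 18–50 via a Gaussian copula, sex Bernoulli(0.5) via median
split, FD/fluid-intelligence/cognitive-screen normal with means, SDs, and
behavior correlations echoing a young-adult cohort's descriptive
statistics (mean FD 0.14 ± 0.04 mm, etc.).

Time-series synthesis draws multivariate normals whose population
correlation is the target connectome after nearest-PSD repair (eigenvalue
clipping at 1e−8, adjustment Frobenius norm logged), plus additive
motion-like random-walk traces, slow component noise, and a global
signal, each with configurable loadings; FD and DVARS are derived from
the synthetic motion so spike flagging and QC operate on coherent inputs.

What this emulates — and what it does not: the generator reproduces the
*statistical couplings* the analysis assumes (edge–behavior effects,
nuisance correlations with both sides, block network structure, known
ground truth), but not hemodynamics, spatial autocorrelation, scanner
drift, or realistic artifact structure. Passing tests therefore establish
correctness and calibration of the *procedures*, not effect sizes or
significance in any real dataset.

## Problem sizes and numerical choices

The test and acceptance workloads use reduced but non-trivial scales
chosen to keep the full suite in the minutes range on one CPU: 200 null
cohorts of n = 60 subjects × 500 edges with 100 permutations each for
calibration; a planted cohort of n = 243 subjects × 2016 edges (64 ROIs,
50 signal edges at β = 0.3) for power, consensus recovery, and lesion
specificity; T = 2000 timepoints for connectome recovery, where the
documented tolerance doubles the 2/√(T−3) sampling bound to cover the
autocorrelation the band-pass filter introduces. Determinism is enforced
end to end: every stochastic step takes a seed, stage seeds derive from
one master seed, and pipeline outputs are asserted byte-identical across
reruns at the stored 10-significant-digit text precision.

## Known limitations

- Covariate edge loadings in the generator shift all edges uniformly; no
  spatially structured nuisance topography is simulated.
- The HRF is the canonical double gamma only; no dispersion/temporal
  derivatives.
- The lesion table's permutation p-values at small `n_permutations` are
  coarse; the lesion *r* values are the stable quantity.
- No k-fold alternatives to LOOCV, and no penalized predictive models —
  the two-term summed-strength OLS is the implemented protocol.
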