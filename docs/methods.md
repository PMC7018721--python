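# Methods

This note documents the models, numerical choices and validation logic of
the package, in the spirit of a methods supplement. Everything quantitative
stated here is computed by the test suite or the example scripts; nothing
is asserted from memory.

## Gabor codec

The analysis raster is 32 x 32 pixels over 43 degrees (1.34 deg/px).
Filters are Gabor wavelets `exp(-(x'^2+y'^2)/(2 sigma^2)) cos(2 pi x'/lambda + phase)`
at 4 orientations (0/45/90/135 deg) and 2 phases (0 and 90 deg, a
quadrature pair). Four scales carry spatial frequencies 0.02, 0.04, 0.09
and 0.18 cycles/deg, realized by setting the carrier wavelength on the
analysis raster; grids of 1x1, 3x3, 5x5 and 11x11 centers are evenly
spaced with half-spacing margins, giving 8 + 72 + 200 + 968 = 1248 filters.
Filters larger than the raster are evaluated on it and truncated at the
borders, then DC-removed.

Two choices were genuinely open:

- **Envelope width.** With sigma = lambda/2 the bank's round-trip fidelity
  on 1/f images is mediocre (mean pixel r ~ 0.86). We use
  sigma = 0.4 lambda, which maximizes self-inversion in a scan over the
  envelope factor.
- **Row normalization.** After unit-L2 normalization we apply one gain per
  scale, obtained in closed form by least-squares fitting
  `sum_c w_c G_c^T G_c` to the identity (4 unknowns). This "tight-frame
  calibration" raises the mean round-trip correlation to 0.90 +/- 0.01 on
  1/f ensembles. Both steps run at bank-construction time and are
  deterministic.

`alpha` has the closed form `<M I, I> / ||M I||^2` with `M = G^T G`,
accumulated over an image stack; a test checks it against a bounded 1-D
numerical minimizer to 1e-8. Decoded images are not clipped; a clipped
view exists for rendering only. Because the bank is only approximately
self-inverting, every reconstruction is evaluated against the
round-tripped stimulus `I'`, never the raw `I`.

## Trace processing and evoked extraction

Traces are 30 Hz. The pipeline is: optional neuropil subtraction
(`signal - ratio * ring`, ratio 0.7 in the awake preset), removal of
components slower than 60 s/cycle (Gaussian low-cut for the anesthetized
preset, running-median for awake; the trace mean is retained so dF/F stays
well-defined), Savitzky-Golay smoothing (order 4, 15 frames), and
`dF/F = (F - F20)/F20` in percent with F20 the per-cell 20th percentile.
Cells with F20 <= 0 are flagged invalid, never silently dropped.

The stimulus is a train of three 200 ms flashes with 200 ms gaps. The
baseline window is the 6 frames before onset; the stimulus value is the
mean over each flash's 6 frames, averaged over the three flashes
(per-flash values are averaged, not pooled — the protocol reports one
response per train and the alternative is not distinguishable from the
text of the protocol). Evoked = stimulus - baseline, stored per
(cell, stimulus, trial) with missing trials as NaN (available-case
statistics downstream, no imputation).

## Responsiveness criteria

A cell is responsive if a one-way ANOVA over N stimulus activities plus
one baseline group (the per-trial mean of baseline windows across stimuli)
rejects at alpha = 0.01. A responsive cell responds to a given image if a
paired t-test (stimulus vs baseline across trials) rejects at 0.01 AND the
trial-averaged evoked response exceeds 10 %dF/F. The t-test is paired
because both quantities are measured within the same trial; the protocol
text does not resolve paired vs unpaired, and the choice is recorded here.
The label-shuffle control permutes the N+1 group labels within every
(cell, trial) and re-applies the criteria; on i.i.d. Gaussian nulls the
ANOVA criterion flags ~1% of cells at alpha 0.01 (binomial-interval test).
ANOVA is computed vectorized across cells with available-case counts.

Population sparseness uses the Treves-Rolls form
`s = [1 - (sum R_i)^2/(N sum R_i^2)]/(1 - 1/N)` on raw (not z-scored)
evoked responses.

## Ridge regression by evidence maximization

Both the encoding and the reconstruction regressions minimize
`||y - (Wx + b)||^2 + lambda ||W||^2` with lambda = (prior precision)/(noise
precision) set by the standard fixed-point updates of the Bayesian linear
model (bias unpenalized, handled by centering). Convergence: relative
evidence change < 1e-6 or 200 iterations; non-convergence returns the last
iterate flagged. The implementation works in the SVD eigenbasis of the
centered design, so the per-iteration cost is O(rank) and many targets
sharing one design (the 1248 feature regressions of the all-cell decoder)
run vectorized on one SVD. With lambda forced to 0 the fit equals OLS to
1e-8 (tested); the evidence-maximized fit is cross-checked against
scikit-learn's BayesianRidge.

## Encoding models

Inputs are z-scored evoked responses (per cell, across stimuli and
trials). Feature selection takes |Pearson r| between single-trial
responses and each feature over the training folds, with a threshold from
the 13-point grid 0.05-0.35; absolute value is used because negative
weights are legitimate. For each threshold and each of 10 image-level CV
folds: selection, ridge-EM, then a four-parameter sigmoid
`NL(x) = A/(1+exp(Bx+C)) + D` fitted to rescale the linear prediction
(analytic-Jacobian Levenberg-Marquardt, three slope starts; on failure an
identity scaling over the data range is used and flagged). Performance is
the Pearson correlation between trial-averaged observed and predicted
responses over held-out images; the best threshold wins, ties going to the
higher (sparser) threshold; the returned model is refit on all data at
that threshold. Fold assignments are seeded and shared with the
reconstruction stage.

Receptive fields use the regularized pseudoinverse of the pixel design
with 13 log-spaced regularizers (1e-3..1e3), the winner chosen by CV
response prediction. Only smooth RFs are identifiable from 1/f stimuli —
the ensemble carries almost no energy at sharp edges — which the tests
respect by planting Gaussian-blob templates.

## Reconstruction

Per feature j, `F_j = H_j R + c_j` is fitted on single-trial samples of
the training folds (ridge-EM, per-feature lambda). Modes: `all_cell`
(every cell in every regression), `cell_selection` (a cell participates in
the features it encodes; features with no cells are fixed at zero), and
`nested_cv` (the selection itself is redone inside each fold on a
10% test / 9% validation / 81% training split so the test fold never
touches model selection). Subset reconstruction rescales the frozen
decoder by one factor `a'` (closed-form ratio of inner products on the
training folds) after zeroing excluded cells' z-scores. Scores are R and
CD per single trial and for the trial-averaged image.

## Synthetic data generator

The generator defines the study conditions explicitly, since the analyses
were designed for recordings that are not redistributable:

- **Stimuli**: 32x32 random-phase images with 1/f^beta power spectra
  (beta = 2, natural-image-like), rescaled to [-1, 1]; pairwise pixel
  correlations are near zero.
- **Populations**: per cell, a random visual-field center and preferred
  orientation define candidate features (within 8 px, orientation within
  +/-45 deg); a lognormal count with median 21 (clipped to 8-51) is drawn
  from them, weighted by each feature's ensemble SD (so low-SF features
  are used by more cells, matching the usage gradient across spatial
  frequency that this kind of recording shows); weights are signed
  Gaussian, normalized so the linear drive is standard over the image
  ensemble.
- **Responses**: `R = NL(WF + b) + noise` with per-cell sigmoid amplitude
  ~ lognormal(60 %dF/F, 0.3), slope 3, and the threshold placed so the
  response crosses the 10 %dF/F criterion at drive z = 1.96 — i.e. ~2.5%
  of (cell, image) pairs pass the responsiveness criteria, the sparse
  regime the analyses assume. Trial noise (SD 8 %dF/F) is split between
  stimulus and baseline windows; options add additive shared noise (to
  plant a target pairwise noise correlation), a multiplicative shared gain
  per stimulus x trial (the classic source of correlated variability), and
  a locomotion gain on labeled running trials.
- **Traces**: presentations laid out in shuffled trial blocks at 30 Hz
  with 3 s inter-trial gaps; each evoked response launches a sum of
  exponential decays (tau = 0.5 s, GCaMP6s-like) at the three flash
  onsets, scaled so the extraction windows read back the planted amplitude
  after Savitzky-Golay smoothing (the smoothing is linear, so this gain is
  exact up to boundary effects); slow sinusoidal drift and per-frame shot
  noise are added. The end-to-end round trip recovers planted amplitudes
  with < 10% bias.

What the generator does **not** emulate: eye movements, imaging artifacts
and frame registration errors, non-Poisson bursting, calcium indicator
saturation, and any structured higher-order correlations beyond one shared
gain. Passing tests therefore validate the analysis chain, not the
biology.

### The recovery benchmark

`SimulationConfig.recovery_benchmark` defines the conditions under which
parameter recovery is assessed: 200 images x 12 trials, noise SD
0.5 %dF/F, sigmoid slope 0.5 with criterion crossing at z = 0.5, 8-16
features per cell, uniform (unbiased) feature sampling. Two facts force
these choices, both verified empirically in the development scans:

- Under the sparse default regime a cell's response carries graded signal
  for only ~5 of 200 images; no estimator can identify ~20 weights from
  that, at any noise level. Recovery must be tested where the response
  carries information.
- The bank is overcomplete with strongly correlated neighbors, and low-SF
  features are nearly collinear over 1/f ensembles; energy-biased feature
  sets are unidentifiable in the weight metric even when the fitted
  *function* is essentially exact (restricting the regression to the true
  features recovers weights with r > 0.98).

Under the benchmark conditions the encoding chain reaches median CV
performance ~0.93 and pooled true-weight correlation ~0.87.

## Population analyses: formulations and scales

- **Representation areas**: reverse filters (reverse transform of each
  cell's fold-averaged decoder weights) are z-scored over pixels,
  thresholded at |z| > 1.5, the largest 8-connected component kept, and
  the contour smoothed by morphological closing with a 3-px disc (the
  smoothing operator and connectivity are not dictated by the protocol;
  these are the recorded choices). Overlap is the Jaccard index; overlap
  sets collect responsive cells with index > 0.2 around a reference cell.
- **Addition/drop curves** order cells by trial-averaged evoked amplitude,
  responsive cells first (filters: >= 10 responsive cells for addition,
  >= 5 for drop), and reuse per-cell contributions so each subset is an
  O(f) update. Under an evidence-regularized decoder the performance curve
  is *flat* beyond the informative cells (uninformative cells get near-zero
  weights), so the "peak location" is degenerate; the acceptance test
  asserts the substantive claim instead — the responsive prefix reaches
  the curve's peak within 0.05 in R on a planted 20-cell sparse code.
- **Sequential drops** remove the reference cell first, then random orders
  (120 by default, seeded) of the remaining overlap-set members, scoring
  the pixel correlation on the local overlap area.
- **Reliability**: across-trial similarity is the mean correlation of
  single trials with the trial average; across-trial variability is the
  DoF-corrected error ratio, equal to 1/F of a one-way ANOVA with units as
  groups — an identity the tests verify to 1e-10 on random instances.
  The variability-vs-overlapping-cells effect requires per-trial-unreliable
  cells with well-estimated, aligned decoder patterns; the test plants an
  8-cell redundant clique at half amplitude over 150 images x 12 trials.
- **Noise correlations**: responses z-scored within (cell, stimulus)
  across trials, collected across stimuli, correlated per pair; removal by
  permuting trials within stimulus independently per cell. Removing a
  planted multiplicative shared gain raises (never lowers) the median
  single-trial reconstruction CD; note the trial-averaged CD is almost
  invariant under shuffling by construction, so the single-trial score is
  the meaningful comparison.
- **Capacity**: with the offset d shared across images the least-squares
  optimum is d = the column mean of F and per-image coefficients from the
  pseudoinverse of H; the error is evaluated in image space (percent of
  target variance unexplained).
- **RMI** = (R_run - R_rest)/(R_run + R_rest) per responded image, averaged
  per cell; images require >= 5 responsive cells and >= 4 trials in each
  locomotion state.

Test and acceptance problem sizes (hundreds of cells, 40-200 images, 4-12
trials) are reduced relative to a full imaging experiment (which would be
~700 cells and thousands of presentations); they are chosen as the
smallest sizes at which each effect is stable across seeds, and the
directional claims are evaluated as medians over images, never as single
draws.

## Known limitations

- The codec is calibrated for the 32x32/43-deg raster; other rasters work
  but the per-scale gains are refit at build time, and no steerable or
  color variants exist.
- The encoding model over-selects features relative to the planted count
  when features are mutually correlated (CV prediction is insensitive to
  redundant inclusions); weight *patterns* are recovered, set sizes are
  upper bounds.
- The awake median low-cut is O(window) per frame and slow on very long
  traces.
- `nested_cv` redoes per-cell selection in every fold and is the most
  expensive mode; use it for final performance numbers, not exploration.
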