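# Methods

## Model and estimation

Calibration data are spectra `X (N×K)` and reference values `y (N×1)` under
the linear model `y = 1 g0 + X b + e`, `Var(e) = σ²`.  Spectral collinearity
makes the ordinary least-squares solution ill-posed, so the package uses PCR:
column mean-centering of `X` and `y`, SVD `X_c = U S Pᵀ`, retention of the
`M` components whose singular values exceed `1e-10` times the largest (never
more than `N − 1` because of centering), and regression of the centered
response on the first `A` orthonormal score columns.  Orthonormality makes the
coefficients `g_m = u_mᵀ y_c`; they are computed for **all** `M` retained
components at fit time because the omitted-component bias needs coefficients
beyond `A`.  Predictions add the calibration mean of `y` back.

Sign convention: each loading column's largest-magnitude element is made
positive, ties broken at the lowest channel index; scores and coefficients
flip accordingly.  This gives bitwise-reproducible fits and pins down the
basis in which the simulator states its ground truth.

## Error decomposition

For a sample with scores `u`:

- random error `σ²`;
- variance (estimation) contribution `σ²/N + σ² Σ_{a≤A} u_a²` — exact for
  fixed scores, because the `ĝ_a` are independent with variance `σ²` and the
  fitted mean contributes `σ²/N`;
- signed omitted-component bias `−Σ_{m>A} u_m g_m`, entering the total as its
  square.  The identity `total = σ² + variance + bias²` is exact by
  construction and tested to 1e-10.

Plug-in choices (all configurable):

| parameter | default | meaning |
|---|---|---|
| `a_noise` | 50 | components of the large model whose MSEC estimates σ²; capped at retained rank − 1 with a warning |
| `alpha`   | 0.01 | two-sided significance level of the per-component univariate t-test (d.o.f. `N − 2`; the intercept is absorbed by centering) |
| `m_max_bias` | 15 | last component eligible for the bias sum; farther components are dominated by estimation noise |

The significance mask gates only the bias sum, never the prediction.  The
mask is computed once per calibration, not re-tested per choice of `A`.  No
multiple-testing correction is applied across the 15 tests; with α = 0.01 the
expected number of false flags is 0.15 and a null simulation keeps the
average well below one.

MSEC uses denominator `N − A − 1` by default: with `K ≥ N` the channel-based
`N − K − 1` is infeasible, and only the component-based version makes the
large-`A` MSEC a coherent χ²-type estimator of σ² (unbiased when components
beyond `A` carry no signal).  `N − K − 1` remains selectable for `K < N`.
MSECV divides by `N` with no further correction, and every leave-one-out fold
refits centering, SVD and coefficients from scratch — no shortcut formulae —
trading speed for unambiguous correctness.

The OLS reference `σ²(1 + 1/N + xᵀ(XᵀX)⁻¹x)` is provided for full-rank data;
the PCR formula with `A = M` and an empty bias range reduces to it exactly
via `Σ_m u_m² = xᵀ(XᵀX)⁻¹x`.

## Preprocessing

Savitzky–Golay second-derivative filtering (window 21, polynomial order 2) is
the default spectral pretreatment.  Only the valid interior region is
returned (`K − window + 1` channels): no edge values are fabricated, every
retained channel comes from the same full-window filter, and the trimmed
wavelength axis is carried so calibration and prediction stay aligned.  The
derivative is per channel-index step; a uniform nm spacing only rescales
columns, which the regression absorbs.

## Synthetic data generator

The generator emulates single-kernel NIR protein calibration: 85 channels
(860–1028 nm at 2 nm), 15 latent components with smooth orthonormal loadings
(Gaussian-smoothed noise, kernel width 4 channels, QR-orthonormalized),
geometrically decaying score scales `2.0 · 0.78^m`, response offset 12
(protein-% level) and response noise `σ² = 0.25`, giving a response variance
near 1.2 — the scale of protein content in wheat.  Default sizes are 100
calibration and 423 prediction samples.

Calibration scores are drawn, centered, exactly orthogonalized and scaled to
column norms `score_sd·√(N−1)`, so at zero spectral noise the calibration SVD
recovers the generative basis up to the shared sign convention, `g_true` is
the exact score-space coefficient vector, and the stored noise-free test
scores are exactly the `u` of the error formula.  Test samples are fresh
independent draws.  Spectral noise defaults to zero because the error
formulae assume errorless spectra; a nonzero option exists for realism
experiments.  One root seed is split into fixed per-draw-site child streams
(`SeedSequence.spawn`), so new features can never silently shift existing
streams.

Two scenarios:

- **standard** — informative coefficients `(4.5, 4.0, 3.5, 3.0, 2.6)` on the
  five dominant components and `(3.6, −3.3, 3.0)` on components 6–8.  The
  minor coefficients are sized from a power analysis: a component is flagged
  by the univariate t-test only if its coefficient exceeds ≈ 2.63× the total
  response SD in coefficient-norm units (≈ 2.7 here), so minor-but-detectable
  components must sit just above that floor — which also matches the
  qualitative pattern of real NIR calibrations (a few significant
  coefficients beyond the chosen rank).
- **strong_signal** — the five dominant components only, `σ² = 0.05`; used
  where an unambiguous informative rank is needed (component-selection and
  complexity-tradeoff tests).

The Monte-Carlo oracle holds the calibration spectra (hence `U, S, P`) fixed,
redraws calibration responses, refits the `A`-component regression, predicts
a sample conditioned on its score vector, redraws that sample's own response,
and averages `(ŷ − y)²`, returning the estimate with its standard error.  The
closed-form expectation is exact for this design, so agreement within
Monte-Carlo noise (3 SE at R = 5000) is the package's headline correctness
test.

What the generator does *not* emulate: scatter/baseline instrument artifacts,
wavelength shift, non-representative prediction populations (type-1 bias),
non-Gaussian reference errors.  Passing tests therefore certify the formulas
and their implementation under the stated model, not robustness to those
real-data effects; leverage and spectral residuals are reported as
*diagnostics* for representativeness, nothing is corrected.

## Bias diagnostics

The least-squares effect — shrinkage of `E(ŷ | y)` toward the mean with slope
`bᵀ Σxy / Σy` — is computed from plug-in calibration moments; in score space
the slope reduces to the R² of the fit.

Loess: tricube weights on distance scaled by the neighbourhood radius,
neighbourhood = `⌈span · n_included⌉` nearest included points (span 0.5,
degree 2 by default), no robustness iterations, evaluated at the observed
abscissae.  Points can be excluded from fitting yet still evaluated; an
optional trimming rule (drop the top 1% of the abscissa) is exposed in the
CLI, off by default since no principled exclusion criterion is built in.
The scalar "tendency slope" is a straight-line fit to the Loess curve over
the central 90% of the abscissa — a repository convention that avoids
boundary-leverage artifacts.  A constant abscissa yields a flagged
not-available slope, not an exception.

## Simulation-study result

On the standard scenario at `A = 5`, the Loess slope of true conditional bias
on significance-gated estimated bias is ≈ 0.9 (median over ten seeds;
individual seeds 0.79–1.20): the bias formula recovers the true systematic
error with tendency slope near unity.  The mild shortfall from 1 is the
expected attenuation from plug-in coefficient noise — regressing on `ĝ = g +
ε` attenuates the slope by ≈ `Σg²/(Σg² + Σε²)` ≈ 0.97, and conditioning on
t-test selection inflates the selected `|ĝ|` slightly, adding a few more
percent.  Binning prediction samples by their expected squared error and
averaging observed squared errors per bin reproduces the formula within
sampling noise.

## Known limitations

- LOOCV model selection is honest and therefore mildly overfit-prone: beyond
  the informative rank the MSECV curve is flat with noise dips of order
  `σ²/N`, so the *global* argmin can exceed the informative rank even though
  MSECV at that rank is within a few percent of the minimum.  The package
  reports the curve and its argmin; it deliberately implements no further
  selection rule.
- `σ̂²` from MSEC at large `A` has χ² noise with roughly `N − A − 1` degrees
  of freedom; on small calibrations the estimate is correspondingly wide.
- The error formula conditions on the calibration score basis; it does not
  propagate uncertainty in the loadings themselves, nor errors in the
  spectra of the sample being predicted.
- LOOCV refits `N` SVDs per curve; at the default study size this costs well
  under a second, but for very large `N` a user may prefer a coarser grid of
  `A` values.
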