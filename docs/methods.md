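# Methods

## Stimulus model

A stimulus is the Heaviside thresholding of a scaled triangular carrier
against a source map S ∈ [0, 1] (1 = figure).  The triangular wave
`triangle(x, y)` is periodic in x with period 1/f and carries a
y-dependent phase shift built from an arcsin-of-cosine triangular term, so
rows tile into zigzag elements of height `r_h/w / f` pixels; within one
half tile the x-offset grows linearly with y at slope cot(α).  Because the
triangle's value is uniformly distributed over [0, 1] along a period, the
ink (I = 0) fraction of a region with constant source level s converges to
`d_off + s·(d_on − d_off)` as resolution grows — the duty-cycle law that
all rendering tests rest on.

Conventions chosen here (each configurable):

* **Polarity.** S = 1 means "signal present" (the dark part of a
  silhouette); output 0 is ink.  Only this reading makes figure regions
  come out with thickened lines when d_on > d_off.  Luminance-coded files
  are inverted on load (`read_source_image(invert=True)`, the default).
* **Sampling.** The carrier is evaluated at pixel centers (col + 0.5,
  row + 0.5), top-left origin.  Published figures of this stimulus family
  do not state their sampling; centers are the symmetric choice.
* **Angle.** α is accepted in radians in (0, π), with tan(α) = 0 rejected
  as singular (tolerance 1e−12) and a degree convenience
  (`HalftoneParams.with_degrees`, `--alpha-deg`) because the angle
  conventions in circulation are inconsistent.  The package's reference
  parameter set (`FIG_PARAMS`) uses α = π/4, a 45° zigzag: every quantity
  asserted anywhere (duty fractions, spectral peak) is independent of α,
  and π/4 gives clearly visible zigzag segments.
* **Heaviside at 0 is 1**, per the customary right-continuous convention.
* **Low-pass demodulation** defaults to a Gaussian with σ = 1/(2π·cutoff)
  (the σ that puts the half-amplitude point near the cutoff); an ideal
  radial cutoff is selectable.  Both have DC gain exactly 1.

## Optical observer

Pixels convert to visual angle through
`px/deg = 2·distance·tan(0.5°)/pitch`.  Defocus of D diopters over a
circular pupil of radius r adds the wavefront error W(ρ) = D·ρ²/2; the
incoherent PSF is |FFT(pupil·exp(i2πW/λ))|².  The pupil plane is sampled
so FFT output lands on the screen's angular pixel grid; when screen pixels
are too coarse to Nyquist-sample the diffraction pattern, the PSF is
computed on an odd-factor oversampled grid and integrated (binned) into
screen pixels, keeping the peak centered.  The kernel is trimmed to the
support holding 99% of its mass (Airy tails decay too slowly to keep more)
and renormalized to unit sum, so convolution preserves mean luminance;
boundaries are handled by reflection.  Defaults nothing upstream
prescribes: pupil 4 mm, wavelength 555 nm, monochromatic and
aberration-free apart from defocus, no Stiles–Crawford apodization.
Bangerter occlusion foils have no published optical model and are stood in
for by an equivalent Gaussian blur of configurable angular σ
(`foil_psf`) — an acknowledged approximation, not a scatter model.

A useful check: for large defocus the PSF tends to the geometric blur disc
of angular diameter pupil_diameter·D (radians).  The test suite measures
width as the side of the centered square holding half the kernel mass
(robust to defocus ringing); for a uniform disc that side is 0.627× the
disc diameter.

## Neural mechanisms

* **Ricco summation** — convolution with a uniform disc of given angular
  diameter (default 10 arcmin, the photopic foveal summation area),
  DC gain 1.  Discs smaller than one pixel return the input with a
  warning.
* **Frequency channels** — radial log-Gaussian filters with
  half-amplitude points at the band edges, renormalized to a partition of
  unity inside the covered passband, so band images plus the DC term
  reconstruct the original exactly there; outside the passband the
  outermost bands roll off with quarter-width Gaussian tails (steep enough
  that ≥70% of each band's output energy stays inside its own edges on
  broadband input).  The default six bands use the printed edge values
  0.03–0.08–0.22–0.61–1.72–4.82–13.49 cpd.  Their edge ratio (~2.77×,
  ≈1.47 octaves) is narrower than the ~2.8-octave average bandwidth
  reported for cortical frequency channels; the edge values are kept
  verbatim as the default, and a geometric-spacing constructor covers any
  other choice.
* **ODOG** — oriented difference-of-Gaussians: 6 orientations ×
  7 octave-spaced center frequencies (0.10–6.5 cpd), surround/center width
  ratio 2, surround elongated 2:1 along the orientation, scale weights
  ∝ f^0.1, per-orientation RMS normalization before summing across
  orientations.  Both DoG lobes have unit volume, so the response to a
  constant image is exactly zero and the output is zero-mean.  These
  constants follow the published ODOG model family; none of them is fixed
  by the stimulus itself, so all sit in `OdogParams`.

## Simulated psychophysics

The observer demodulates the stimulus with any composition of the stages
above, Pearson-correlates the result against each lightly smoothed
(σ = 3 px), polarity-matched template, and answers with the best match if
its correlation clears a criterion (default 0.4), else "not recognized".
The staircase is a transformed 1-up/2-down on log₂ SF (converging to the
70.7% point of the 2AFC psychometric function): initial step 0.5 log₂
units, halved after each of the first 4 reversals, stopping after 8
reversals, estimate = geometric mean of the last 6 reversal frequencies,
bounds 0.5–16 cpd.  These details are standard practice rather than a
published protocol, and every one is in `StaircaseConfig`.  A descending
method-of-limits mode (`method_of_limits_run`) is provided because the
verbal description of the live procedure mixes the two; trial timeout
(10 s) and inter-stimulus interval (1.5 s) are retained as schedule
metadata only — a simulated observer never times out, so the
missed-and-repeat rule never fires.

Simulations run at 40 px/deg (256-px stimuli spanning 6.4°) so carriers of
1–12 cpd are renderable; the live experiment's 300 cm / 0.025 cm geometry
(209 px/deg) is kept for single-image demodulation demonstrations.  At
0 D the Ricco disc's MTF changes sign near 8 cpd, producing a narrow
carrier-contrast inversion notch; staircases therefore start at 12 cpd,
above the notch.

Acuity prediction is the affine map VA = intercept + slope·SF with the
published per-type coefficients bundled as constants;
`min_sf_for_va` is its algebraic inversion.  Published minimum-frequency
tables were produced by a regression in the other direction and differ
from this inversion by design; the package exposes the inversion and, when
data are supplied, an inverse regression, claiming neither as canonical.

## Statistics

* **Outlier screen**: squared Mahalanobis distance of (SF, VA) pairs
  against the χ²(2) 97.5th percentile, within each degradation level by
  default (global screening selectable).  Cutoff and grouping are conventions that
  differ between analyses, so exclusion counts obtained elsewhere with
  unstated settings are not promised to match.
* **Mixed model**: VA ~ SF + type + level(type) + SF:type + SF:level(type)
  with a per-subject random intercept, REML.  Best-corrected rows are
  replicated into both degradation types and serve as the shared nested
  baseline — which is also why the type main effect is structurally near
  zero.  The SF covariate is centered (the interaction columns are
  otherwise ill-conditioned; the slope estimate is unchanged).  Marginal
  tests are Wald F statistics with a residual (n − rank X) denominator df,
  named as such in the output: Satterthwaite/Kenward–Roger approximations
  are not available in the underlying fitter, so F and df values are
  comparable with other software's only approximately.  Shapiro–Wilk
  normality, Brown–Forsythe (median-centered Levene) homoscedasticity and
  variance inflation factors accompany every fit.  Optimization tries
  Powell, then Nelder–Mead, then BFGS; the gradient path of L-BFGS is
  numerically fragile for this design.
* **OLS / Bland–Altman**: per-type least squares of VA on SF; agreement of
  predictions with their own training observations has mean difference
  exactly 0 and paired t = 0 because OLS residuals sum to zero.  Limits of
  agreement are mean ± 1.96 SD with exact t-based CIs using
  Var(LoA) ≈ SD²(1/n + z²/(2(n−1))).
* **Quartiles** use linear interpolation between order statistics.
  Adjusted-R² and variance-decomposition figures reported by proprietary
  software depend on its definitions and are computed here as analogues
  only, never asserted equal.

## Synthetic data

`make_silhouette` provides five deterministic binary shapes (disc, ring,
cross, heart, smiley) with figure fractions between 10% and 60%; the
hand-drawn animal outlines used in live experiments are not
redistributable, and these stand-ins exercise every pipeline stage the
same way.  `simulate_subjects`
draws, per subject and condition, a limiting SF from a normal
(condition-mean, SD 0.45 cpd, truncated at 0.5 cpd) and computes
VA = intercept(type) + slope(type)·SF + subject offset + noise.  Defaults
emulate a typical acuity-degradation experiment: 21 subjects; condition
means 5.1, 3.7, 2.9, 3.8, 3.3 cpd (published per-condition medians); generating lines = the published
regression coefficients, best-corrected rows on their average; subject SD
0.12 and residual SD 0.15 logMAR, chosen once so the pooled per-type R²
lands near the published ≈0.51/0.72.  What the generator does **not**
emulate: heteroscedasticity across levels, response biases, learning
effects, or any optics — so passing statistical tests demonstrates the
pipeline's correctness on its assumed generative structure, not properties
of real observers.  Real measurement tables in the same schema (or any
foreign CSV layout via a column map) load with `load_measurements`, and
the full pipeline runs on them unchanged.

## Problem sizes and numerical notes

Rendering checks use 400×400 px (20 carrier periods per row; the spectral
peak bin is exact at that width).  Oracle equivalence is checked on a full
64×64 grid at 1e−12.  Staircase recovery uses 100 seeded runs against
hard-threshold observers spanning 1–6 cpd; mixed-model recovery uses 100
seeded 21-subject tables.  Degenerate inputs fail loudly: d_on = d_off,
tan α = 0, empty images, singular covariances, constant predictors, and
images too narrow for two carrier periods all raise with messages naming
the offending quantity.
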