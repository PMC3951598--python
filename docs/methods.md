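# Methods

`bakevision` implements a multispectral quality-assessment workflow for baked
goods: a sensory-anchored **browning score** built by Fisher discriminant
analysis (FDA) over cookie-surface pixel spectra, a **quadratic response
surface** of that score over baking time and oven temperature, and a **PLSR
water-content model** mapping mean surface spectra to gravimetric water
percent.  Because no image data for this kind of study is publicly deposited,
the package ships a synthetic multispectral image generator that reproduces
the statistical structure the analysis assumes; every model component is
validated end to end against it.

## The synthetic generator

### Exposure

All kinetics are driven by a scalar *thermal exposure* in minute-equivalents,

    E = t + (T − T_ref) / k,      T_ref = 180 °C,  k = 10 °C/min.

The linear-additive form (rather than an Arrhenius law) makes the
"1 min ≈ 10 °C" time–temperature equivalence exact by construction, which
turns the response-surface sensitivity analysis into a genuine parameter
recovery problem with a known answer.  Negative exposures (short bakes in a
cool oven) clamp to zero effect.

### Water and pigment kinetics

* Water mass fraction decays exponentially toward a dry floor:
  `X(E) = floor + (initial − floor)·exp(−E/τ)` with `initial = 11.5 %`,
  `floor = 1.0 %`, `τ = 4.48` min-equivalents.  τ is calibrated from the
  closed form so the full time×temperature design (exposures 1–18) spans
  ≈ 1.2–9.4 % average water, the range the gravimetric reference method
  should cover.
* Brown pigment accumulates linearly after a short lag:
  `c(E) = rate·max(0, E − lag)`, `rate = 0.04` per min-equivalent,
  `lag = 0.5`.  The moderate rate keeps the reflectance response
  quasi-exponential but not saturated over the design box, so a quadratic
  surface describes the resulting score with R² > 0.99 and stays monotone
  over the whole validity box.

### Rendering

A cookie is a centred disk (default radius 96 px in a 256×256 frame; the
native 1280×960 frame of laboratory multispectral rigs is supported) on a
flat dark background (reflectance 0.08).  Browning and drying lead at the
rim: a pixel at normalised radius ρ experiences
`E_local = E·(edge_lead + (1 − edge_lead)·ρ)` with `edge_lead = 0.88`, so
browning propagates edge → centre.  `edge_lead` is calibrated so that
pixel-level "underbaked" areas occur only in 4-min bakes, the behaviour the
classifier is expected to reproduce; at lower values the pale centre of a
6-min cookie crosses the under/adequate limit.

Per-pixel reflectance composes Beer–Lambert attenuations on a bright dough
baseline `R_base(λ)` (0.85 → 0.80 across 385–970 nm):

    R(λ) = R_base(λ) · exp(−c·A_brown(λ)) · exp(−w·A_water(λ)) + ε

* `A_brown` peaks at **395 nm** (σ 12 nm, amplitude 1.0) and **525 nm**
  (σ 40 nm, amplitude 0.75) — a melanoidin-like near-UV/green absorber.  The
  two largest template entries sit exactly at 395 and 525 nm so that
  discriminant-loading recovery is a real test, not an artefact of the grid.
* `A_water` peaks at **970 nm** (σ 25 nm, amplitude 1.2), the short-wave NIR
  water overtone.  The amplitude keeps the 970 nm response quasi-linear over
  the simulated water range, as a linear calibration model assumes.
* `w` is the **evaporated** water fraction (initial − current), not the
  current one.  This choice makes the unbaked cookie equal `R_base` exactly
  and makes reflectance monotonically non-increasing in baking time at every
  band — the covariance direction observed in real data, where visible-range
  differences dominate and NIR differences are smaller.  The current water
  content remains linearly recoverable from the 970 nm band.
* `ε` is i.i.d. Gaussian sensor noise, `noise_sd = 0.004` reflectance units.

### Heterogeneity

Real images are not noiseless functions of a single latent variable.  Three
heterogeneity terms break that degeneracy:

| term | default | emulates |
|---|---|---|
| `tau_jitter_sd` (lognormal on τ, per cookie) | 0.05 | replicate-to-replicate drying variability |
| `pigment_jitter_sd` (lognormal on rate, per cookie) | 0.03 | replicate-to-replicate browning variability |
| `pigment_texture_sd`, `water_texture_sd` (lognormal, per pixel) | 0.10 | surface mottle |

These matter: without them every band is an exact function of exposure, the
within-class scatter matrix collapses onto a one-dimensional manifold, the
FDA direction is decided by curvature accidents rather than pigment
absorbance, and the visible bands become a physically spurious but perfect
water predictor.  With them, the discriminant concentrates on the pigment
template (max |loading| at 395 nm) and the water regression on the 970 nm
channel, which is the structure reported for real instruments.

### Reference measurements

Gravimetry simulates the drying-cabinet protocol: initial and dried masses
(nominal 11 g) each carry independent balance noise (`mass_noise_sd_g =
0.005` g); water percent is `100·(initial − dried)/initial`.  A sensory
panel of 6 untrained assessors is simulated by perturbing the perceived
exposure per panelist (`vote_noise = 0.5` min-equivalents) and thresholding
at 5 and 11 min-equivalents, which reproduces the intended categorisation:
4 min underbaked, 6–10 min adequate, ≥ 12 min overbaked at 180 °C, and no
cookie ever receives both under- and overbaked votes.

### What the generator does *not* emulate

It is statistical, not mechanistic: no radiative transfer, no Maillard
chemistry, no moisture diffusion PDE, no specular artefacts, no
cookie-shape irregularity, no instrument calibration drift.  Passing tests
therefore demonstrate that the *analysis pipeline* recovers known structure
from data of the assumed form — not that the pipeline would meet the same
accuracy on any particular real instrument.

## Segmentation

Background removal thresholds the across-band mean of the visible bands
(≤ 700 nm; NIR contrast varies with water) against a local mean (window =
1/4 of the image side), keeps the largest 4-connected component and fills
holes.  Local-mean thresholding is gain-robust: scaling the image and the
offset together changes no mask pixel.  The exact thresholding variant used
with real instruments is usually unspecified; local-mean is the simplest
member of that family and is documented here as a choice.

## Browning score (FDA)

Surface pixels of the sensory-labelled training set are pooled (every pixel
inherits its cookie's consensus class; consensus = majority vote, ties →
adequately baked).  With within/between scatter matrices S_W, S_B the
loadings solve the symmetric generalized eigenproblem
`S_B v = λ (S_W + r·I) v`, keeping at most `n_groups − 1 = 2` unit-norm
eigenvectors; the default ridge `r = 1e-6·tr(S_W)/n_bands` guards against
near-singular pixel scatter.  For two classes and full-rank S_W the first
loading is collinear with the classic LDA direction `S_W⁻¹(μ₁−μ₂)`; this is
enforced as an oracle test at 1e-8.

The score is the first-loading projection, oriented and offset so that the
mean pixel of the lightest (underbaked) class scores 0 and browner pixels
score lower.  "No browning = 0" is thereby anchored to the underbaked-class
mean, the lightest reference available in-sample; the anchoring mechanism is
a design choice since field practice varies.  Class limits on the score axis
are midpoints of the 4/6-min and 10/12-min baking-time group means.  Cookies
are classified by thresholding their mean score (ties to the more-baked
class); pixels by thresholding a masked-Gaussian-smoothed score map (σ = 1 px
by default — smoothing removes isolated single-pixel class islands without
letting background values bleed under the mask).  Only the first loading is
used for scoring; the second is retained for diagnostics.

## Response surface

Whole-cookie mean scores over the time×temperature grid are fit by ordinary
least squares to the full 6-term quadratic
`S = b0 + b1·x1 + b2·x2 + b11·x1² + b22·x2² + b12·x1·x2` (x1 time in min,
x2 temperature in °C).  Extreme bakes (20 min) are excluded; the fit is valid
only inside the investigated box (4–16 min, 150–200 °C) and evaluation
outside warns.  The time/temperature sensitivity ratio
`(∂S/∂x1)/(∂S/∂x2)` is computed from the analytic gradient; at the design
centre (10 min, 175 °C) the generator's built-in equivalence implies ≈ 10
°C/min, and the pipeline recovers a median within [9, 11] over seeds.  The
quadratic order is fixed; no lack-of-fit testing or order selection is
performed.

## Water model (PLSR)

Per cookie, the mean surface spectrum (19 bands; an 18-band analysis is
available via band exclusion) is regressed on gravimetric water percent with
PLS1 by the NIPALS algorithm: mean-centering, no variance scaling by default
(bands share units; a scaling switch exists), deflation after each
component, final coefficients `B = W(PᵀW)⁻¹q`.  With as many components as
the predictor rank, PLSR equals OLS (oracle test at 1e-8; additionally
cross-checked against an independent reference implementation).
Zero-variance bands are dropped with a warning and get zero coefficients.

Model selection follows the study protocol: a seeded random 2/3–1/3
train/test split (99 samples → 66/33), fivefold cross-validation on the
training split with contiguous folds after a seeded shuffle, and the
smallest component count within 1 % of the minimum CV-RMSEP (so pure-noise
responses fall back to one component).  Accuracy is RMSEP =
√(Σ(ŷ−y)²/n) on the held-out third.  Pixel-wise water maps apply the
coefficient vector per pixel with optional masked Gaussian smoothing; for a
linear model the unsmoothed map average equals the mean-spectrum prediction.

## Numerical and design notes

* Eigen- and least-squares problems use symmetric `eigh` and `lstsq`; no
  hand-rolled linear algebra.
* The NIR wavelength peaks at 1440/1930 nm relevant to water analysis lie
  outside the 385–970 nm instrument range and are not modelled.
* The design grid keeps 105 cookies (5 temps × 7 times × 3 replicates);
  train/test arithmetic for 99 samples is validated separately because both
  set sizes occur in practice.
* Default problem sizes: 256×256 images, 30 + 105 cookies per run, 10 seed
  replicates for stochastic summaries.  A full replicate (generate, segment,
  train, fit, evaluate) takes ~10 s on one CPU; unit tests run on 64×64
  images with identical structure.
* Determinism: every stochastic step is seeded; one global seed fans out to
  per-stage seeds via `seed·1009 + offset (mod 2³¹)`, so stages can be rerun
  in isolation.  Same seed ⇒ byte-identical datasets and artifacts.

## Known limitations

* The component count selected by cross-validation occasionally (≈ 1 seed in
  10) rises above 3, in which case near-collinear visible bands can develop
  large cancelling coefficients that displace the largest-|coefficient|
  wavelength from 970 nm for that replicate; stochastic summaries therefore
  report the modal wavelength over seed replicates.
* The score anchor (underbaked-class mean = 0) is in-sample; scoring cookies
  lighter than the training underbaked class yields small positive scores.
* Segmentation assumes one cookie per frame on a darker background; touching
  cookies are out of scope.
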