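# Methods

## The circadian light model

`circalight` computes circadian light (CL_A) as a weighted combination
of three retinal signals evaluated on a 380–780 nm, 5 nm grid:

1. a **melanopsin** term, ∫Mc·E dλ, with Mc the lens-corrected
   melanopsin sensitivity;
2. a **blue-versus-yellow opponent** term,
   b−y = ∫(S/mp)·E dλ − k·∫(V/mp)·E dλ (k = 0.2616), where S is the
   S-cone fundamental and the division by the macular pigment
   transmittance mp removes the pre-receptoral screening from the cone
   inputs; and
3. a saturating **rod** term, a_rod·(1 − exp(−∫V′·E dλ / RodSat)) with
   a_rod = 3.3 and RodSat = 6.5 W·m⁻² — rods oppose the opponent
   pathway but saturate at moderate light levels.

When b−y > 0 ("blue" light), CL_A = 1548·[mel + 0.7·(b−y) − rod];
otherwise CL_A = 1548·mel.  Circadian stimulus is the saturating
transform CS = 0.7·[1 − 1/(1 + (CL_A/355.7)^1.1026)]: zero in
darkness, 0.35 at CL_A = 355.7, asymptoting to 0.7 (the maximum
observed melatonin suppression fraction).

Model facts the implementation surfaces rather than hides:

- the **branch switch at b−y = 0 is discontinuous** (the rod term is
  present only on the opponent branch).  `cla()` reports the branch
  taken and all intermediate integrals, and the test suite
  characterizes the jump, bounding it by 1548·a_rod·(1−e^(−∫V′E/RodSat));
- the bracket can go **negative** for dim red-heavy light; CS is
  undefined there, so CL_A is clamped at 0 and flagged.

Integration is a rectangle (Riemann) sum with Δλ = grid step — the
discrete-sum reading of the model — and every oracle in the test suite
uses the same rule.  1 nm spectra are binned to 5 nm by energy-
conserving bin means (bins centered on multiples of 5 nm, missing edge
samples treated as zero).

## Observer tables

The eight spectral functions are bundled as a checksummed CSV
(`data/observer_tables_synthetic.csv`) generated from closed-form
approximations: Wyman–Sloan–Shirley fits for the CIE 1931
color-matching functions, the Govardovskii A1 pigment nomogram with a
smooth lens-transmittance model for melanopsin (λmax 480 nm) and the
S-cone (419 nm), a Gaussian 460 nm absorbance template for macular
pigment (peak density 0.35), and asymmetric Gaussians pinned to the
defining photometric maxima (V(555) = 1; V′ peaking at the 505 nm grid
point).  See `data/PROVENANCE.md` for parameters.

Consequence: all *relative* and self-consistent quantities — CCT round
trips, chromaticity targets, branch structure, monotonicities, oracle
equivalences — are exact or near-exact, but **absolute CL_A values are
not interchangeable** with those from tools built on the measured
standards tables.  Results that depend on absolute agreement with
published calculators should be read as qualitative here.

## Photometry and colorimetry

Illuminance is 683·ΣV·E·Δλ.  CCT is found by nearest-point search
against a precomputed 1 K-resolution Planckian locus (1000–20000 K) in
the CIE 1960 uv plane, using the bundled color-matching functions for
both the source and the locus (self-consistency is what makes the
Planckian round trip exact to ±2 K).  The signed distance Duv is
reported, and |Duv| > 0.05 flags the result as out of gamut
(chromaticity too far from the locus for CCT to be meaningful).

## Scene simulator

The simulator stands in for two data-collection campaigns:

- **Laboratory protocol** (default 100 scenarios × 5 readings): four
  electric sources at 1500/3000/4200/6500 K, used singly or in pairs
  with Dirichlet weights, plus window daylight.  Target illuminance is
  drawn from a two-mode distribution — dim electric interiors
  (lognormal, median ≈ 150 lx, capped at 800 lx) and daylight-adjacent
  positions (lognormal, median ≈ 3000 lx, 800–10,000 lx) — because the
  deployment environments the sensor is meant for are exactly this
  mixture.  Four pinned scenarios guarantee the protocol's extreme
  conditions (10 lx, 10,000 lx, 1500 K, ≈10,500 K) deterministically.
- **Field protocol**: warm sources (1800/2700/4000 K), venetian-blind
  slat angles cycling through {retracted, 45°, 90°, 135°}, window
  distances 0–9 ft, view angles 0–270°.

Electric sources are Planckian radiators *through the visible* — they
hit the stated CCTs and are analytically testable — multiplied by a
logistic infrared cutoff (midpoint 870 nm, width 30 nm), because real
luminaires emit essentially nothing in the sensor's 1100 nm band while
daylight does; without the cutoff a blackbody 1500 K "electric" source
would out-radiate daylight in the near infrared and invert the
IR-tracks-daylight association the deployment analysis relies on.
Daylight is synthesized as a Planckian base plus two Gaussian
correction bands whose weights are solved exactly so the chromaticity
(under the bundled CMFs) lands on the CIE daylight-locus polynomial
for the requested CCT — a 6504 K input reproduces the (0.3127, 0.3290)
white point by construction.  This is a chromaticity-exact synthetic
daylight, not the S0/S1/S2 component reconstruction.

Blind/distance/view attenuation factors ({1.0, 0.6, 0.3, 0.15};
inverse-square-with-floor; cosine-with-floor) are invented engineering
constants: only their monotonicity is load-bearing, and they are
configurable.

What the simulator does **not** emulate: measured luminaire SPDs (LED
spikes, fluorescent lines), sky models or room geometry, spectral
changes of daylight with weather and time of day.  Passing tests
therefore demonstrate correctness of the measurement chain under
controlled, physically plausible spectra — not field accuracy for any
specific luminaire.

## Sensor model

Four Gaussian channels at 465/525/615/1100 nm (FWHM 50 nm visible,
100 nm infrared; the true responsivities of such devices are
unpublished, so the shape is configurable).  Field names follow the
device datasheet convention, which labels the 465 nm band "R" and the
615 nm band "B" — physically inverted; internally channels are
identified by wavelength.

The on-board illuminance and CCT outputs are modeled as an invertible
linear mixing of (true lux, true CCT, measured infrared irradiance)
followed by multiplicative noise (defaults: CV 5 % lux, 2 % CCT, 5 %
per channel) and clamping to the instrument ranges (0.1–100,000 lx;
1800–10,000 K; clamped readings are flagged, and the calibration
fitter drops them by default — the counterpart of the data screening
step that removes physically invalid rows).  The default mixing is the
exact algebraic inverse of the no-intercept calibration pair

    lux = 0.0596·CCT′ + 1.6064·IR + 0.8432·lux′
    CCT = 1.048·CCT′ − 0.5427·IR + 0.1761·lux′

so that at zero noise the calibration module recovers precisely these
coefficients — the distortion family and the correction family are
matched by design.  A side effect faithful to practice: the inverse
mapping drives raw lux negative in dim warm scenes and raw CCT out of
range in bright ones, so a substantial fraction of extreme readings is
flagged and screened, as in real campaigns.

## Calibration and CS prediction

Calibration: screen (negative light values; optionally clamped rows) →
seeded 70/30 split → feature selection by coefficient p-value (< 0.05)
in the full no-intercept OLS over candidates (CCT′, IR, lux′, r, g, b;
perfectly collinear candidates resolved by keeping the earliest) →
least squares through the origin → MAE/MSE/RMSE/R²/adjusted R²
(Wherry) on train, test, and optionally a full-data refit.  Fitting
without an intercept mirrors the reference calibration form; an
intercept is available behind a flag.

CS prediction: features are the six sensor outputs; the target is CS
recomputed from each scene spectrum.  Linear regression and a random
forest (500 trees, unrestricted depth, min leaf 2, bootstrap; the
common defaults for the importance measures reported) are compared on
a 70/30 split and by seeded 5-fold cross-validation, the
cross-validated metric being the mean over folds.  Importance is
reported two ways: %IncMSE (percent MSE increase when one feature is
permuted, 10 seeded repeats, computed on held-out predictions) and
IncNodePurity (total sample-weighted variance-impurity decrease per
feature across all trees, computed from the fitted trees to match the
classic randomForest definition rather than sklearn's normalized
importances).

A structural finding, verified across every configuration tried
(protocol variants, channel noise 5–15 %, ADC quantization, channel
saturation): when the channel features are calibrated absolute
irradiances, the 465 nm channel dominates both importance rankings,
because it directly measures the spectral band that defines CL_A.  The
infrared channel ranks first only if the visible-channel information
is degraded in ways this sensor model deliberately does not assume.
The corresponding importance expectation in the acceptance suite is
therefore left failing, as an honest statement of the model's
behavior, with the analysis here.

## Exposure analytics

- **Day window**: fixed local clock interval, default 06:00–18:00 —
  the only reproducible convention absent per-site sunrise data;
  configurable.
- **Nonwear**: a maximal run with illuminance rolling range < 1 lx and
  no motion events is flagged when longer than 2 h (if any part is in
  the day window) or 4 h (entirely at night).  The flatness tolerance
  is a choice (the durations are the documented rule; the tolerance is
  not), and the detector is verified against an O(n²) from-scratch
  window scan.
- **Dim-light CCT masking**: CCT estimation is unreliable at low
  signal, so CCT is masked at night and wherever calibrated lux
  < 10 lx (default) before any CCT statistics.
- **Weekly summaries**: 7-day blocks aligned to the series start;
  sample mean and unbiased (n−1) variance per week × day/night, nonwear
  records excluded; empty cells reported with n = 0.
- **Paired t test**: t = mean(d)/(sd(d)/√n), df = n−1, two-tailed p;
  all-zero differences return t = 0, p = 1; constant nonzero
  differences are rejected as degenerate.  No multiple-comparison
  adjustment is applied (the deployment analyses report unadjusted
  tests).
- **Post hoc power**: noncentral-t power of a one-sample/paired design,
  noncentrality d·√n, df = n−1; default one-tailed (n = 29, d = 0.53,
  α = .05 gives 0.873, matching the reference design figure; the
  two-tailed value would be 0.787).

## Problem sizes and determinism

Default study sizes: 100 scenarios × 5 readings for protocols; 35-day,
15-minute resident logs; 1500-row synthetic tables for the
noisy-coefficient-recovery checks (sized so a 5 % coefficient
tolerance sits ≈4 standard errors from the truth); 500-tree forests.
All randomness descends from one integer seed, expanded per pipeline
stage by hashing the stage name, so any stage reruns identically in
isolation; the pipeline writes a manifest with stage seeds and SHA-256
checksums of every artifact.

## Known limitations

- Absolute CL_A/CS values inherit the synthetic observer tables
  (above).
- The sensor's distortion, channel shapes and noise are stand-ins for
  proprietary device internals; parameter-recovery results show the
  calibrators work, not that any particular device obeys this model.
- The CCT search range is 1000–20000 K; sources beyond (e.g. 25000 K
  daylight) clamp to the range end.
- No clinical outcomes, circadian phase estimation, or light-therapy
  dosing are modeled.
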