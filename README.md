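# circalight

Tools for measuring **personal circadian light exposure** with wearable
light loggers — for lighting researchers and health-care study teams
who need circadian-effective light metrics (not just lux) from cheap
body-worn sensors, validated against spectrophotometer ground truth.

Ordinary photometry weights light by the visual response V(λ); the
circadian system responds differently, with strong short-wavelength
(melanopsin) drive. `circalight` implements the circadian light /
circadian stimulus model:

    CL_A = 1548 · [ ∫Mc(λ)E(λ)dλ
                    + a_{b−y}·( ∫(S(λ)/mp(λ))E(λ)dλ − k·∫(V(λ)/mp(λ))E(λ)dλ )
                    − a_rod·(1 − e^{−∫V'(λ)E(λ)dλ / RodSat}) ]   if b−y > 0
    CL_A = 1548 · ∫Mc(λ)E(λ)dλ                                   otherwise

    CS   = 0.7 · [ 1 − 1 / (1 + (CL_A / 355.7)^{1.1026}) ]

where E(λ) is spectral irradiance, Mc the lens-corrected melanopsin
sensitivity, S the S-cone fundamental, mp the macular pigment
transmittance, V/V′ the photopic/scotopic efficiency functions, and
b−y the blue-versus-yellow opponent channel whose sign selects the
branch.  CS estimates fractional nocturnal melatonin suppression and
saturates below 0.7 (CS = 0.35 exactly at CL_A = 355.7).

Around this core the package provides the full measurement chain:

- **`spectral`** — SPDs, photopic illuminance, CCT (Planckian-locus
  search in the CIE 1960 uv plane), CL_A and CS on a canonical
  380–780 nm / 5 nm grid;
- **`scenes`** — synthetic laboratory and nursing-home lighting
  protocols (Planckian electric sources 1500–6500 K, chromaticity-exact
  daylight, blinds/distance/view-angle attenuation, 360–1200 nm grids
  for the infrared channel);
- **`sensor`** — a four-channel wearable model (465/525/615/1100 nm
  Gaussian bands) with configurable distortion, noise, instrument-range
  clamping, and multi-day log generation with nonwear episodes;
- **`calibration`** — no-intercept linear calibration of raw sensor lux
  and CCT against ground truth, with significance-based feature
  selection, 70/30 evaluation and MAE/MSE/RMSE/R²/adjusted-R² metrics;
- **`cs_prediction`** — CS prediction from sensor features by linear
  regression and random forest, with 5-fold cross-validation and dual
  feature importance (%IncMSE and IncNodePurity);
- **`analytics`** — calibrated exposure series, day/night segmentation,
  nonwear detection (2 h day / 4 h night flat-signal rule), dim-light
  CCT masking, weekly summaries, paired t tests, post hoc power;
- **`io` / `cli` / `pipeline`** — CSV/JSON/YAML formats and a
  `circalight` command-line tool (`simulate-scenes`, `simulate-logs`,
  `compute-cs`, `calibrate`, `train-cs`, `analyze-exposure`,
  `run-all`).

The bundled observer tables are synthetic analytic reconstructions of
the standard spectral functions (see
`src/circalight/data/PROVENANCE.md` and `docs/methods.md`).

## Worked example

A nursing-home room: one 2700 K luminaire, blinds at 45°, three feet
from the window, daylight carrying 60 % of the light, 750 lx at the
wearer:

```python
from circalight.observers import load_observer_tables
from circalight.scenes import LightSource, Scenario, mix_scene
from circalight.spectral import spd_to_metrics

tables = load_observer_tables()
scene = Scenario(
    sources=((LightSource("planckian-electric", 2700.0), 1.0),),
    daylight_fraction=0.6, daylight_cct=6500.0,
    blind_angle="45", window_distance_ft=3.0, target_lux=750.0,
)
m = spd_to_metrics(mix_scene(scene, tables=tables), tables)
print(f"illuminance : {m.lux:8.1f} lx")
print(f"CCT         : {m.cct.cct:8.0f} K   (Duv {m.cct.duv:+.4f})")
print(f"CL_A        : {m.cla.value:8.1f}     ({m.cla.branch} branch)")
print(f"CS          : {m.cs:8.3f}")
```

prints

```
illuminance :    750.0 lx
CCT         :     3398 K   (Duv -0.0045)
CL_A        :    689.2     (opponent branch)
CS          :    0.472
```

The scene reads as a warm mixed electric/daylight condition (3398 K,
slightly below the Planckian locus), and its circadian stimulus of
0.47 is in the range considered effective daytime exposure — the
blue-rich daylight share pushes CL_A well past the 355.7
half-saturation point even at a moderate 750 lx.

The full simulate → calibrate → train → analyze chain, with every
artifact and a seed/checksum manifest, is one command:

```sh
circalight run-all --seed 1 --out run_output
```

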