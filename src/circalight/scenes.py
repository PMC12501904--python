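"""Synthetic lighting scenes: electric sources, daylight, and mixtures.

Emulates two data-collection protocols for wearable-sensor calibration:

* a *laboratory* protocol — 100 lighting scenarios from four dimmable
  electric sources (1500/3000/4200/6500 K) plus window daylight,
  spanning 10-10,000 lux and 1500-10,500 K, with readings concentrated
  in a dim-interior mode and a daylight-adjacent mode;
* a *field* (nursing-home) protocol — warm sources (1800/2700/4000 K)
  with venetian-blind slat angles, window distances and view angles
  modulating daylight admission.

Electric sources are modeled as Planckian radiators through the
visible — they match the stated CCTs, are analytically testable, and
cover the 1500 K source that the CIE daylight series cannot — with a
smooth infrared cutoff beyond ~900 nm, since indoor luminaires emit
essentially nothing in the sensor's 1100 nm band.  This is a
documented stand-in for the real fixtures, not a claim about their
spectra.  Daylight is
synthesized to land exactly on the CIE daylight-locus chromaticity for
its CCT (see :func:`daylight_spd`).  Scene spectra run 360-1200 nm at
5 nm so the sensor's 1100 nm infrared channel is computable; all
photometric/circadian math still uses 380-780 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .observers import ObserverTables, load_observer_tables
from .spectral import (
    SPD,
    SpectralError,
    photopic_illuminance,
    planck_spectral_irradiance,
)

__all__ = [
    "SCENE_WAVELENGTHS",
    "LightSource",
    "Scenario",
    "BLIND_FACTORS",
    "planckian_spd",
    "electric_spd",
    "daylight_spd",
    "mix_scene",
    "lab_protocol",
    "field_protocol",
]

#: default scene grid: 360-1200 nm at 5 nm
SCENE_WAVELENGTHS = np.arange(360.0, 1201.0, 5.0)

LAB_SOURCE_CCTS = (1500.0, 3000.0, 4200.0, 6500.0)
FIELD_SOURCE_CCTS = (1800.0, 2700.0, 4000.0)
BLIND_ANGLES = ("retracted", "45", "90", "135")

# blind-slat transmission factors: invented engineering constants; only
# their monotone ordering (retracted > 45 > 90 > 135) is load-bearing
BLIND_FACTORS = {"retracted": 1.0, "45": 0.6, "90": 0.3, "135": 0.15}


@dataclass(frozen=True)
class LightSource:
    """One luminaire or daylight contribution in a scene."""

    kind: str            # "planckian-electric" | "cie-daylight"
    cct: float           # kelvin
    dimmer: float = 1.0  # fraction of full output in [0, 1]

    def __post_init__(self):
        if self.kind == "planckian-electric":
            if not 1000.0 <= self.cct <= 20000.0:
                raise ValueError(f"planckian cct {self.cct} outside [1000, 20000] K")
        elif self.kind == "cie-daylight":
            if not 4000.0 <= self.cct <= 25000.0:
                raise ValueError(f"daylight cct {self.cct} outside [4000, 25000] K")
        else:
            raise ValueError(f"unknown source kind {self.kind!r}")
        if not 0.0 <= self.dimmer <= 1.0:
            raise ValueError("dimmer must be in [0, 1]")


@dataclass(frozen=True)
class Scenario:
    """One lighting condition: weighted electric sources plus attenuated
    daylight, rescaled to a target illuminance."""

    sources: tuple          # tuple of (LightSource, weight >= 0)
    daylight_fraction: float = 0.0
    daylight_cct: float = 6500.0
    blind_angle: str = "retracted"
    window_distance_ft: float = 0.0   # 0-9 feet
    view_angle_deg: float = 0.0       # 0 facing window .. 270
    target_lux: float = 100.0

    def __post_init__(self):
        if any(w < 0 for _, w in self.sources):
            raise ValueError("source weights must be nonnegative")
        if not 0.0 <= self.daylight_fraction <= 1.0:
            raise ValueError("daylight_fraction must be in [0, 1]")
        if self.blind_angle not in BLIND_FACTORS:
            raise ValueError(f"blind_angle must be one of {BLIND_ANGLES}")
        if not 0.0 <= self.window_distance_ft <= 9.0:
            raise ValueError("window distance must be in [0, 9] feet")
        if not 0.0 <= self.view_angle_deg <= 270.0:
            raise ValueError("view angle must be in [0, 270] degrees")
        if self.target_lux <= 0:
            raise ValueError("target_lux must be positive")

    def attenuation(self) -> float:
        """Daylight attenuation from blinds, window distance, and view
        angle; each factor in (0, 1], monotone in its argument."""
        blind = BLIND_FACTORS[self.blind_angle]
        distance = 1.0 / (1.0 + (self.window_distance_ft / 3.0) ** 2)
        theta = min(self.view_angle_deg, 180.0)
        view = 0.2 + 0.8 * (1.0 + np.cos(np.radians(theta))) / 2.0
        return float(blind * distance * view)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sources"] = [
            {"kind": s.kind, "cct": s.cct, "dimmer": s.dimmer, "weight": w}
            for s, w in self.sources
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        sources = tuple(
            (LightSource(s["kind"], s["cct"], s.get("dimmer", 1.0)), s["weight"])
            for s in d["sources"]
        )
        rest = {k: v for k, v in d.items() if k != "sources"}
        return cls(sources=sources, **rest)


def _unit_lux(spd: SPD, tables: ObserverTables) -> SPD:
    lux = photopic_illuminance(spd, tables)
    if lux <= 0:
        raise SpectralError("cannot normalize an SPD with zero illuminance")
    return spd.scaled(1.0 / lux)


def planckian_spd(T: float, grid=None, tables: ObserverTables | None = None) -> SPD:
    """Planckian (blackbody) source at temperature T, normalized to unit
    photopic lux; smooth and strictly positive on the grid."""
    if not 1000.0 <= T <= 20000.0:
        raise ValueError(f"Planckian temperature {T} outside [1000, 20000] K")
    grid = SCENE_WAVELENGTHS if grid is None else np.asarray(grid, dtype=float)
    tables = tables or load_observer_tables()
    return _unit_lux(SPD(grid, planck_spectral_irradiance(grid, T)), tables)


def _ir_cutoff(lam: np.ndarray) -> np.ndarray:
    """Smooth infrared roll-off of indoor luminaires (logistic, midpoint
    870 nm): electric fixtures emit almost nothing in the sensor's
    1100 nm band, unlike daylight, so near-infrared tracks daylight."""
    return 1.0 / (1.0 + np.exp((lam - 870.0) / 30.0))


def electric_spd(T: float, grid=None, tables: ObserverTables | None = None) -> SPD:
    """Indoor electric source at CCT ≈ T: Planckian through the visible
    with the luminaire infrared cutoff, normalized to unit photopic
    lux.  (The cutoff's visible tail shifts CCT by well under 1 %.)"""
    grid = SCENE_WAVELENGTHS if grid is None else np.asarray(grid, dtype=float)
    tables = tables or load_observer_tables()
    values = planck_spectral_irradiance(grid, T) * _ir_cutoff(grid)
    return _unit_lux(SPD(grid, values), tables)


def daylight_chromaticity(cct: float):
    """CIE daylight-locus chromaticity (x_D, y_D) for a CCT in
    [4000, 25000] K (the standard cubic polynomials in 1/T)."""
    if not 4000.0 <= cct <= 25000.0:
        raise ValueError(f"daylight cct {cct} outside [4000, 25000] K")
    t = 1.0e3 / cct
    if cct <= 7000.0:
        x = 0.244063 + 0.09911 * t + 2.9678 * t**2 - 4.6070 * t**3
    else:
        x = 0.237040 + 0.24748 * t + 1.9018 * t**2 - 2.0064 * t**3
    y = -3.000 * x**2 + 2.870 * x - 0.275
    return x, y


def _gaussian_band(grid, center, sigma):
    return np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def daylight_spd(cct: float, grid=None, tables: ObserverTables | None = None) -> SPD:
    """Synthetic daylight at a given CCT, normalized to unit photopic lux.

    A Planckian base at the requested CCT is corrected by two broad
    visible Gaussian bands whose weights are solved exactly so the
    spectrum's chromaticity under the bundled color-matching functions
    equals the CIE daylight-locus chromaticity for that CCT (D65 input
    reproduces the (0.3127, 0.3290) white point).  The Planckian base
    provides a physically shaped near-infrared tail for the sensor's
    1100 nm channel; the full 360-1200 nm spectrum is smooth with no
    splice.  This is a chromaticity-exact synthetic daylight, not the
    CIE S0/S1/S2 component reconstruction.
    """
    grid = SCENE_WAVELENGTHS if grid is None else np.asarray(grid, dtype=float)
    tables = tables or load_observer_tables()
    x, y = daylight_chromaticity(cct)
    basis = [
        planck_spectral_irradiance(grid, cct),
        _gaussian_band(grid, 460.0, 30.0),
        _gaussian_band(grid, 555.0, 45.0),
    ]
    lam_mask = (grid >= 380.0) & (grid <= 780.0)
    lam = grid[lam_mask]
    cmf = np.stack(
        [tables.on_grid(n, lam) for n in ("xbar", "ybar", "zbar")]
    )
    step = grid[1] - grid[0]
    A = np.stack([cmf @ (b[lam_mask] * step) for b in basis], axis=1)  # 3x3
    target = np.array([x / y, 1.0, (1.0 - x - y) / y])
    w = np.linalg.solve(A, target)
    values = sum(wi * b for wi, b in zip(w, basis))
    if values.min() < 0:
        # tiny negative overshoot possible at grid edges; clip and keep
        # chromaticity error negligible
        values = np.clip(values, 0.0, None)
    return _unit_lux(SPD(grid, values), tables)


def mix_scene(
    scenario: Scenario,
    grid=None,
    tables: ObserverTables | None = None,
) -> SPD:
    """Compose a scenario into one SPD.

    Weighted unit-lux source spectra are summed with the attenuated
    daylight contribution (``daylight_fraction`` of the pre-rescale
    mix), then the whole scene is rescaled to ``target_lux``.
    """
    grid = SCENE_WAVELENGTHS if grid is None else np.asarray(grid, dtype=float)
    tables = tables or load_observer_tables()
    total = np.zeros_like(grid)
    weight_sum = 0.0
    for source, weight in scenario.sources:
        if weight == 0 or source.dimmer == 0:
            continue
        if source.kind == "planckian-electric":
            spd = electric_spd(source.cct, grid, tables)
        else:
            spd = daylight_spd(source.cct, grid, tables)
        total = total + weight * source.dimmer * spd.values
        weight_sum += weight * source.dimmer
    df = scenario.daylight_fraction
    if df > 0:
        day = daylight_spd(scenario.daylight_cct, grid, tables)
        # daylight_fraction is the share of scene lux carried by daylight
        # at full admission; blinds/distance/view attenuate it
        electric_lux = weight_sum
        day_lux = df / (1.0 - df) * max(electric_lux, 1.0) if df < 1 else 1.0
        if df >= 1:
            total = np.zeros_like(grid)
        total = total + day_lux * scenario.attenuation() * day.values
    if not np.any(total > 0):
        raise SpectralError("empty scene: all weights zero and no daylight")
    spd = SPD(grid, total)
    lux = photopic_illuminance(spd, tables)
    return spd.scaled(scenario.target_lux / lux)


def _bimodal_lux(rng: np.random.Generator, dim_frac: float = 0.5) -> tuple:
    """Sample a target illuminance from the two stated modes: dim
    electric interiors (median ~150 lux) and daylight-adjacent
    positions (median ~3000 lux).  Returns (lux, is_daylight_mode)."""
    if rng.random() < dim_frac:
        lux = float(np.exp(rng.normal(np.log(150.0), 0.6)))
        return min(max(lux, 10.0), 800.0), False
    lux = float(np.exp(rng.normal(np.log(3000.0), 0.5)))
    return min(max(lux, 800.0), 10000.0), True


def lab_protocol(
    n_scenarios: int = 100,
    reps: int = 5,
    seed: int = 0,
    grid=None,
    tables: ObserverTables | None = None,
) -> list:
    """Generate the laboratory calibration protocol.

    Returns ``n_scenarios * reps`` (Scenario, SPD) pairs: each scenario
    is emitted ``reps`` times (the repeated readings of one stabilized
    condition; sensor noise is added downstream).  Scenarios sample a
    bimodal illuminance distribution over [10, 10000] lux and CCTs over
    [1500, 10500] K from the four electric sources plus daylight.  The
    first four scenarios pin the protocol's extreme conditions so the
    stated coverage is deterministic.
    """
    if n_scenarios < 1:
        raise ValueError("need at least one scenario")
    grid = SCENE_WAVELENGTHS if grid is None else np.asarray(grid, dtype=float)
    tables = tables or load_observer_tables()
    rng = np.random.default_rng(seed)

    def electric(cct, w=1.0):
        return (LightSource("planckian-electric", cct), w)

    pinned = [
        Scenario(sources=(electric(3000.0),), target_lux=10.0),
        Scenario(sources=(electric(6500.0),), daylight_fraction=0.8,
                 target_lux=10000.0),
        Scenario(sources=(electric(1500.0),), target_lux=120.0),
        Scenario(sources=(electric(6500.0),), daylight_fraction=0.97,
                 daylight_cct=11000.0, target_lux=6000.0),
    ]
    scenarios = list(pinned[:n_scenarios])
    while len(scenarios) < n_scenarios:
        lux, daylight_mode = _bimodal_lux(rng)
        n_src = int(rng.integers(1, 3))
        ccts = rng.choice(LAB_SOURCE_CCTS, size=n_src, replace=False)
        weights = rng.dirichlet(np.ones(n_src))
        sources = tuple(electric(float(c), float(w))
                        for c, w in zip(ccts, weights))
        if daylight_mode:
            df = float(rng.uniform(0.5, 0.95))
            dcct = float(rng.uniform(5000.0, 11000.0))
        else:
            df = float(rng.uniform(0.0, 0.2))
            dcct = float(rng.uniform(5000.0, 7500.0))
        scenarios.append(
            Scenario(sources=sources, daylight_fraction=df,
                     daylight_cct=dcct, target_lux=lux)
        )
    out = []
    for sc in scenarios:
        spd = mix_scene(sc, grid, tables)
        out.extend((sc, spd) for _ in range(reps))
    return out


def field_protocol(
    n_scenarios: int = 100,
    reps: int = 5,
    seed: int = 0,
    grid=None,
    tables: ObserverTables | None = None,
) -> list:
    """Generate the on-site (nursing home) protocol: warm electric
    sources (1800/2700/4000 K) with blind-angle, window-distance and
    view-angle grids modulating daylight; warm-dominant CCTs with a
    daylight-driven high tail."""
    if n_scenarios < 1:
        raise ValueError("need at least one scenario")
    grid = SCENE_WAVELENGTHS if grid is None else np.asarray(grid, dtype=float)
    tables = tables or load_observer_tables()
    rng = np.random.default_rng(seed)

    scenarios = []
    for i in range(n_scenarios):
        lux, daylight_mode = _bimodal_lux(rng, dim_frac=0.6)
        n_src = int(rng.integers(1, 3))
        ccts = rng.choice(FIELD_SOURCE_CCTS, size=n_src, replace=False)
        weights = rng.dirichlet(np.ones(n_src))
        sources = tuple(
            (LightSource("planckian-electric", float(c)), float(w))
            for c, w in zip(ccts, weights)
        )
        blind = BLIND_ANGLES[i % len(BLIND_ANGLES)]  # cycle: full coverage
        df = float(rng.uniform(0.4, 0.9)) if daylight_mode else float(
            rng.uniform(0.0, 0.25)
        )
        scenarios.append(
            Scenario(
                sources=sources,
                daylight_fraction=df,
                daylight_cct=float(rng.uniform(5000.0, 9000.0)),
                blind_angle=blind,
                window_distance_ft=float(rng.uniform(0.0, 9.0)),
                view_angle_deg=float(rng.uniform(0.0, 270.0)),
                target_lux=min(lux, 6000.0),
            )
        )
    out = []
    for sc in scenarios:
        spd = mix_scene(sc, grid, tables)
        out.extend((sc, spd) for _ in range(reps))
    return out
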