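"""Wearable light-sensor simulation.

Models a pendant-worn four-channel light logger: Gaussian-band channel
irradiances at 465, 525, 615 and 1100 nm, plus on-board illuminance and
correlated-color-temperature outputs that are *distorted* versions of
the true photometric quantities.  The distortion is a configurable
linear mixing of (true lux, true CCT, infrared irradiance) followed by
seeded noise and clamping to the instrument's specified measurement
ranges (0.1-100,000 lux; 1800-10,000 K).

The default distortion is the exact inverse of the reference
calibration pair

    lux = 0.0596·CCT' + 1.6064·IR + 0.8432·lux'
    CCT = 1.048·CCT' − 0.5427·IR + 0.1761·lux'

so that, at zero noise, a no-intercept least-squares calibration on
(CCT', IR, lux') recovers those coefficients exactly.

A note on channel labels: the device datasheet labels the 465 nm band
"R" and the 615 nm band "B" (physically inverted).  Internally the
channels are named by wavelength; the ``r/g/b`` reading fields and log
columns follow the datasheet labeling so files round-trip faithfully
(``r`` = 465 nm, ``g`` = 525 nm, ``b`` = 615 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np

from .observers import ObserverTables, load_observer_tables
from .spectral import SPD, photopic_illuminance, cct_of_spd

__all__ = [
    "ChannelSet",
    "SensorReading",
    "DistortionSpec",
    "WearSchedule",
    "LUX_RANGE",
    "CCT_RANGE",
    "channel_response",
    "distort",
    "generate_log",
]

#: instrument measurement ranges (illuminance lux, color temperature K)
LUX_RANGE = (0.1, 100000.0)
CCT_RANGE = (1800.0, 10000.0)

#: datasheet label -> channel center wavelength (nm); note R/B inversion
DATASHEET_LABELS = {"r": 465.0, "g": 525.0, "b": 615.0, "ir": 1100.0}


@dataclass(frozen=True)
class ChannelSet:
    """Gaussian channel responsivities, peak-normalized.

    Center wavelengths are fixed by the device (465/525/615/1100 nm);
    bandwidths are configurable because the real responsivity curves
    are unpublished (defaults: 50 nm FWHM visible, 100 nm infrared).
    """

    centers: tuple = (465.0, 525.0, 615.0, 1100.0)
    fwhm: tuple = (50.0, 50.0, 50.0, 100.0)

    def responsivity(self, center: float, width: float, lam) -> np.ndarray:
        sigma = width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((np.asarray(lam, float) - center) / sigma) ** 2)


@dataclass(frozen=True)
class SensorReading:
    """One timestamped wearable record (datasheet channel labels)."""

    timestamp: datetime
    lux_raw: float
    cct_raw: float
    r: float        # 465 nm channel irradiance, W·m⁻²
    g: float        # 525 nm
    b: float        # 615 nm
    ir: float       # 1100 nm
    motion: bool
    clamped: bool = False  # lux_raw or cct_raw hit an instrument limit


@dataclass(frozen=True)
class DistortionSpec:
    """Linear mixing (lux, cct, ir) -> (lux_raw, cct_raw) plus noise.

    ``lux_mix`` and ``cct_mix`` are coefficient triples over
    (true lux, true CCT, IR channel irradiance).  Noise is
    multiplicative with coefficient of variation ``cv`` plus an
    additive floor, per output.  The mixing must be invertible in the
    (lux, cct) block so a linear calibration can undo it.
    """

    lux_mix: tuple = field(default=None)
    cct_mix: tuple = field(default=None)
    lux_cv: float = 0.0
    cct_cv: float = 0.0
    channel_cv: float = 0.0  # multiplicative noise on each channel irradiance
    lux_floor: float = 0.0   # additive noise scale, lux
    cct_floor: float = 0.0   # additive noise scale, K
    seed: int = 0

    def __post_init__(self):
        if self.lux_mix is None or self.cct_mix is None:
            a, b = _default_forward_mixing()
            object.__setattr__(self, "lux_mix", a)
            object.__setattr__(self, "cct_mix", b)
        det = self.lux_mix[0] * self.cct_mix[1] - self.lux_mix[1] * self.cct_mix[0]
        if abs(det) < 1e-12:
            raise ValueError("distortion mixing is singular in the (lux, cct) block")
        for s in (self.lux_cv, self.cct_cv, self.lux_floor, self.cct_floor):
            if s < 0:
                raise ValueError("noise scales must be nonnegative")


#: reference calibration coefficients over (CCT', IR, lux')
LUX_CALIBRATION = (0.0596, 1.6064, 0.8432)
CCT_CALIBRATION = (1.048, -0.5427, 0.1761)


def _default_forward_mixing():
    """Invert the reference calibration pair to get the forward sensor
    distortion: (lux, cct, ir) -> (lux_raw, cct_raw)."""
    # calibration: [lux, cct]^T = B [lux', cct']^T + c·ir
    B = np.array(
        [
            [LUX_CALIBRATION[2], LUX_CALIBRATION[0]],
            [CCT_CALIBRATION[2], CCT_CALIBRATION[0]],
        ]
    )
    c = np.array([LUX_CALIBRATION[1], CCT_CALIBRATION[1]])
    Binv = np.linalg.inv(B)
    # [lux', cct']^T = Binv [lux, cct]^T − Binv c · ir
    d = -Binv @ c
    lux_mix = (Binv[0, 0], Binv[0, 1], d[0])
    cct_mix = (Binv[1, 0], Binv[1, 1], d[1])
    return lux_mix, cct_mix


def channel_response(spd: SPD, channels: ChannelSet = ChannelSet()) -> dict:
    """Channel irradiances Σ responsivity(λ)·E(λ)·Δλ, keyed by the
    datasheet labels; linear in the SPD.

    The grid must cover every channel's center ± FWHM (in particular
    the 1100 nm infrared band, so scene spectra must extend to
    1200 nm).
    """
    lam = spd.wavelengths
    out = {}
    for label, (center, width) in zip(
        DATASHEET_LABELS, zip(channels.centers, channels.fwhm)
    ):
        if lam[0] > center - width or lam[-1] < center + width:
            raise ValueError(
                f"SPD grid {lam[0]:.0f}-{lam[-1]:.0f} nm does not cover the "
                f"{center:.0f} nm channel support (± {width:.0f} nm)"
            )
        resp = channels.responsivity(center, width, lam)
        out[label] = float(np.sum(resp * spd.values) * spd.step)
    return out


def distort(
    true_lux: float,
    true_cct: float,
    channels: dict,
    spec: DistortionSpec = DistortionSpec(),
    timestamp: datetime | None = None,
    motion: bool = False,
    rng: np.random.Generator | None = None,
) -> SensorReading:
    """Produce one raw sensor reading from true photometrics.

    Channel noise is applied first; the on-board lux'/CCT' outputs mix
    the *measured* infrared irradiance (the device only knows its own
    channels), then get multiplicative + additive noise and are clamped
    to the instrument ranges (clamped readings flagged).  Deterministic
    for a fixed spec seed (or caller-supplied ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.channel_cv > 0:
        channels = {
            k: max(v * (1.0 + spec.channel_cv * rng.standard_normal()), 0.0)
            for k, v in channels.items()
        }
    ir = channels["ir"]
    lux_raw = (
        spec.lux_mix[0] * true_lux + spec.lux_mix[1] * true_cct + spec.lux_mix[2] * ir
    )
    cct_raw = (
        spec.cct_mix[0] * true_lux + spec.cct_mix[1] * true_cct + spec.cct_mix[2] * ir
    )
    if spec.lux_cv > 0 or spec.lux_floor > 0:
        lux_raw = lux_raw * (1.0 + spec.lux_cv * rng.standard_normal())
        lux_raw += spec.lux_floor * rng.standard_normal()
    if spec.cct_cv > 0 or spec.cct_floor > 0:
        cct_raw = cct_raw * (1.0 + spec.cct_cv * rng.standard_normal())
        cct_raw += spec.cct_floor * rng.standard_normal()
    clamped = not (
        LUX_RANGE[0] <= lux_raw <= LUX_RANGE[1]
        and CCT_RANGE[0] <= cct_raw <= CCT_RANGE[1]
    )
    lux_raw = float(np.clip(lux_raw, *LUX_RANGE))
    cct_raw = float(np.clip(cct_raw, *CCT_RANGE))
    return SensorReading(
        timestamp=timestamp or datetime(2000, 1, 1),
        lux_raw=lux_raw,
        cct_raw=cct_raw,
        r=channels["r"],
        g=channels["g"],
        b=channels["b"],
        ir=channels["ir"],
        motion=motion,
        clamped=clamped,
    )


@dataclass(frozen=True)
class WearSchedule:
    """Multi-day wear plan for one simulated person.

    ``nonwear`` episodes are (start, end) datetime pairs during which
    the device sits still: light readings freeze and motion stays off.
    """

    start: datetime
    days: int
    cadence_min: int = 5
    day_start_hour: int = 6
    day_end_hour: int = 18
    nonwear: tuple = ()

    def __post_init__(self):
        if self.days < 1:
            raise ValueError("schedule must cover at least one day")
        eps = sorted(self.nonwear)
        for (s1, e1), (s2, e2) in zip(eps, eps[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping nonwear episodes at {s2}")
        for s, e in eps:
            if e <= s:
                raise ValueError("nonwear episode must have positive duration")

    def in_nonwear(self, t: datetime) -> bool:
        return any(s <= t < e for s, e in self.nonwear)

    def is_day(self, t: datetime) -> bool:
        return self.day_start_hour <= t.hour < self.day_end_hour


def generate_log(
    schedule: WearSchedule,
    day_scenes: list,
    night_scenes: list,
    spec: DistortionSpec = DistortionSpec(),
    tables: ObserverTables | None = None,
    seed: int = 0,
    motion_prob: float = 0.3,
) -> list:
    """Simulate a multi-day sensor log.

    ``day_scenes``/``night_scenes`` are pools of scene SPDs (full
    360-1200 nm grid); each reading samples one, with a per-reading
    brightness jitter so worn intervals are never flat.  Nonwear
    episodes freeze the light values at the episode's first reading and
    force ``motion=False``.  Deterministic under ``seed``.
    """
    tables = tables or load_observer_tables()
    rng = np.random.default_rng(seed)
    cache = {}

    def metrics_of(scene_idx, pool):
        if (id(pool), scene_idx) not in cache:
            spd = pool[scene_idx]
            lux = photopic_illuminance(spd.restrict(), tables)
            cct = cct_of_spd(spd.restrict(), tables).cct
            ch = channel_response(spd)
            cache[(id(pool), scene_idx)] = (spd, lux, cct, ch)
        return cache[(id(pool), scene_idx)]

    n = schedule.days * 24 * 60 // schedule.cadence_min
    readings = []
    frozen = None
    for i in range(n):
        t = schedule.start + timedelta(minutes=i * schedule.cadence_min)
        if schedule.in_nonwear(t):
            if frozen is None:
                pool = day_scenes if schedule.is_day(t) else night_scenes
                _, lux, cct, ch = metrics_of(int(rng.integers(len(pool))), pool)
                frozen = (lux, cct, ch)
            lux, cct, ch = frozen
            reading = distort(lux, cct, ch, spec, timestamp=t, motion=False,
                              rng=np.random.default_rng(spec.seed))
        else:
            frozen = None
            pool = day_scenes if schedule.is_day(t) else night_scenes
            _, lux, cct, ch = metrics_of(int(rng.integers(len(pool))), pool)
            jitter = float(np.exp(rng.normal(0.0, 0.25)))
            ch = {k: v * jitter for k, v in ch.items()}
            reading = distort(
                lux * jitter, cct, ch, spec, timestamp=t,
                motion=bool(rng.random() < motion_prob), rng=rng,
            )
        readings.append(reading)
    return readings
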