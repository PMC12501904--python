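"""Photometric and circadian quantities from spectral power distributions.

The central object is the :class:`SPD`, spectral irradiance in
W·m⁻²·nm⁻¹ on a uniform 1 nm or 5 nm wavelength grid.  From an SPD the
module computes:

* photopic illuminance (lux), ``683 · Σ V(λ)·E(λ)·Δλ``;
* correlated color temperature (CCT) by nearest-point search on the
  Planckian locus in the CIE 1960 uv plane;
* circadian light CL_A, the Rea-model combination of a melanopsin term,
  a blue-versus-yellow spectral-opponent term and a saturating rod
  term; and
* circadian stimulus CS, a saturating transform of CL_A bounded below
  0.7 that estimates fractional nocturnal melatonin suppression.

All integrals are rectangle (Riemann) sums with Δλ equal to the grid
step; the canonical computation grid is 380-780 nm at 5 nm.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .observers import ObserverTables, load_observer_tables

__all__ = [
    "SPD",
    "CircadianParams",
    "CCTResult",
    "ClaResult",
    "SpdMetrics",
    "resample_to_5nm",
    "photopic_illuminance",
    "cct_of_spd",
    "chromaticity",
    "cla",
    "cs",
    "spd_to_metrics",
    "planck_spectral_irradiance",
]

VISIBLE_LO = 380.0
VISIBLE_HI = 780.0

#: hc/k in nm·K (second radiation constant)
_C2_NM_K = 1.4388e7


class SpectralError(ValueError):
    """Invalid spectral input (grid, coverage, or domain violations)."""


@dataclass(frozen=True)
class SPD:
    """Spectral irradiance on a uniform wavelength grid.

    Parameters
    ----------
    wavelengths : array of nm, strictly increasing, uniform step
    values : array of W·m⁻²·nm⁻¹, nonnegative, same length
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.wavelengths, dtype=float)
        val = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", lam)
        object.__setattr__(self, "values", val)
        if lam.ndim != 1 or len(lam) < 2:
            raise SpectralError("SPD needs at least two wavelength samples")
        if len(lam) != len(val):
            raise SpectralError("wavelengths and values must have equal length")
        steps = np.diff(lam)
        if np.any(steps <= 0):
            raise SpectralError("wavelengths must be strictly increasing")
        if np.ptp(steps) > 1e-9:
            raise SpectralError("wavelength step must be uniform to 1e-9 nm")
        if np.any(val < 0):
            raise SpectralError("spectral irradiance must be nonnegative")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def scaled(self, factor: float) -> "SPD":
        return SPD(self.wavelengths, self.values * factor)

    def total_irradiance(self) -> float:
        """Integrated irradiance over the grid, W·m⁻² (rectangle rule)."""
        return float(np.sum(self.values) * self.step)

    def restrict(self, lo: float = VISIBLE_LO, hi: float = VISIBLE_HI) -> "SPD":
        """Restrict to [lo, hi], zero-filling missing interior coverage.

        Coverage outside the window is dropped; a window not fully
        covered by the input raises a warning and is zero-filled, per
        the canonical-grid convention.
        """
        step = self.step
        grid = np.arange(lo, hi + step / 2, step)
        values = np.zeros_like(grid)
        mask = (self.wavelengths >= lo - 1e-9) & (self.wavelengths <= hi + 1e-9)
        inside = self.wavelengths[mask]
        if len(inside) < len(grid):
            warnings.warn(
                f"SPD does not fully cover {lo:.0f}-{hi:.0f} nm; "
                "missing samples treated as zero",
                stacklevel=2,
            )
        idx = np.round((inside - lo) / step).astype(int)
        keep = (idx >= 0) & (idx < len(grid))
        values[idx[keep]] = self.values[mask][keep]
        return SPD(grid, values)


@dataclass(frozen=True)
class CircadianParams:
    """Constants of the circadian-light (CL_A) and stimulus (CS) model."""

    k: float = 0.2616
    a_by: float = 0.7
    a_rod: float = 3.3
    rod_sat: float = 6.5  # W·m⁻², scotopic rod-saturation scale
    cla_scale: float = 1548.0
    cs_max: float = 0.7
    cla_half: float = 355.7
    cs_exponent: float = 1.1026

    def __post_init__(self):
        for name in (
            "k", "a_by", "a_rod", "rod_sat", "cla_scale",
            "cs_max", "cla_half", "cs_exponent",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class CCTResult:
    cct: float          # kelvin
    duv: float          # signed distance from the Planckian locus in uv
    out_of_gamut: bool  # |duv| > 0.05: CCT not meaningful

    def __float__(self):
        return self.cct


@dataclass(frozen=True)
class ClaResult:
    value: float
    branch: str          # "opponent" (b-y > 0) or "melanopsin-only"
    clamped: bool        # negative bracket clamped to zero
    integrals: dict = field(compare=False)

    def __float__(self):
        return self.value


@dataclass(frozen=True)
class SpdMetrics:
    lux: float
    cct: CCTResult | None   # None when chromaticity is undefined (zero SPD)
    cla: ClaResult
    cs: float


def resample_to_5nm(spd: SPD) -> SPD:
    """Bin a 1 nm SPD to the 5 nm grid by energy-conserving bin means.

    Bins are centered on multiples of 5 nm and cover center ± 2 nm;
    samples missing at the grid edges are treated as zero, so
    ``sum(out)·5 == sum(in)·1`` exactly.
    """
    if abs(spd.step - 1.0) > 1e-9:
        raise SpectralError(f"resample_to_5nm requires a 1 nm grid, got {spd.step} nm")
    lam = spd.wavelengths
    centers = np.arange(np.ceil(lam[0] / 5) * 5, lam[-1] + 1e-9, 5.0)
    values = np.zeros(len(centers))
    for j, c in enumerate(centers):
        lo = int(round(c - 2 - lam[0]))
        window = spd.values[max(lo, 0):min(lo + 5, len(lam))]
        values[j] = window.sum() / 5.0
    return SPD(centers, values)


def _canonical(spd: SPD) -> SPD:
    """Project an SPD onto the canonical 380-780 nm / 5 nm grid."""
    if abs(spd.step - 1.0) < 1e-9:
        spd = resample_to_5nm(spd)
    elif abs(spd.step - 5.0) > 1e-9:
        raise SpectralError(f"unsupported grid step {spd.step} nm (need 1 or 5 nm)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return spd.restrict()


def photopic_illuminance(spd: SPD, tables: ObserverTables | None = None) -> float:
    """Illuminance in lux: 683 · Σ V(λ)·E(λ)·Δλ over 380-780 nm."""
    if tables is None:
        tables = load_observer_tables()
    if spd.values.size == 0:
        raise SpectralError("empty SPD")
    v = tables.on_grid("V", spd.wavelengths)
    mask = (spd.wavelengths >= VISIBLE_LO) & (spd.wavelengths <= VISIBLE_HI)
    return float(683.0 * np.sum(v[mask] * spd.values[mask]) * spd.step)


def planck_spectral_irradiance(wavelengths_nm, T: float) -> np.ndarray:
    """Blackbody spectral shape at temperature T (relative units).

    Planck's law  B(λ) ∝ λ⁻⁵ / (exp(c₂/(λT)) − 1)  with λ in nm,
    normalized to unit maximum over the supplied grid.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    x = _C2_NM_K / (lam * T)
    # expm1 keeps the long-wavelength tail accurate
    b = (lam / 560.0) ** -5 / np.expm1(x)
    return b / b.max()


@functools.lru_cache(maxsize=4)
def _planckian_locus_uv(table_key: str = "default"):
    """(T, u, v) of the Planckian locus at 1 K from 1000-20000 K,
    computed with the bundled color-matching functions."""
    tables = load_observer_tables()
    lam = tables.wavelengths
    temps = np.arange(1000.0, 20001.0, 1.0)
    x = _C2_NM_K / lam[None, :] / temps[:, None]
    b = (lam[None, :] / 560.0) ** -5 / np.expm1(x)
    X = b @ tables.xbar
    Y = b @ tables.ybar
    Z = b @ tables.zbar
    denom = X + 15.0 * Y + 3.0 * Z
    return temps, 4.0 * X / denom, 6.0 * Y / denom


def _uv_of_xyz(X, Y, Z):
    denom = X + 15.0 * Y + 3.0 * Z
    return 4.0 * X / denom, 6.0 * Y / denom


def chromaticity(spd: SPD, tables: ObserverTables | None = None):
    """CIE 1931 (x, y) chromaticity of an SPD (visible range)."""
    if tables is None:
        tables = load_observer_tables()
    mask = (spd.wavelengths >= VISIBLE_LO) & (spd.wavelengths <= VISIBLE_HI)
    lam = spd.wavelengths[mask]
    e = spd.values[mask]
    X = float(np.sum(tables.on_grid("xbar", lam) * e) * spd.step)
    Y = float(np.sum(tables.on_grid("ybar", lam) * e) * spd.step)
    Z = float(np.sum(tables.on_grid("zbar", lam) * e) * spd.step)
    total = X + Y + Z
    if total <= 0:
        raise SpectralError("undefined chromaticity: SPD has no visible energy")
    return X / total, Y / total, (X, Y, Z)


def cct_of_spd(spd: SPD, tables: ObserverTables | None = None) -> CCTResult:
    """Correlated color temperature by Planckian-locus nearest-point
    search in the CIE 1960 uv plane (1000-20000 K, 1 K resolution)."""
    x, y, (X, Y, Z) = chromaticity(spd, tables)
    u, v = _uv_of_xyz(X, Y, Z)
    temps, lu, lv = _planckian_locus_uv()
    d2 = (lu - u) ** 2 + (lv - v) ** 2
    i = int(np.argmin(d2))
    duv = float(np.sqrt(d2[i]))
    # sign: positive above the locus (toward green)
    if v < lv[i]:
        duv = -duv
    return CCTResult(cct=float(temps[i]), duv=duv, out_of_gamut=abs(duv) > 0.05)


def cla(
    spd: SPD,
    tables: ObserverTables | None = None,
    params: CircadianParams = CircadianParams(),
) -> ClaResult:
    """Circadian light CL_A from a 5 nm SPD.

    The blue-yellow opponent channel is
    ``b−y = Σ (S/mp)·E·Δλ − k·Σ (V/mp)·E·Δλ``.  For ``b−y > 0`` the
    melanopsin term is augmented by the opponent contribution and
    reduced by a saturating rod term; otherwise CL_A is the melanopsin
    term alone.  A negative bracket (possible for dim red-less light)
    is clamped to zero and flagged, since CS is undefined below zero.
    """
    if tables is None:
        tables = load_observer_tables()
    if len(spd.wavelengths) != len(tables.wavelengths) or np.any(
        np.abs(spd.wavelengths - tables.wavelengths) > 1e-9
    ):
        raise SpectralError(
            "SPD and observer tables must share the canonical 5 nm grid; "
            "resample/restrict first"
        )
    dl = spd.step
    e = spd.values
    mel = float(np.sum(tables.Mc * e) * dl)
    s_term = float(np.sum(tables.S / tables.mp * e) * dl)
    v_term = float(np.sum(tables.V / tables.mp * e) * dl)
    rod_irr = float(np.sum(tables.Vprime * e) * dl)
    b_minus_y = s_term - params.k * v_term
    integrals = {
        "melanopsin": mel,
        "s_over_mp": s_term,
        "v_over_mp": v_term,
        "scotopic": rod_irr,
        "b_minus_y": b_minus_y,
    }
    if b_minus_y > 0:
        rod = params.a_rod * (1.0 - np.exp(-rod_irr / params.rod_sat))
        bracket = mel + params.a_by * b_minus_y - rod
        branch = "opponent"
    else:
        bracket = mel
        branch = "melanopsin-only"
    value = params.cla_scale * bracket
    clamped = value < 0
    if clamped:
        value = 0.0
    return ClaResult(value=float(value), branch=branch, clamped=clamped,
                     integrals=integrals)


def cs(cla_value: float, params: CircadianParams = CircadianParams()) -> float:
    """Circadian stimulus from CL_A:
    CS = cs_max·[1 − 1/(1 + (CL_A/cla_half)^exponent)], in [0, cs_max)."""
    cla_value = float(cla_value)
    if cla_value < 0:
        raise ValueError(f"CS undefined for negative CL_A ({cla_value})")
    if cla_value == 0:
        return 0.0
    ratio = (cla_value / params.cla_half) ** params.cs_exponent
    return params.cs_max * (1.0 - 1.0 / (1.0 + ratio))


def spd_to_metrics(
    spd: SPD,
    tables: ObserverTables | None = None,
    params: CircadianParams = CircadianParams(),
) -> SpdMetrics:
    """Bundle lux, CCT, CL_A and CS for one SPD (canonical 5 nm grid).

    Idempotent for input already on the canonical grid.  A spectrum
    with no visible energy gets ``cct=None`` (undefined chromaticity)
    and zero for the other quantities.
    """
    if tables is None:
        tables = load_observer_tables()
    canon = _canonical(spd)
    lux = photopic_illuminance(canon, tables)
    try:
        cct = cct_of_spd(canon, tables)
    except SpectralError:
        cct = None
    cla_res = cla(canon, tables, params)
    return SpdMetrics(lux=lux, cct=cct, cla=cla_res,
                      cs=cs(cla_res.value, params))
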