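"""Observer spectral functions for photometry, colorimetry and circadian modeling.

The circadian-light model needs eight spectral weighting functions on a
common 380-780 nm grid: the lens-corrected melanopsin sensitivity ``Mc``,
the S-cone fundamental ``S``, the macular pigment transmittance ``mp``,
the photopic and scotopic luminous efficiency functions ``V`` and
``Vprime``, and the CIE 1931 2-degree color-matching functions
``xbar/ybar/zbar``.

The functions shipped here are *synthetic* reconstructions built from
published closed-form approximations rather than reprinted standards
tables:

* color-matching functions: the multi-lobe piecewise-Gaussian fits of
  Wyman, Sloan & Shirley (2013), accurate to about 1 % of peak;
* photoreceptor sensitivities (melanopsin, S-cone): the Govardovskii
  (2000) A1 visual-pigment nomogram (alpha band) at the appropriate
  peak wavelength, filtered by a smooth crystalline-lens transmittance
  model;
* luminous efficiency: asymmetric Gaussians pinned to the defining
  maxima (V = 1 at 555 nm; V' = 1 near 507 nm);
* macular pigment: a Gaussian absorbance template at 460 nm with peak
  optical density 0.35.

They reproduce the qualitative structure the circadian-stimulus model
depends on (band positions, widths, opponent-channel sign behavior) and
are exactly self-consistent with the bundled CSV resource, which is the
canonical tabulation used throughout the package.  See
``data/PROVENANCE.md`` for the parameterization.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "ObserverTables",
    "CANONICAL_WAVELENGTHS",
    "load_observer_tables",
    "synthesize_tables",
    "table_checksums",
]

#: canonical grid: 380-780 nm inclusive at 5 nm (81 samples)
CANONICAL_WAVELENGTHS = np.arange(380.0, 781.0, 5.0)

_TABLE_COLUMNS = ("Mc", "S", "mp", "V", "Vprime", "xbar", "ybar", "zbar")

_DATA_CSV = "observer_tables_synthetic.csv"
_MANIFEST = "observer_tables_manifest.json"


def _split_gauss(lam, mu, sigma_l, sigma_r):
    """Piecewise Gaussian with different widths below/above the peak."""
    lam = np.asarray(lam, dtype=float)
    sigma = np.where(lam < mu, sigma_l, sigma_r)
    return np.exp(-0.5 * ((lam - mu) / sigma) ** 2)


# --- CIE 1931 2-deg CMFs: Wyman-Sloan-Shirley multi-lobe fits -------------

def xbar_fit(lam):
    return (
        1.056 * _split_gauss(lam, 599.8, 37.9, 31.0)
        + 0.362 * _split_gauss(lam, 442.0, 16.0, 26.7)
        - 0.065 * _split_gauss(lam, 501.1, 20.4, 26.2)
    )


def ybar_fit(lam):
    return 0.821 * _split_gauss(lam, 568.8, 46.9, 40.5) + 0.286 * _split_gauss(
        lam, 530.9, 16.3, 31.1
    )


def zbar_fit(lam):
    return 1.217 * _split_gauss(lam, 437.0, 11.8, 36.0) + 0.681 * _split_gauss(
        lam, 459.0, 26.0, 13.8
    )


# --- luminous efficiency ---------------------------------------------------

def photopic_v(lam):
    """Photopic luminous efficiency; exactly 1.0 at the 555 nm maximum."""
    return _split_gauss(lam, 555.0, 38.2, 46.7)


def scotopic_v(lam):
    """Scotopic luminous efficiency; unit maximum pinned to the 505 nm
    grid point (the defining rhodopsin peak sits at ~507 nm)."""
    return _split_gauss(lam, 505.0, 38.0, 40.0)


# --- photoreceptor sensitivities ------------------------------------------

def pigment_nomogram(lam, lam_max):
    """Govardovskii (2000) A1 pigment template, alpha band only.

    The beta (UV) band peaks near 189 + 0.315*lam_max nm and is
    negligible above 380 nm for the pigments used here.
    """
    lam = np.asarray(lam, dtype=float)
    x = lam_max / lam
    a = 0.8795 + 0.0459 * np.exp(-((lam_max - 300.0) ** 2) / 11940.0)
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    return 1.0 / (
        np.exp(A * (a - x)) + np.exp(B * (0.922 - x)) + np.exp(C * (1.104 - x)) + D
    )


def lens_transmittance(lam):
    """Smooth crystalline-lens transmittance: optical density decaying
    exponentially from ~1.0 at 380 nm with a 55 nm scale (young adult
    lens shape, synthetic parameterization)."""
    lam = np.asarray(lam, dtype=float)
    density = np.exp(-(lam - 380.0) / 55.0)
    return 10.0 ** (-density)


def macular_transmittance(lam):
    """Macular pigment transmittance: Gaussian absorbance template at
    460 nm (sigma 35 nm), peak optical density 0.35; strictly positive."""
    lam = np.asarray(lam, dtype=float)
    absorbance = np.exp(-0.5 * ((lam - 460.0) / 35.0) ** 2)
    return 10.0 ** (-0.35 * absorbance)


def melanopsin_lens_corrected(lam):
    """Melanopsin sensitivity (lambda_max 480 nm) seen through the lens,
    peak-normalized on a fine grid."""
    fine = np.arange(380.0, 781.0, 1.0)
    raw = pigment_nomogram(fine, 480.0) * lens_transmittance(fine)
    peak = raw.max()
    lam = np.asarray(lam, dtype=float)
    return pigment_nomogram(lam, 480.0) * lens_transmittance(lam) / peak


def s_cone_fundamental(lam):
    """S-cone corneal fundamental: 419 nm pigment nomogram filtered by
    lens and macular pigment, peak-normalized on a fine grid."""
    fine = np.arange(380.0, 781.0, 1.0)

    def raw(x):
        return (
            pigment_nomogram(x, 419.0)
            * lens_transmittance(x)
            * macular_transmittance(x)
        )

    peak = raw(fine).max()
    return raw(np.asarray(lam, dtype=float)) / peak


@dataclass(frozen=True)
class ObserverTables:
    """Tabulated observer functions on a shared uniform wavelength grid."""

    wavelengths: np.ndarray
    Mc: np.ndarray
    S: np.ndarray
    mp: np.ndarray
    V: np.ndarray
    Vprime: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    provenance: str = field(default="synthetic-analytic-v1", compare=False)

    def __post_init__(self):
        n = len(self.wavelengths)
        for name in _TABLE_COLUMNS:
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"table {name!r} length {len(arr)} != grid {n}")
            if np.any(arr < 0):
                raise ValueError(f"table {name!r} has negative entries")
        if np.any(self.mp <= 0):
            raise ValueError("macular transmittance must be strictly positive")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def on_grid(self, name: str, wavelengths) -> np.ndarray:
        """Linearly interpolate a table onto another grid (zero outside)."""
        lam = np.asarray(wavelengths, dtype=float)
        table = getattr(self, name)
        fill = 1.0 if name == "mp" else 0.0
        return np.interp(lam, self.wavelengths, table, left=fill, right=fill)


def synthesize_tables(wavelengths=None) -> ObserverTables:
    """Evaluate the analytic observer functions on a grid (default
    canonical 380-780 nm / 5 nm)."""
    lam = CANONICAL_WAVELENGTHS if wavelengths is None else np.asarray(
        wavelengths, dtype=float
    )
    return ObserverTables(
        wavelengths=lam,
        Mc=melanopsin_lens_corrected(lam),
        S=s_cone_fundamental(lam),
        mp=macular_transmittance(lam),
        V=photopic_v(lam),
        Vprime=scotopic_v(lam),
        xbar=np.clip(xbar_fit(lam), 0.0, None),
        ybar=np.clip(ybar_fit(lam), 0.0, None),
        zbar=np.clip(zbar_fit(lam), 0.0, None),
    )


def _tables_to_csv(tables: ObserverTables) -> str:
    buf = io.StringIO()
    buf.write("wavelength_nm," + ",".join(_TABLE_COLUMNS) + "\n")
    for i, lam in enumerate(tables.wavelengths):
        row = ",".join(
            format(getattr(tables, c)[i], ".12e") for c in _TABLE_COLUMNS
        )
        buf.write(f"{lam:.1f},{row}\n")
    return buf.getvalue()


def write_package_data(directory) -> None:
    """Regenerate the bundled CSV resource and its checksum manifest."""
    from pathlib import Path

    directory = Path(directory)
    text = _tables_to_csv(synthesize_tables())
    (directory / _DATA_CSV).write_text(text)
    digest = hashlib.sha256(text.encode()).hexdigest()
    manifest = {
        "file": _DATA_CSV,
        "sha256": digest,
        "provenance": "synthetic-analytic-v1",
        "grid": "380-780 nm, 5 nm step",
    }
    (directory / _MANIFEST).write_text(json.dumps(manifest, indent=2) + "\n")


def table_checksums() -> dict:
    """Checksum manifest of the bundled observer-table resource."""
    pkg = resources.files("circalight.data")
    return json.loads(pkg.joinpath(_MANIFEST).read_text())


def load_observer_tables(verify: bool = True) -> ObserverTables:
    """Load the canonical bundled tables, verifying the checksum manifest."""
    pkg = resources.files("circalight.data")
    text = pkg.joinpath(_DATA_CSV).read_text()
    if verify:
        manifest = table_checksums()
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != manifest["sha256"]:
            raise RuntimeError(
                "observer table resource does not match its checksum manifest"
            )
    rows = [line.split(",") for line in text.strip().splitlines()[1:]]
    data = np.array(rows, dtype=float)
    cols = {name: data[:, i + 1] for i, name in enumerate(_TABLE_COLUMNS)}
    return ObserverTables(wavelengths=data[:, 0], **cols)
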