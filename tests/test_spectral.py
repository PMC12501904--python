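import math

import numpy as np
import pytest

from circalight.observers import CANONICAL_WAVELENGTHS
from circalight.spectral import (
    SPD,
    CircadianParams,
    SpectralError,
    cct_of_spd,
    chromaticity,
    cla,
    cs,
    photopic_illuminance,
    planck_spectral_irradiance,
    resample_to_5nm,
    spd_to_metrics,
)

from conftest import random_spd


# ---------------------------------------------------------------- oracles

def binned_means_oracle(spd):
    """Independent loop implementation of 5 nm binning (zero-extended)."""
    centers, out = [], []
    c = math.ceil(spd.wavelengths[0] / 5) * 5
    while c <= spd.wavelengths[-1] + 1e-9:
        total = 0.0
        for w, v in zip(spd.wavelengths, spd.values):
            if c - 2 <= w <= c + 2:
                total += v
        centers.append(c)
        out.append(total / 5.0)
        c += 5
    return np.array(centers), np.array(out)


def cla_oracle(spd, tables, p):
    """Straight-loop evaluation of the circadian-light model, written
    independently of the vectorized implementation."""
    dl = spd.step
    mel = s_t = v_t = rod = 0.0
    for i in range(len(spd.wavelengths)):
        e = spd.values[i]
        mel += tables.Mc[i] * e * dl
        s_t += tables.S[i] / tables.mp[i] * e * dl
        v_t += tables.V[i] / tables.mp[i] * e * dl
        rod += tables.Vprime[i] * e * dl
    b_y = s_t - p.k * v_t
    if b_y > 0:
        value = p.cla_scale * (
            mel + p.a_by * b_y - p.a_rod * (1.0 - math.exp(-rod / p.rod_sat))
        )
    else:
        value = p.cla_scale * mel
    return max(value, 0.0), b_y


def brute_force_cct(spd, tables):
    """Dense Planckian-locus scan in uv, independent of the production
    search (coarse-to-fine instead of a precomputed table)."""
    x, y, (X, Y, Z) = chromaticity(spd, tables)
    u = 4 * X / (X + 15 * Y + 3 * Z)
    v = 6 * Y / (X + 15 * Y + 3 * Z)
    best = (None, np.inf)
    lam = tables.wavelengths
    for T in np.arange(1000.0, 20001.0, 2.0):
        b = planck_spectral_irradiance(lam, T)
        Xb = float(np.sum(tables.xbar * b) * 5)
        Yb = float(np.sum(tables.ybar * b) * 5)
        Zb = float(np.sum(tables.zbar * b) * 5)
        ub = 4 * Xb / (Xb + 15 * Yb + 3 * Zb)
        vb = 6 * Yb / (Xb + 15 * Yb + 3 * Zb)
        d = (u - ub) ** 2 + (v - vb) ** 2
        if d < best[1]:
            best = (T, d)
    return best[0]


# ---------------------------------------------------------------- resample

class TestResample:
    def test_constant_spd_stays_constant_on_aligned_range(self):
        lam = np.arange(358.0, 783.0, 1.0)  # complete 5 nm bins
        out = resample_to_5nm(SPD(lam, np.full(lam.size, 3.7)))
        np.testing.assert_allclose(out.values, 3.7)
        assert out.step == 5.0
        assert np.all(out.wavelengths % 5 == 0)

    def test_energy_conservation_for_random_spd(self):
        rng = np.random.default_rng(0)
        lam = np.arange(360.0, 781.0, 1.0)
        spd = SPD(lam, rng.random(lam.size))
        out = resample_to_5nm(spd)
        assert out.total_irradiance() == pytest.approx(
            spd.total_irradiance(), rel=1e-12
        )

    def test_linear_ramp_matches_binning_oracle(self):
        lam = np.arange(360.0, 781.0, 1.0)
        spd = SPD(lam, (lam - 360.0) / 420.0)
        out = resample_to_5nm(spd)
        centers, expected = binned_means_oracle(spd)
        np.testing.assert_allclose(out.wavelengths, centers)
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_rejects_non_1nm_input(self):
        lam = np.arange(380.0, 781.0, 5.0)
        with pytest.raises(SpectralError, match="1 nm"):
            resample_to_5nm(SPD(lam, np.ones(lam.size)))


# ---------------------------------------------------------------- lux

class TestIlluminance:
    def test_zero_spd_gives_zero_lux(self, tables):
        spd = SPD(CANONICAL_WAVELENGTHS, np.zeros(81))
        assert photopic_illuminance(spd, tables) == 0.0

    def test_monochromatic_555nm_line_gives_683_lux(self, tables):
        values = np.zeros(81)
        values[CANONICAL_WAVELENGTHS == 555.0] = 1.0 / 5.0  # 1 W/m2 total
        assert photopic_illuminance(
            SPD(CANONICAL_WAVELENGTHS, values), tables
        ) == pytest.approx(683.0)

    def test_smooth_spd_matches_independent_sum_oracle(self, tables):
        spd = SPD(
            CANONICAL_WAVELENGTHS,
            planck_spectral_irradiance(CANONICAL_WAVELENGTHS, 6504.0),
        )
        expected = 0.0
        for i in range(81):  # independent rectangle sum
            expected += 683.0 * tables.V[i] * spd.values[i] * 5.0
        assert photopic_illuminance(spd, tables) == pytest.approx(
            expected, rel=1e-12
        )


# ---------------------------------------------------------------- cct

class TestCct:
    @pytest.mark.parametrize("T", [1500.0, 3000.0])
    def test_planckian_source_recovers_its_temperature(self, tables, T):
        spd = SPD(CANONICAL_WAVELENGTHS,
                  planck_spectral_irradiance(CANONICAL_WAVELENGTHS, T))
        result = cct_of_spd(spd, tables)
        assert abs(result.cct - T) <= 2.0
        assert not result.out_of_gamut

    def test_daylight_whitepoint_matches_brute_force_scan(self, tables):
        from circalight.scenes import daylight_spd

        spd = daylight_spd(6504.0, grid=CANONICAL_WAVELENGTHS, tables=tables)
        result = cct_of_spd(spd, tables)
        assert abs(result.cct - brute_force_cct(spd, tables)) <= 2.0
        assert result.cct == pytest.approx(6504.0, abs=100.0)

    def test_zero_visible_energy_is_undefined(self, tables):
        spd = SPD(CANONICAL_WAVELENGTHS, np.zeros(81))
        with pytest.raises(SpectralError, match="chromaticity"):
            cct_of_spd(spd, tables)

    def test_far_from_locus_flags_out_of_gamut(self, tables):
        values = np.zeros(81)
        values[CANONICAL_WAVELENGTHS == 530.0] = 1.0  # saturated green
        result = cct_of_spd(SPD(CANONICAL_WAVELENGTHS, values), tables)
        assert result.out_of_gamut
        assert abs(result.duv) > 0.05


# ---------------------------------------------------------------- cla / cs

class TestCla:
    def test_zero_spd(self, tables, params):
        result = cla(SPD(CANONICAL_WAVELENGTHS, np.zeros(81)), tables, params)
        assert result.value == 0.0
        assert result.branch == "melanopsin-only"
        assert result.integrals["b_minus_y"] == 0.0

    def test_long_wavelength_spd_uses_melanopsin_only_branch(
        self, tables, params
    ):
        rng = np.random.default_rng(1)
        spd = random_spd(rng, kind="red")
        result = cla(spd, tables, params)
        assert result.branch == "melanopsin-only"
        direct = params.cla_scale * float(
            np.sum(tables.Mc * spd.values) * spd.step
        )
        assert result.value == pytest.approx(direct, rel=1e-12)

    def test_incandescent_scene_matches_brute_force_model(self, tables, params):
        spd = SPD(CANONICAL_WAVELENGTHS,
                  planck_spectral_irradiance(CANONICAL_WAVELENGTHS, 2856.0))
        spd = spd.scaled(100.0 / photopic_illuminance(spd, tables))
        expected, _ = cla_oracle(spd, tables, params)
        assert cla(spd, tables, params).value == pytest.approx(expected, rel=0.01)

    def test_oracle_equivalence_on_50_random_scenes(self, tables, params):
        rng = np.random.default_rng(42)
        branches = set()
        for i in range(50):
            kind = ("broad", "red", "blue")[i % 3]
            spd = random_spd(rng, kind=kind)
            result = cla(spd, tables, params)
            expected, b_y = cla_oracle(spd, tables, params)
            assert result.value == pytest.approx(expected, rel=1e-9, abs=1e-12)
            branches.add(result.branch)
        assert branches == {"opponent", "melanopsin-only"}

    def test_grid_mismatch_rejected(self, tables, params):
        lam = np.arange(400.0, 701.0, 5.0)
        with pytest.raises(SpectralError, match="grid"):
            cla(SPD(lam, np.ones(lam.size)), tables, params)

    def test_branch_continuity_probe(self, tables, params):
        """Blend a red and a blue spectrum to cross the opponent-channel
        zero; the jump between branches at the crossing is bounded by
        the rod term's magnitude (the model's known discontinuity)."""
        rng = np.random.default_rng(5)
        red, blue = random_spd(rng, "red"), random_spd(rng, "blue")

        def at(w):
            spd = SPD(red.wavelengths, (1 - w) * red.values + w * blue.values)
            return cla(spd, tables, params), spd

        lo, hi = 0.0, 1.0
        assert at(lo)[0].branch == "melanopsin-only"
        assert at(hi)[0].branch == "opponent"
        for _ in range(40):
            mid = (lo + hi) / 2
            if at(mid)[0].branch == "opponent":
                hi = mid
            else:
                lo = mid
        below, spd_below = at(lo)
        above, _ = at(hi)
        rod_irr = below.integrals["scotopic"]
        bound = params.cla_scale * params.a_rod * (
            1.0 - math.exp(-rod_irr / params.rod_sat)
        )
        assert abs(above.value - below.value) <= bound + 1e-6


class TestCs:
    def test_anchor_values(self, params):
        assert cs(0.0, params) == 0.0
        assert cs(params.cla_half, params) == pytest.approx(0.35)
        assert cs(1e6, params) == pytest.approx(0.7, abs=1e-3)

    def test_negative_cla_rejected(self, params):
        with pytest.raises(ValueError):
            cs(-1.0, params)

    def test_strictly_increasing_and_bounded(self, params):
        grid = np.logspace(-2, 7, 200)
        values = np.array([cs(g, params) for g in grid])
        assert np.all(np.diff(values) > 0)
        assert np.all((values >= 0) & (values < params.cs_max))


# ---------------------------------------------------------------- bundle

class TestSpdToMetrics:
    def test_zero_spd_bundle(self, tables, params):
        m = spd_to_metrics(SPD(CANONICAL_WAVELENGTHS, np.zeros(81)),
                           tables, params)
        assert m.lux == 0.0
        assert m.cct is None
        assert m.cla.value == 0.0
        assert m.cs == 0.0

    def test_planckian_scene_cct(self, tables, params):
        from circalight.scenes import SCENE_WAVELENGTHS

        spd = SPD(SCENE_WAVELENGTHS,
                  planck_spectral_irradiance(SCENE_WAVELENGTHS, 3000.0))
        m = spd_to_metrics(spd, tables, params)
        assert m.cct.cct == pytest.approx(3000.0, abs=2.0)

    def test_composition_identity_on_mixed_scene(self, tables, params):
        from circalight.scenes import (
            LightSource, Scenario, mix_scene,
        )

        sc = Scenario(
            sources=((LightSource("planckian-electric", 3000.0), 1.0),),
            daylight_fraction=0.5, target_lux=400.0,
        )
        spd = mix_scene(sc, tables=tables).restrict()
        m = spd_to_metrics(spd, tables, params)
        assert m.lux == pytest.approx(photopic_illuminance(spd, tables))
        assert m.cct.cct == cct_of_spd(spd, tables).cct
        assert m.cla.value == cla(spd, tables, params).value
        assert m.cs == cs(m.cla.value, params)

    def test_scaling_increases_lux_and_cs(self, tables, params):
        rng = np.random.default_rng(9)
        for _ in range(10):
            spd = random_spd(rng, "broad")
            m1 = spd_to_metrics(spd, tables, params)
            m2 = spd_to_metrics(spd.scaled(3.0), tables, params)
            assert m2.lux > m1.lux
            assert m2.cs > m1.cs

    def test_cs_grid_invariance_for_smooth_spd(self, tables, params):
        lam1 = np.arange(360.0, 781.0, 1.0)
        spd1 = SPD(lam1, planck_spectral_irradiance(lam1, 5000.0))
        cs_1nm = spd_to_metrics(spd1, tables, params).cs
        cs_5nm = spd_to_metrics(resample_to_5nm(spd1), tables, params).cs
        assert cs_5nm == pytest.approx(cs_1nm, rel=0.01)
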