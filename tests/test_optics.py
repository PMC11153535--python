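import numpy as np
import pytest

import ivoct
from ivoct.optics import (
    ALine,
    MediumProfile,
    fluid_coefficients,
    grayscale,
    i_max,
    medium_profile,
    propagate,
    tissue_coefficients,
)

GEO = ivoct.GeometryConfig()
LUMEN_PATH_MM = GEO.vessel_inner_radius - GEO.oct_catheter_radius  # 1.55


class TestFluidCoefficients:
    def test_whole_blood_total_attenuation(self):
        assert fluid_coefficients(0.45).phi_t == pytest.approx(1.1925, abs=1e-4)

    def test_zero_haematocrit_is_transparent(self):
        c = fluid_coefficients(0.0)
        assert c.phi_a == 0.0 and c.phi_s == 0.0 and c.phi_t == 0.0

    def test_half_haematocrit(self):
        assert fluid_coefficients(0.225).phi_t == pytest.approx(0.8013, abs=1e-4)

    def test_attenuation_identity_holds_exactly(self):
        for X in np.linspace(0.0, 1.0, 11):
            c = fluid_coefficients(float(X))
            assert c.phi_t == pytest.approx(c.phi_a + c.phi_s * (1 - c.delta), rel=1e-12)


@pytest.mark.parametrize(
    "layer,phi_t,phi_b",
    [
        ("intima", 0.67, 0.73),
        ("media", 0.48, 0.69),
        ("adventitia", 0.53, 0.68),
        ("extramural", 0.50, 0.50),
    ],
)
def test_tissue_coefficients_table(layer, phi_t, phi_b):
    c = tissue_coefficients(layer)
    assert (c.phi_t, c.phi_b) == (phi_t, phi_b)


def test_unknown_tissue_layer_raises():
    with pytest.raises(KeyError):
        tissue_coefficients("epithelium")


class TestPropagate:
    def test_homogeneous_whole_blood_wall_residual(self):
        profile = medium_profile(GEO, 0.45)
        aline = propagate(profile, wall_radius_mm=2.0)
        expected = np.exp(-fluid_coefficients(0.45).phi_t * LUMEN_PATH_MM)
        assert aline.M_w == pytest.approx(expected, rel=1e-6)
        assert aline.M_w == pytest.approx(0.1575, abs=2e-4)

    def test_all_saline_lumen_constant_then_decaying(self):
        profile = medium_profile(GEO, 0.0)
        aline = propagate(profile, wall_radius_mm=2.0)
        assert aline.M_w == pytest.approx(1.0)
        lumen = aline.r < 2.0
        assert np.all(aline.M[lumen] == 1.0)
        beyond = aline.r > 2.01
        assert np.all(np.diff(aline.M[beyond]) < 0)

    def test_vacuum_profile(self):
        r = np.linspace(0.45, 5.0, 912)
        profile = MediumProfile(
            r=r,
            phi_t=np.zeros_like(r),
            phi_b=np.zeros_like(r),
            labels=np.full(r.size, "lumen", dtype=object),
            haematocrit=np.zeros_like(r),
        )
        aline = propagate(profile)
        assert np.all(aline.M == 1.0)
        assert np.all(aline.I == 0.0)

    def test_m_starts_at_one_and_is_non_increasing(self):
        profile = medium_profile(GEO, lambda r: 0.45 * (r < 1.2))
        aline = propagate(profile)
        assert aline.M[0] == 1.0
        assert np.all(np.diff(aline.M) <= 1e-15)

    def test_closed_form_agreement_with_richardson_refinement(self):
        """Homogeneous-segment attenuation matches exp(-phi_t L) to 1e-6."""
        for dr in (0.005, 0.0025):
            profile = medium_profile(GEO, 0.3, dr_mm=dr)
            aline = propagate(profile, wall_radius_mm=2.0)
            expected = np.exp(-fluid_coefficients(0.3).phi_t * LUMEN_PATH_MM)
            assert aline.M_w == pytest.approx(expected, rel=1e-6)

    def test_chaining_identity(self):
        """Splitting the path and restarting with E0' = E(r) is exact."""
        profile = medium_profile(GEO, lambda r: 0.4 * np.exp(-((r - 1.0) ** 2)))
        full = propagate(profile)
        m = 333
        head = MediumProfile(
            r=profile.r[: m + 1],
            phi_t=profile.phi_t[: m + 1],
            phi_b=profile.phi_b[: m + 1],
            labels=profile.labels[: m + 1],
            haematocrit=profile.haematocrit[: m + 1],
        )
        tail = MediumProfile(
            r=profile.r[m:],
            phi_t=profile.phi_t[m:],
            phi_b=profile.phi_b[m:],
            labels=profile.labels[m:],
            haematocrit=profile.haematocrit[m:],
        )
        part1 = propagate(head)
        part2 = propagate(tail, E0=float(part1.E[-1]))
        np.testing.assert_allclose(part2.E, full.E[m:], rtol=1e-12)

    def test_single_pass_energy_bookkeeping(self):
        """integral of phi_t e^{-tau} dr equals 1 - M(end)."""
        profile = medium_profile(GEO, 0.45)
        aline = propagate(profile)
        absorbed = np.trapezoid(profile.phi_t * aline.M, profile.r)
        assert absorbed == pytest.approx(1.0 - aline.M[-1], abs=1e-4)

    def test_non_monotone_grid_rejected(self):
        r = np.array([0.45, 0.44, 0.46])
        profile = MediumProfile(
            r=r,
            phi_t=np.zeros(3),
            phi_b=np.zeros(3),
            labels=np.full(3, "lumen", dtype=object),
            haematocrit=np.zeros(3),
        )
        with pytest.raises(ValueError):
            propagate(profile)


class TestNormalisation:
    def test_i_max_default(self):
        assert i_max(1.0) == pytest.approx(1.1925, abs=1e-4)

    def test_i_max_scales_with_e0_and_alpha(self):
        assert i_max(3.0) == pytest.approx(3.0 * i_max(1.0))
        assert i_max(1.0, alpha=0.0) == 0.0

    def test_grayscale_endpoints_and_rounding(self):
        imax = i_max(1.0)
        assert grayscale(np.array([imax]), imax)[0] == 255
        assert grayscale(np.array([0.0]), imax)[0] == 0
        # half-to-even rounding of 127.5
        assert grayscale(np.array([imax / 2.0]), imax)[0] == 128

    def test_grayscale_requires_positive_imax(self):
        with pytest.raises(ValueError):
            grayscale(np.array([0.5]), 0.0)
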