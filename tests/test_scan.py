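import numpy as np
import pytest

import ivoct
from ivoct.fixtures import make_fixture
from ivoct.scan import (
    FrameQualitySeries,
    NoTriggerError,
    cil,
    frame_mw,
    gamma,
    pullback_trigger,
    run_scan,
    scan_summary,
)

GEO = ivoct.GeometryConfig()
PROTO = ivoct.ScanProtocolConfig()


def _series(mw, spacing=0.2, length=50.0):
    mw = np.asarray(mw, dtype=float)
    return FrameQualitySeries(
        times=np.arange(mw.size) * 0.01,
        lens_z=60.0 - 0.2 * np.arange(mw.size),
        mw=mw,
        cif=mw >= 0.75,
        frame_spacing=spacing,
        pullback_length=length,
    )


class TestFrameMw:
    def test_all_saline_column(self):
        field = make_fixture("uniform", value=0.0)
        assert frame_mw(field, 30.0, GEO) == pytest.approx(1.0)

    def test_whole_blood_column(self):
        field = make_fixture("uniform", value=0.45)
        assert frame_mw(field, 30.0, GEO) == pytest.approx(0.1575, abs=2e-4)

    def test_half_haematocrit_column(self):
        field = make_fixture("uniform", value=0.225)
        assert frame_mw(field, 30.0, GEO) == pytest.approx(
            np.exp(-0.8013 * 1.55), abs=5e-4
        )

    def test_lens_outside_domain_rejected(self):
        field = make_fixture("uniform", value=0.0)
        with pytest.raises(ValueError):
            frame_mw(field, 500.0, GEO)


class TestTrigger:
    def test_first_crossing(self):
        t = np.array([0.0, 0.01, 0.02, 0.03])
        mw = np.array([0.1, 0.5, 0.8, 0.9])
        assert pullback_trigger(t, mw, 0.75) == pytest.approx(0.02)

    def test_constant_one_triggers_immediately(self):
        t = np.arange(5) * 0.01
        assert pullback_trigger(t, np.ones(5), 0.75) == 0.0

    def test_never_reached_raises_with_max(self):
        t = np.arange(5) * 0.01
        with pytest.raises(NoTriggerError) as err:
            pullback_trigger(t, np.full(5, 0.5), 0.75)
        assert err.value.max_mw == pytest.approx(0.5)

    def test_idempotent(self):
        t = np.arange(10) * 0.01
        mw = np.linspace(0.0, 1.0, 10)
        first = pullback_trigger(t, mw, 0.75)
        assert pullback_trigger(t, mw, 0.75) == first


class TestRunScan:
    def test_default_protocol_frame_geometry(self):
        field = make_fixture("uniform", value=0.0)
        series = run_scan(field, PROTO, GEO)
        assert series.n_frames == 251
        assert series.pullback_length == pytest.approx(50.0)
        spacing = np.diff(series.lens_z)
        np.testing.assert_allclose(spacing, -0.2)
        assert series.lens_z[0] == pytest.approx(60.0)
        assert series.lens_z[-1] == pytest.approx(10.0)

    def test_zero_speed_keeps_lens_stationary(self):
        proto = ivoct.ScanProtocolConfig(pullback_speed=0.0)
        field = make_fixture("uniform", value=0.0)
        series = run_scan(field, proto, GEO)
        assert np.all(series.lens_z == 60.0)

    def test_coarsest_sampling_two_endpoint_frames(self):
        proto = ivoct.ScanProtocolConfig(frame_dt=2.5)
        field = make_fixture("uniform", value=0.0)
        series = run_scan(field, proto, GEO)
        assert series.n_frames == 2
        np.testing.assert_allclose(series.lens_z, [60.0, 10.0])


class TestCil:
    def test_all_clear_capped_at_pullback_length(self):
        series = _series(np.ones(251))
        assert cil(series) == pytest.approx(50.0)

    def test_no_clear_frames(self):
        assert cil(_series(np.zeros(251))) == 0.0

    def test_alternating_pattern(self):
        mw = np.where(np.arange(251) % 2 == 0, 1.0, 0.0)
        # 126 clear frames at 0.2 mm -> 25.2, here we check the count rule
        assert cil(_series(mw)) == pytest.approx(126 * 0.2)

    def test_cil_fraction_equals_cif_fraction(self):
        rng = np.random.default_rng(3)
        mw = rng.uniform(0.0, 1.0, 251)
        series = _series(mw)
        assert cil(series) / 50.2 == pytest.approx(series.cif.mean(), rel=1e-9)


class TestGamma:
    def test_perfect_scan(self):
        g, mean, var = gamma(_series(np.ones(100)))
        assert (g, mean, var) == (1.0, 1.0, 0.0)

    def test_constant_series_closed_form(self):
        g, _, _ = gamma(_series(np.full(100, 0.6)))
        assert g == pytest.approx(0.7 * 0.6 + 0.3)

    def test_maximal_variance_bernoulli(self):
        mw = np.concatenate([np.zeros(50), np.ones(50)])
        g, mean, var = gamma(_series(mw))
        assert mean == pytest.approx(0.5)
        assert var == pytest.approx(0.25)
        assert g == pytest.approx(0.35)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            gamma(_series(np.array([])))

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            gamma(_series(np.ones(5)), f1=0.7, f2=0.4)

    def test_bounds_on_random_series(self):
        """gamma in [0,1] and variance <= 0.25 for 10,000 random series."""
        rng = np.random.default_rng(42)
        mw = rng.uniform(0.0, 1.0, size=(10000, 100))
        mean = mw.mean(axis=1)
        var = ((mw - mean[:, None]) ** 2).mean(axis=1)
        g = 0.7 * mean + 0.3 * (1.0 - var / 0.25)
        assert np.all(var <= 0.25 + 1e-15)
        assert np.all((g >= 0.0) & (g <= 1.0))
        # spot-check agreement with the implementation
        for i in range(0, 10000, 1111):
            gi, _, vi = gamma(_series(mw[i]))
            assert gi == pytest.approx(g[i], rel=1e-12)

    def test_monotone_under_raising_below_mean_value(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            mw = rng.uniform(0.0, 1.0, 40)
            g0, mean, _ = gamma(_series(mw))
            below = np.nonzero(mw < mean)[0]
            j = below[0]
            mw2 = mw.copy()
            mw2[j] = min(mw2[j] + rng.uniform(0.0, mean - mw2[j]), 1.0)
            g1, _, _ = gamma(_series(mw2))
            assert g1 >= g0 - 1e-12


class TestSummaryAndFixtures:
    def test_zero_injection_summary_sits_at_whole_blood_floor(self):
        field = make_fixture("uniform", value=0.45)
        series = run_scan(field, PROTO, GEO)
        summary = scan_summary(series, None, 0.0, PROTO, scheme="none")
        assert summary.dosage_ml == 0.0
        assert summary.mean_mw == pytest.approx(0.1575, abs=1e-3)
        assert summary.gamma == pytest.approx(0.7 * 0.1575 + 0.3, abs=1e-3)

    def test_cyclic_slugs_land_between_the_uniform_extremes(self):
        field = make_fixture("cyclic_slugs", amplitude=0.15, duty=0.5)
        series = run_scan(field, PROTO, GEO)
        summary = scan_summary(series, None, 0.0, PROTO, scheme="slugs")
        assert 0.0 < summary.cil_mm < 50.0
        lo = gamma(_series(np.full(251, 0.1575)))[0]
        hi = 1.0
        assert lo < summary.gamma < hi

    def test_series_csv_round_trip(self, tmp_path):
        import pandas as pd

        series = _series(np.linspace(0, 1, 251))
        path = tmp_path / "frames.csv"
        series.to_csv(str(path))
        back = pd.read_csv(path)
        np.testing.assert_allclose(back["M_w"], series.mw)
        assert back.shape[0] == 251
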