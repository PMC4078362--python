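import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from zoomfit.metrics import (
    FpcaCurve,
    InsufficientDataError,
    TensionTransient,
    UndefinedMetricsError,
    assemble_metric_vector,
    fpca_metrics,
    hill_linearize,
    transient_metrics,
)


def triangle_pulse():
    """Rise 0->1 kPa over [0,10] ms, linear fall 1->0 over [10,30] ms."""
    t = np.linspace(0, 30, 3001)
    f = np.where(t <= 10, t / 10, (30 - t) / 20)
    return TensionTransient(t, f)


class TestTwitchMetrics:
    def test_piecewise_linear_pulse(self):
        m = transient_metrics(triangle_pulse())
        assert m.ttp == pytest.approx(10.0)
        assert m.peak == pytest.approx(1.0)
        assert m.min == pytest.approx(0.0)
        assert m.rt50 == pytest.approx(10.0, abs=1e-6)
        assert m.rt90 == pytest.approx(18.0, abs=1e-6)

    def test_half_sine(self):
        t = np.linspace(0, 40, 40001)
        m = transient_metrics(TensionTransient(t, np.sin(np.pi * t / 40)))
        assert m.ttp == pytest.approx(20.0, abs=1e-3)
        # sin crosses 0.5 on the way down at t = 40*5/6
        assert m.rt50 == pytest.approx(40 * 5 / 6 - 20, abs=1e-3)

    def test_flat_record_rejected(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(UndefinedMetricsError):
            transient_metrics(TensionTransient(t, np.ones_like(t)))

    def test_unreached_relaxation_is_nan(self):
        t = np.linspace(0, 10, 101)
        f = np.where(t < 5, t / 5, 1.0 - 0.02 * (t - 5))  # barely relaxes
        m = transient_metrics(TensionTransient(t, f))
        assert math.isnan(m.rt50) and math.isnan(m.rt90)
        assert m.ttp == pytest.approx(5.0)

    @given(shift=st.floats(-50, 50), scale=st.floats(0.01, 100))
    def test_shift_and_scale_equivariance(self, shift, scale):
        base = triangle_pulse()
        m0 = transient_metrics(base)
        m1 = transient_metrics(TensionTransient(base.time + shift, scale * base.tension))
        assert m1.ttp == pytest.approx(m0.ttp)
        assert m1.rt50 == pytest.approx(m0.rt50)
        assert m1.rt90 == pytest.approx(m0.rt90)
        assert m1.peak == pytest.approx(scale * m0.peak)
        assert m1.min == pytest.approx(scale * m0.min)

    def test_rt50_before_rt90_for_monotone_decay(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            tau = rng.uniform(3, 30)
            t = np.linspace(0, 200, 2001)
            f = np.exp(-np.maximum(t - 10, 0) / tau) * np.minimum(t / 10, 1)
            m = transient_metrics(TensionTransient(t, f))
            assert m.rt50 <= m.rt90


class TestHillLinearization:
    def test_midpoint_maps_to_zero(self):
        pca = np.array([7.0, 6.5, 6.0, 5.5, 5.0])
        force = np.array([0.1, 0.25, 0.5, 0.8, 1.0])
        x, y = hill_linearize(FpcaCurve(pca, force))
        assert y[np.argmin(np.abs(x - 6.0))] == pytest.approx(0.0, abs=1e-12)

    def test_saturated_rows_removed(self):
        pca = np.linspace(7, 5, 10)
        force = np.linspace(0.1, 1.0, 10)
        force[-2] = 0.9995  # (1-F) = 5e-4 after normalization by max=1.0
        x, y = hill_linearize(FpcaCurve(pca, force))
        assert len(x) == 8  # top point and the 0.9995 row are gone

    def test_all_filtered_is_an_error(self):
        pca = np.linspace(7, 5, 6)
        force = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 0.0])
        with pytest.raises(InsufficientDataError):
            hill_linearize(FpcaCurve(pca, force))


class TestFpcaMetrics:
    @pytest.mark.parametrize("n", [2.0, 5.0, 12.0])
    def test_exact_hill_recovery(self, n):
        # working grid plus a saturating 10 uM point: normalization by the
        # (near-saturated) maximum distorts the slope only in O(1 - Hmax)
        ca = np.concatenate([np.geomspace(0.15, 1.0, 60), [10.0]])  # uM, Ca50 = 0.5
        F = (ca / 0.5) ** n / (1 + (ca / 0.5) ** n)
        curve = FpcaCurve(-np.log10(ca * 1e-6), F)
        m = fpca_metrics(curve)
        assert abs(m.slope) == pytest.approx(n, abs=1e-2)
        assert m.r2force > 0.999

    def test_self_target_distance_is_zero(self):
        ca = np.geomspace(0.15, 1.0, 30)
        F = (ca / 0.5) ** 5 / (1 + (ca / 0.5) ** 5)
        curve = FpcaCurve(-np.log10(ca * 1e-6), F)
        m = fpca_metrics(curve, target=curve)
        assert m.rmsd_force == pytest.approx(0.0, abs=1e-14)

    def test_known_residuals_give_rmsep(self):
        # perturbation pattern orthogonal to [1, x] so the OLS line is
        # unchanged and the residuals are exactly the added pattern
        x = np.linspace(5, 7, 8)
        y = 1.2 - 0.8 * (x - 5.0)  # keeps F comfortably inside (0, 0.999)
        r = 0.05
        y[1] += r
        y[2] -= r
        y[5] -= r
        y[6] += r
        # forces whose linearization equals y exactly: F = 10^y/(1+10^y);
        # an appended saturated point pins the normalizing maximum at 1 and
        # is itself removed by the saturation filter
        F = 10**y / (1 + 10**y)
        m = fpca_metrics(FpcaCurve(np.append(x, 4.9), np.append(F, 1.0)))
        assert m.rmsep == pytest.approx(r * np.sqrt(4 / 8), rel=1e-4)

    def test_mismatched_target_grid_regridded(self):
        ca = np.geomspace(0.15, 1.0, 30)
        F = (ca / 0.5) ** 5 / (1 + (ca / 0.5) ** 5)
        curve = FpcaCurve(-np.log10(ca * 1e-6), F)
        ca2 = np.geomspace(0.15, 1.0, 47)
        F2 = (ca2 / 0.5) ** 5 / (1 + (ca2 / 0.5) ** 5)
        target = FpcaCurve(-np.log10(ca2 * 1e-6), F2)
        with pytest.warns(UserWarning, match="re-gridding"):
            m = fpca_metrics(curve, target=target)
        assert m.rmsd_force == pytest.approx(0.0, abs=1e-3)


class TestMetricVector:
    def test_vector_shape_and_order(self, toy_target):
        v = toy_target.values
        assert len(v) == 33  # (5 twitch + 6 force-pCa metrics) x 3 lengths
        assert list(v.index[:5]) == ["RT50@0.9", "RT90@0.9", "TTP@0.9", "Peak@0.9", "Min@0.9"]

    def test_missing_metric_propagates(self):
        from zoomfit.metrics import FpcaMetrics, TwitchMetrics

        tw = {1.0: TwitchMetrics(np.nan, 12.0, 5.0, 2.0, 0.0)}
        fp = {1.0: FpcaMetrics(-5.0, 1.0, 0.0, 1.0, 10.0)}
        v = assemble_metric_vector(tw, fp)
        assert math.isnan(v["RT50@1"])
        assert v["RT90@1"] == 12.0

    def test_inconsistent_lengths_rejected(self):
        from zoomfit.metrics import FpcaMetrics, TwitchMetrics

        tw = {1.0: TwitchMetrics(1, 2, 3, 4, 0)}
        fp = {1.1: FpcaMetrics(-5, 1, 0, 1, 10)}
        with pytest.raises(ValueError, match="inconsistent"):
            assemble_metric_vector(tw, fp)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assemble_metric_vector({}, {})
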