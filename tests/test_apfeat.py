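"""AP detection/features and sparse PCA against analytic oracles."""

import numpy as np
import pandas as pd
import pytest

import patchseqkit as pk
from patchseqkit import apfeat
from patchseqkit.apfeat import APDetectParams, FeatureMatrix
from patchseqkit.synth import make_ap_template

DT = 2e-5  # 50 kHz


def trace_with_template(peak_dvdt, height=60.0, base=-70.0, n=30000, at=10000, dt=DT):
    tpl = make_ap_template(peak_dvdt, height=height, sampling_rate=1e-3 / dt)
    v = np.full(n, base)
    v[at: at + len(tpl)] += tpl
    return v


class TestDetection:
    def test_strong_template_detected_once(self):
        v = trace_with_template(40.0)
        events = apfeat.detect_aps(v, DT)
        assert len(events) == 1
        assert events[0].peak_v == pytest.approx(-10.0, abs=0.5)

    def test_slow_bump_not_detected(self):
        v = trace_with_template(10.0)
        assert apfeat.detect_aps(v, DT) == []

    def test_small_spikelet_rejected_by_height_filter(self):
        # steep (passes the dV/dt gate) but only 1 mV tall (< 2 mV min height)
        dt = 2e-6
        v = trace_with_template(40.0, height=1.0, n=20000, at=5000, dt=dt)
        assert apfeat.detect_aps(v, dt) == []

    @pytest.mark.parametrize("factor,expected", [(1.5, 1), (0.5, 0)])
    def test_detection_margin_around_threshold(self, factor, expected):
        v = trace_with_template(20.0 * factor)
        assert len(apfeat.detect_aps(v, DT)) == expected


class TestThresholdRefinement:
    def quadratic_rise(self, dt=2e-6, rise_ms=20.0, peak_dvdt=40.0):
        g = peak_dvdt / rise_ms
        t = np.arange(0.0, rise_ms, dt * 1e3)
        rise = -70.0 + 0.5 * g * t**2
        fall = np.linspace(rise[-1], -70.0, len(t) // 2)
        v = np.concatenate([np.full(2000, -70.0), rise, fall])
        peak = 2000 + len(rise) - 1
        ev = apfeat.APEvent(detect_index=2100, threshold_index=2100, peak_index=peak,
                            trough_index=len(v) - 1, threshold_v=v[2100], peak_v=v[peak])
        return v, dt, ev, peak_dvdt

    def test_refined_point_sits_at_five_percent_of_max_dvdt(self):
        v, dt, ev, m = self.quadratic_rise()
        j = apfeat.refine_threshold(ev, v, dt, avg_max_dvdt=m)
        sm = apfeat._smoothed_dvdt(v, dt, APDetectParams().smooth_samples)
        assert sm[j] / m == pytest.approx(0.05, rel=0.01)
        assert sm[j - 1] / m < 0.05

    def test_identical_aps_get_identical_relative_thresholds(self):
        v = trace_with_template(40.0)
        tpl = make_ap_template(40.0, sampling_rate=1e-3 / DT)
        v[20000: 20000 + len(tpl)] += tpl
        events = apfeat.refine_thresholds(apfeat.detect_aps(v, DT), v, DT)
        rel = [ev.peak_index - ev.threshold_index for ev in events]
        assert len(events) == 2 and rel[0] == rel[1]

    def test_threshold_rule_is_scale_invariant(self):
        v, dt, ev, m = self.quadratic_rise()
        j1 = apfeat.refine_threshold(ev, v, dt, avg_max_dvdt=m)
        v2 = -70.0 + 2.0 * (v + 70.0)
        j2 = apfeat.refine_threshold(ev, v2, dt, avg_max_dvdt=2 * m)
        assert j1 == j2


class TestShapeFeatures:
    def triangle(self, rise_ms, fall_ms, height=40.0, dt=DT, base=-70.0):
        n_r, n_f = int(rise_ms * 1e-3 / dt), int(fall_ms * 1e-3 / dt)
        v = np.concatenate([
            np.full(500, base),
            base + np.linspace(0, height, n_r, endpoint=False),
            base + np.linspace(height, 0, n_f + 1),
            np.full(500, base),
        ])
        ev = apfeat.APEvent(detect_index=500, threshold_index=500,
                            peak_index=500 + n_r, trough_index=500 + n_r + n_f,
                            threshold_v=base, peak_v=base + height)
        return v, ev

    def test_symmetric_triangle_has_unit_ratio(self):
        v, ev = self.triangle(1.0, 1.0)
        ev = apfeat.ap_shape_features(ev, v, DT)
        assert ev.upstroke_downstroke_ratio == pytest.approx(1.0, rel=1e-6)

    def test_asymmetric_triangle_geometry(self):
        """Rise 0->40 mV in 1 ms, fall in 2 ms: ratio 2, half-height width 1.5 ms."""
        v, ev = self.triangle(1.0, 2.0)
        ev = apfeat.ap_shape_features(ev, v, DT)
        assert ev.upstroke == pytest.approx(40.0, rel=1e-6)
        assert ev.downstroke == pytest.approx(-20.0, rel=1e-6)
        assert ev.upstroke_downstroke_ratio == pytest.approx(2.0, rel=1e-6)
        assert ev.width_half_height == pytest.approx(1.5, rel=1e-3)

    def test_peak_equals_window_maximum(self):
        v = trace_with_template(40.0)
        ev = apfeat.extract_aps(v, DT)[0]
        assert ev.peak_v == v[ev.threshold_index: ev.trough_index + 1].max()

    def test_ratio_invariant_to_offset_and_time_scaling(self):
        v1, e1 = self.triangle(1.0, 2.0)
        r1 = apfeat.ap_shape_features(e1, v1, DT).upstroke_downstroke_ratio
        v2, e2 = self.triangle(1.0, 2.0)
        r2 = apfeat.ap_shape_features(e2, v2 + 17.0, DT).upstroke_downstroke_ratio
        v3, e3 = self.triangle(2.0, 4.0)  # uniform time-axis stretch
        r3 = apfeat.ap_shape_features(e3, v3, DT).upstroke_downstroke_ratio
        assert r1 == pytest.approx(r2, rel=1e-9)
        assert r1 == pytest.approx(r3, rel=1e-3)


def spiking_cell_sweeps(seed=0, amplitudes=(-90.0, -50.0, -10.0, 110.0, 150.0, 190.0)):
    m = pk.MembraneSpec(rmp=-70.0, r_input=200.0, tau=20.0, spike_threshold=-50.0)
    out = {}
    for amp in amplitudes:
        ep = pk.StimulusEpoch("long_square", 0.6, 1.6, amp)
        out[amp] = pk.make_sweep(m, [ep], seed=seed, duration=2.2)
    return out


class TestFeatureMatrix:
    def test_category_layout_and_normalization(self):
        fm = pk.build_feature_matrix({"c1": spiking_cell_sweeps()})
        assert isinstance(fm, FeatureMatrix)
        e_cols = fm.categories[fm.categories == "e"]
        assert len(e_cols) == 300  # 3 steps x 100 bins of 10 ms
        d_vals = fm.values.loc["c1", fm.categories.index[fm.categories == "d"]]
        assert d_vals.max() == 1.0  # spiking step: max normalized rate bin is 1
        f_vals = fm.values.loc["c1", fm.categories.index[fm.categories == "f"]]
        assert f_vals.min() >= 0.0 and f_vals.max() <= 1.0 + 1e-9

    def test_missing_amplitude_interpolates_neighbor_mean(self):
        """Without the +40 pA sweep, its PSTH block is the neighbors' average."""
        sweeps = spiking_cell_sweeps()
        full = pk.build_feature_matrix({"c": dict(sweeps)})
        del sweeps[150.0]
        interp = pk.build_feature_matrix({"c": sweeps})
        d_cols = interp.categories.index[interp.categories == "d"]
        d = interp.values.loc["c", d_cols].to_numpy()
        rheo, mid, high = d[:50], d[50:100], d[100:150]
        np.testing.assert_allclose(mid, 0.5 * (rheo + high), atol=1e-12)
        # other categories are untouched by the missing sweep
        a_cols = full.categories.index[full.categories == "a"]
        np.testing.assert_allclose(
            full.values.loc["c", a_cols], interp.values.loc["c", a_cols]
        )

    def test_cell_without_spikes_is_dropped_with_reason(self):
        quiet = {a: s for a, s in spiking_cell_sweeps().items() if a < 0}
        quiet_and_good = {"bad": quiet, "good": spiking_cell_sweeps()}
        fm = pk.build_feature_matrix(quiet_and_good)
        assert list(fm.values.index) == ["good"]
        assert "rheobase" in fm.dropped["bad"]

    def test_construction_is_deterministic(self):
        a = pk.build_feature_matrix({"c": spiking_cell_sweeps()})
        b = pk.build_feature_matrix({"c": spiking_cell_sweeps()})
        pd.testing.assert_frame_equal(a.values, b.values)


def dense_pca(X):
    """Eigendecomposition oracle: loadings of column-centered X."""
    Xc = X - X.mean(axis=0)
    w, V = np.linalg.eigh(Xc.T @ Xc)
    order = np.argsort(w)[::-1]
    return w[order] / np.sum(Xc * Xc), V[:, order]


class TestSparsePCA:
    def make_fm(self, X, cat="a"):
        cols = [f"{cat}_{i:03d}" for i in range(X.shape[1])]
        return FeatureMatrix(
            values=pd.DataFrame(X, columns=cols),
            categories=pd.Series(cat, index=cols),
        )

    def test_zero_penalty_matches_dense_pca(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 6)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.3, 0.1])
        res = pk.sparse_pca(self.make_fm(X), penalty=0.0, retention=0.01)
        ev_frac, V = dense_pca(X)
        for j in range(3):
            cos = abs(res.loadings["a"][:, j] @ V[:, j])
            assert cos == pytest.approx(1.0, abs=1e-6)
            assert res.adjusted_ev["a"][j] == pytest.approx(ev_frac[j], rel=1e-6)

    def test_noise_data_has_bounded_adjusted_ev(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 30))
        res = pk.sparse_pca(self.make_fm(X), penalty=0.5, retention=0.01)
        ev = res.adjusted_ev["a"]
        assert (ev >= -1e-12).all() and ev.sum() <= 1.0 + 1e-9
        assert ev.max() < 0.5  # no dominant direction in iid noise

    def test_planted_direction_is_recovered(self):
        rng = np.random.default_rng(6)
        direction = np.zeros(20)
        direction[:4] = 0.5
        scores = rng.normal(scale=10.0, size=(50, 1))
        X = scores @ direction[None, :] + rng.normal(scale=0.4, size=(50, 20))
        res = pk.sparse_pca(self.make_fm(X), penalty=0.2, retention=0.01)
        lead = res.loadings["a"][:, 0]
        assert abs(lead @ direction / np.linalg.norm(direction)) > 0.95
        assert res.kept["a"][0]

    def test_kept_scores_are_z_scored(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 12))
        res = pk.sparse_pca(self.make_fm(X), penalty=0.0)
        Z = res.scores.to_numpy()
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, rtol=1e-9)

    def test_single_cell_raises(self):
        with pytest.raises(ValueError):
            pk.sparse_pca(self.make_fm(np.ones((1, 4))))
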