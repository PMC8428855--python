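"""Sweep-QC rules: baseline, recovery, autobias, set logic, inclusion."""

import numpy as np
import pytest

import patchseqkit as pk
from patchseqkit.sweepqc import QCConfig, StimulusSetResult, SweepMeta

CFG = QCConfig()  # target -70 mV, 1 mV tolerance, 0.07/0.5 mV RMS


def flat_sweep(level, dt=1e-4, dur=0.6, epochs=()):
    n = int(round(dur / dt))
    return pk.VoltageSweep(0.0, dt, np.full(n, float(level)), np.zeros(n), list(epochs))


class TestBaseline:
    def test_constant_at_target_passes(self):
        v = pk.evaluate_baseline(flat_sweep(CFG.target_vm), CFG)
        assert v.passed and v.measured["rmp"] == CFG.target_vm

    def test_offset_twice_tolerance_fails_rmp(self):
        v = pk.evaluate_baseline(flat_sweep(CFG.target_vm + 2 * CFG.rmp_tolerance), CFG)
        assert not v.passed and v.reasons == ["rmp_out_of_range"]

    def test_square_wave_rms_matches_direct_formula(self):
        """A ±a square wave has RMS exactly a; a = 2x the limit must fail."""
        a = 2 * CFG.rms_long_max
        sweep = flat_sweep(CFG.target_vm, dt=1e-4)
        n = int(round(CFG.baseline_window * 1e-3 / 1e-4))
        half = n // 2
        sweep.voltage[:half] += a
        sweep.voltage[half:n] -= a
        v = pk.evaluate_baseline(sweep, CFG)
        assert v.measured["rms_long"] == pytest.approx(a, rel=1e-9)
        assert "rms_long" in v.reasons

    def test_pass_region_is_product_of_criteria(self):
        """Scanning offset x noise grids traces the rectangular boundary."""
        rng = np.random.default_rng(0)
        for offset in (0.0, 0.9, 1.1):
            for noise in (0.0, 0.3, 0.6):
                sweep = flat_sweep(CFG.target_vm + offset, dt=1e-4)
                wave = noise * np.sign(rng.normal(size=len(sweep.voltage)))
                sweep.voltage += wave - wave.mean()
                v = pk.evaluate_baseline(sweep, CFG)
                expected = (
                    offset <= CFG.rmp_tolerance
                    and v.measured["rms_short"] < CFG.rms_short_max
                    and v.measured["rms_long"] < CFG.rms_long_max
                )
                assert v.passed == expected

    def test_insufficient_pre_stimulus_data_raises(self):
        short = flat_sweep(CFG.target_vm, dt=1e-4, dur=0.2,
                           epochs=[pk.StimulusEpoch("long_square", 0.1, 0.2, 10.0)])
        with pytest.raises(ValueError):
            pk.evaluate_baseline(short, CFG)


class TestRecovery:
    def test_immediate_recovery_passes_after_min_plus_eval(self):
        sweep = flat_sweep(CFG.target_vm, dt=1e-3, dur=12.0)
        v = pk.evaluate_recovery(sweep, stim_end=1.0, cfg=CFG)
        assert v.passed
        assert v.measured["pass_time"] == pytest.approx(1.0 + 0.5 + 0.5)

    def test_persistent_offset_exhausts_ten_seconds(self):
        sweep = flat_sweep(CFG.target_vm + 5.0, dt=1e-3, dur=12.0)
        v = pk.evaluate_recovery(sweep, stim_end=1.0, cfg=CFG)
        assert not v.passed and v.reasons == ["no_recovery"]

    def test_late_recovery_passes_at_next_window_edge(self):
        """Recovery at stim_end+2.3 s passes in window [2.5, 3.0] s."""
        sweep = flat_sweep(CFG.target_vm + 5.0, dt=1e-3, dur=12.0)
        stim_end = 1.0
        sweep.voltage[int((stim_end + 2.3) / 1e-3):] = CFG.target_vm
        v = pk.evaluate_recovery(sweep, stim_end=stim_end, cfg=CFG)
        assert v.passed
        assert v.measured["pass_time"] == pytest.approx(stim_end + 3.0)

    def test_pass_time_is_multiple_of_eval_window(self):
        for delay in (0.0, 0.7, 1.2, 3.9):
            sweep = flat_sweep(CFG.target_vm + 5.0, dt=1e-3, dur=12.0)
            sweep.voltage[int((1.0 + delay) / 1e-3):] = CFG.target_vm
            v = pk.evaluate_recovery(sweep, stim_end=1.0, cfg=CFG)
            assert v.passed
            k = (v.measured["pass_time"] - 1.0 - 0.5) / 0.5
            assert k == pytest.approx(round(k))
            assert v.measured["pass_time"] <= 1.0 + CFG.recovery_max

    def test_stim_end_outside_sweep_raises(self):
        with pytest.raises(ValueError):
            pk.evaluate_recovery(flat_sweep(-70, dur=1.0), stim_end=5.0, cfg=CFG)


class TestAutobias:
    def test_at_target_no_adjustment(self):
        meta = SweepMeta(input_resistance=100.0)
        assert pk.autobias_step(CFG.target_vm, CFG, meta) == 0.0

    def test_ohms_law_gain(self):
        """2 mV above target with 100 MΩ input resistance -> -20 pA."""
        meta = SweepMeta(input_resistance=100.0)
        assert pk.autobias_step(CFG.target_vm + 2.0, CFG, meta) == pytest.approx(-20.0)

    def test_large_deviation_is_clipped(self):
        cfg = QCConfig(autobias_max_step=50.0)
        meta = SweepMeta(input_resistance=100.0)
        assert pk.autobias_step(cfg.target_vm + 50.0, cfg, meta) == -50.0

    def test_zero_input_resistance_raises(self):
        with pytest.raises(ValueError):
            pk.autobias_step(-70.0, CFG, SweepMeta(input_resistance=0.0))


class TestOnlineDetection:
    def make_trace(self, peak_dvdt, n_spikes=1, spacing_ms=50.0, dt=2e-5):
        v = np.full(int(0.5 / dt), -70.0)
        dt_ms = dt * 1e3
        rise = np.arange(1, 151) * peak_dvdt * dt_ms
        fall = rise[-1] - np.arange(1, 301) * 0.5 * peak_dvdt * dt_ms
        tpl = np.concatenate([rise, fall])
        for k in range(n_spikes):
            start = 2000 + int(k * spacing_ms * 1e-3 / dt)
            v[start: start + len(tpl)] += tpl
        return v, dt

    def test_template_above_threshold_gives_one_event(self):
        v, dt = self.make_trace(peak_dvdt=40.0)
        assert len(pk.detect_spikes_online(v, dt, threshold_dvdt=20.0)) == 1

    def test_template_below_threshold_gives_none(self):
        v, dt = self.make_trace(peak_dvdt=10.0)
        assert len(pk.detect_spikes_online(v, dt, threshold_dvdt=20.0)) == 0

    def test_two_templates_in_order(self):
        v, dt = self.make_trace(peak_dvdt=40.0, n_spikes=2)
        ev = pk.detect_spikes_online(v, dt, threshold_dvdt=20.0)
        assert len(ev) == 2 and ev[0] < ev[1]

    def test_event_count_monotone_in_threshold(self):
        v, dt = self.make_trace(peak_dvdt=40.0, n_spikes=3)
        counts = [len(pk.detect_spikes_online(v, dt, threshold_dvdt=th))
                  for th in (5.0, 15.0, 25.0, 45.0)]
        assert counts == sorted(counts, reverse=True)


class TestStimulusSet:
    def responder(self, fail_first=0):
        """Constant-at-target responder that fails (offset) the first k calls."""
        calls = {"n": 0}

        def respond(epochs, tail):
            calls["n"] += 1
            dur = max(ep.offset for ep in epochs) + tail
            n = int(round(dur / 1e-3))
            level = CFG.target_vm + (5.0 if calls["n"] <= fail_first else 0.0)
            return pk.VoltageSweep(0.0, 1e-3, np.full(n, level), np.zeros(n), list(epochs))

        respond.calls = calls
        return respond

    TEMPLATES = [pk.StimulusEpoch("long_square", 0.6, 1.6, 50.0) for _ in range(3)]

    def test_always_passing_responder_has_zero_repeats(self):
        res = pk.run_stimulus_set(self.responder(), self.TEMPLATES, CFG)
        assert isinstance(res, StimulusSetResult)
        assert len(res.passed_sweeps) == 3 and res.failed_attempts == 0 and not res.aborted

    def test_always_failing_responder_aborts_by_counting_rule(self):
        res = pk.run_stimulus_set(self.responder(fail_first=99), self.TEMPLATES, CFG)
        assert res.aborted
        # abort exactly when remaining required (3) + failures > allotted (6)
        assert res.failed_attempts == 4 and len(res.passed_sweeps) == 0

    def test_one_transient_failure_adds_one_sweep(self):
        responder = self.responder(fail_first=1)
        res = pk.run_stimulus_set(responder, self.TEMPLATES, CFG)
        assert not res.aborted and len(res.passed_sweeps) == 3
        assert responder.calls["n"] == len(self.TEMPLATES) + 1

    def test_deterministic_ramp_termination_records_spike_limit(self):
        m = pk.MembraneSpec(rmp=CFG.target_vm, r_input=100.0, tau=20.0,
                            spike_threshold=-50.0)
        ramp = pk.StimulusEpoch("ramp", 0.6, 20.6, 25.0)

        def respond(epochs, tail):
            dur = max(ep.offset for ep in epochs) + tail
            return pk.make_sweep(m, epochs, duration=dur)

        res = pk.run_stimulus_set(respond, [ramp], CFG)
        assert not res.aborted and len(res.passed_sweeps) == 1
        sweep = res.passed_sweeps[0]
        ep = sweep.epochs[0]
        assert ep.offset < ramp.offset  # stimulus terminated online
        seg = sweep.voltage[sweep.index_at(ep.onset): sweep.index_at(ep.offset)]
        spikes = pk.detect_spikes_online(seg, sweep.dt, CFG.spike_dvdt_threshold)
        assert len(spikes) == CFG.ramp_spike_limit

        repeat = pk.run_stimulus_set(respond, [ramp], CFG)
        np.testing.assert_array_equal(sweep.voltage, repeat.passed_sweeps[0].voltage)


class TestInclusion:
    BASE = pk.evaluate_baseline(flat_sweep(CFG.target_vm), CFG)

    def test_bridge_absolute_bound(self):
        meta = SweepMeta(bridge_balance=25.0, bias_current=0.0, input_resistance=500.0)
        v = pk.sweep_inclusion(meta, self.BASE, CFG)
        assert not v.passed and "bridge_abs" in v.reasons

    def test_leak_bound(self):
        meta = SweepMeta(bridge_balance=5.0, bias_current=-120.0, input_resistance=500.0)
        v = pk.sweep_inclusion(meta, self.BASE, CFG)
        assert not v.passed and "leak" in v.reasons

    def test_bridge_fractional_bound(self):
        """10 MΩ bridge on 50 MΩ input resistance is 20% > 15% -> fail."""
        meta = SweepMeta(bridge_balance=10.0, bias_current=0.0, input_resistance=50.0)
        v = pk.sweep_inclusion(meta, self.BASE, CFG)
        assert not v.passed and v.reasons == ["bridge_frac"]

    def test_missing_metadata_raises(self):
        with pytest.raises(ValueError):
            pk.sweep_inclusion(SweepMeta(bridge_balance=5.0), self.BASE, CFG)

    @pytest.mark.parametrize(
        "seal,ra,rin,ok",
        [
            (1.5, 10.0, 150.0, True),   # 6.7% < 15%
            (0.8, 10.0, 150.0, False),  # seal below 1 GΩ
            (1.5, 18.0, 100.0, False),  # 18% > 15%
        ],
    )
    def test_cell_inclusion_rules(self, seal, ra, rin, ok):
        meta = SweepMeta(seal_pre_breakin=seal, access_resistance=ra, input_resistance=rin)
        assert pk.cell_inclusion(meta, CFG).passed is ok
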