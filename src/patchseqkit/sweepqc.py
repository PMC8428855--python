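"""Online current-clamp sweep quality control.

Replicates the acquisition-time analysis used in scaled Patch-seq
recording: a pre-stimulus baseline evaluation (resting membrane
potential held within a tolerance of the target, plus short- and
long-window RMS noise criteria), a post-stimulus recovery assay that
ends the sweep as soon as the membrane potential returns to baseline,
an autobias current controller, online spike detection that terminates
a ramp stimulus after a fixed number of action potentials, the
stimulus-set repeat/abort bookkeeping, and the per-sweep / per-cell
inclusion criteria (bridge balance, bias current, seal and access
resistance).

All voltages are mV, currents pA, resistances MΩ (seal GΩ), times in
seconds unless a config field says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StimulusEpoch",
    "VoltageSweep",
    "QCConfig",
    "SweepMeta",
    "QCVerdict",
    "StimulusSetResult",
    "evaluate_baseline",
    "evaluate_recovery",
    "autobias_step",
    "detect_spikes_online",
    "run_stimulus_set",
    "sweep_inclusion",
    "cell_inclusion",
]


@dataclass(frozen=True)
class StimulusEpoch:
    """One stimulus segment: a brief pulse, a 1 s square step, or a slow ramp.

    ``amplitude`` is pA for pulses/steps and the slope in pA/s for ramps
    (the standard slow ramp rises at 25 pA/s).
    """

    kind: str  # short_pulse | long_square | ramp
    onset: float  # s
    offset: float  # s
    amplitude: float  # pA, or pA/s for ramp

    def __post_init__(self) -> None:
        if self.kind not in ("short_pulse", "long_square", "ramp"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.offset <= self.onset:
            raise ValueError("epoch offset must exceed onset")


@dataclass
class VoltageSweep:
    """A uniformly sampled voltage/stimulus trace with epoch markers."""

    start_time: float  # s
    dt: float  # s
    voltage: np.ndarray  # mV
    stimulus: np.ndarray  # pA
    epochs: list[StimulusEpoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.stimulus = np.asarray(self.stimulus, dtype=float)
        if self.voltage.shape != self.stimulus.shape:
            raise ValueError("voltage and stimulus must have the same length")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        end = self.start_time + self.duration
        for ep in self.epochs:
            if ep.onset < self.start_time - 1e-12 or ep.offset > end + 1e-12:
                raise ValueError("epoch lies outside the sweep")

    @property
    def duration(self) -> float:
        return len(self.voltage) * self.dt

    @property
    def time(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.voltage)) * self.dt

    def index_at(self, t: float) -> int:
        return int(round((t - self.start_time) / self.dt))


@dataclass(frozen=True)
class QCConfig:
    """Acquisition QC thresholds.

    Defaults are the operating constants of the scaled protocol: RMP held
    within 1 mV of target over a 500 ms baseline window; RMS noise under
    0.07 mV in 1.5 ms sub-windows and under 0.5 mV over the full window;
    a 500 ms minimal recovery followed by 500 ms evaluation periods out
    to 10 s; ramp termination after 5 detected spikes; bias current
    within ±100 pA; bridge balance < 20 MΩ and < 15% of the input
    resistance; seal > 1 GΩ before break-in; access resistance < 20 MΩ
    and < 15% of the input resistance.
    """

    target_vm: float = -70.0  # mV
    rmp_tolerance: float = 1.0  # mV
    baseline_window: float = 500.0  # ms
    rms_short_window: float = 1.5  # ms
    rms_short_max: float = 0.07  # mV
    rms_long_window: float = 500.0  # ms
    rms_long_max: float = 0.5  # mV
    recovery_min: float = 500.0  # ms
    recovery_eval: float = 500.0  # ms
    recovery_max: float = 10.0  # s, past stimulus end
    ramp_spike_limit: int = 5
    spike_dvdt_threshold: float = 20.0  # mV/ms, online detection
    leak_limit: float = 100.0  # pA
    bridge_abs_max: float = 20.0  # MΩ
    bridge_frac_max: float = 0.15
    access_abs_max: float = 20.0  # MΩ
    access_frac_max: float = 0.15
    seal_min: float = 1.0  # GΩ
    autobias_max_step: float = 100.0  # pA
    smooth_samples: int = 5  # causal boxcar for online dV/dt


@dataclass(frozen=True)
class SweepMeta:
    bridge_balance: float | None = None  # MΩ
    bias_current: float | None = None  # pA
    seal_pre_breakin: float | None = None  # GΩ
    access_resistance: float | None = None  # MΩ
    input_resistance: float | None = None  # MΩ


@dataclass
class QCVerdict:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    measured: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


def _rms(x: np.ndarray) -> float:
    x = x - x.mean()
    return float(np.sqrt(np.mean(x * x)))


def _rms_metrics(window: np.ndarray, dt_s: float, cfg: QCConfig) -> tuple[float, float]:
    """(short, long) RMS metrics on one evaluation window.

    Long metric: RMS of the mean-subtracted window.  Short metric: the
    maximum RMS over non-overlapping ``rms_short_window`` sub-windows,
    each individually mean-subtracted — sensitive to high-frequency
    noise that a full-window mean would absorb.
    """
    rms_long = _rms(window)
    n_sub = max(1, int(round(cfg.rms_short_window * 1e-3 / dt_s)))
    n_full = (len(window) // n_sub) * n_sub
    subs = window[:n_full].reshape(-1, n_sub)
    rms_short = max(_rms(s) for s in subs) if len(subs) else _rms(window)
    return rms_short, rms_long


def evaluate_baseline(sweep: VoltageSweep, cfg: QCConfig = QCConfig()) -> QCVerdict:
    """Pre-stimulus baseline check: RMP within tolerance, RMS noise within bounds.

    The baseline window is the ``cfg.baseline_window`` ms immediately
    preceding the first stimulus epoch (or the start of the sweep when
    no epoch is declared).  Passing requires the window mean within
    ``rmp_tolerance`` of ``target_vm`` (inclusive) and both RMS metrics
    strictly below their limits.  Measured values are always reported.
    """
    n_base = int(round(cfg.baseline_window * 1e-3 / sweep.dt))
    if sweep.epochs:
        stop = sweep.index_at(min(ep.onset for ep in sweep.epochs))
    else:
        stop = min(n_base, len(sweep.voltage))
    start = stop - n_base
    if start < 0 or stop > len(sweep.voltage) or n_base < 2:
        raise ValueError("sweep has insufficient pre-stimulus data for the baseline window")
    window = sweep.voltage[start:stop]

    rmp = float(window.mean())
    rms_short, rms_long = _rms_metrics(window, sweep.dt, cfg)

    reasons = []
    if abs(rmp - cfg.target_vm) > cfg.rmp_tolerance:
        reasons.append("rmp_out_of_range")
    if not rms_short < cfg.rms_short_max:
        reasons.append("rms_short")
    if not rms_long < cfg.rms_long_max:
        reasons.append("rms_long")
    measured = {"rmp": rmp, "rms_short": rms_short, "rms_long": rms_long}
    return QCVerdict(passed=not reasons, reasons=reasons, measured=measured)


def evaluate_recovery(
    sweep: VoltageSweep, stim_end: float, cfg: QCConfig = QCConfig()
) -> QCVerdict:
    """Post-stimulus recovery assay.

    After a mandatory ``recovery_min`` ms quiet period, consecutive
    non-overlapping ``recovery_eval`` ms windows are assayed; the first
    window whose mean is within ``rmp_tolerance`` of the target (and
    whose RMS metrics pass) ends the sweep, with ``pass_time`` the end
    of that window.  If no window passes before ``stim_end +
    recovery_max`` the sweep fails.
    """
    end_time = sweep.start_time + sweep.duration
    if not (sweep.start_time <= stim_end <= end_time):
        raise ValueError("stim_end lies outside the sweep")
    if end_time - stim_end < cfg.recovery_min * 1e-3:
        raise ValueError("sweep does not extend past the minimal recovery period")

    t0 = stim_end + cfg.recovery_min * 1e-3
    eval_s = cfg.recovery_eval * 1e-3
    deadline = stim_end + cfg.recovery_max
    measured: dict[str, float] = {}
    k = 0
    while True:
        w_start, w_end = t0 + k * eval_s, t0 + (k + 1) * eval_s
        if w_end > deadline + 1e-12 or w_end > end_time + 1e-12:
            break
        window = sweep.voltage[sweep.index_at(w_start): sweep.index_at(w_end)]
        rmp = float(window.mean())
        rms_short, rms_long = _rms_metrics(window, sweep.dt, cfg)
        measured = {"rmp": rmp, "rms_short": rms_short, "rms_long": rms_long}
        if (
            abs(rmp - cfg.target_vm) <= cfg.rmp_tolerance
            and rms_short < cfg.rms_short_max
            and rms_long < cfg.rms_long_max
        ):
            measured["pass_time"] = w_end
            return QCVerdict(passed=True, measured=measured)
        k += 1
    return QCVerdict(passed=False, reasons=["no_recovery"], measured=measured)


def autobias_step(
    measured_rmp: float, cfg: QCConfig = QCConfig(), meta: SweepMeta = SweepMeta()
) -> float:
    """Inter-sweep bias-current adjustment in pA.

    Ohm's-law controller: ΔI = (target − measured) / R_input, clipped to
    ``cfg.autobias_max_step``.  mV / MΩ = nA, hence the factor 1000.
    """
    r_in = meta.input_resistance
    if r_in is None or r_in <= 0:
        raise ValueError("autobias requires a positive input resistance")
    delta = (cfg.target_vm - measured_rmp) / r_in * 1000.0
    return float(np.clip(delta, -cfg.autobias_max_step, cfg.autobias_max_step))


def detect_spikes_online(
    voltage: np.ndarray, dt: float, threshold_dvdt: float = 20.0, smooth_samples: int = 5
) -> np.ndarray:
    """Causal online spike detection: indices where smoothed dV/dt crosses threshold.

    The derivative (mV/ms) is smoothed with a causal boxcar of
    ``smooth_samples`` so the detector only uses past samples, as an
    acquisition system must.  Returns indices of upward crossings of
    ``threshold_dvdt``; the event count is non-increasing in the
    threshold.
    """
    v = np.asarray(voltage, dtype=float)
    if len(v) < 3:
        return np.array([], dtype=int)
    dvdt = np.diff(v) / (dt * 1e3)  # mV/ms
    kernel = np.ones(smooth_samples) / smooth_samples
    smoothed = np.convolve(dvdt, kernel)[: len(dvdt)]  # causal: lags, never leads
    above = smoothed >= threshold_dvdt
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate(([0], crossings))
    return crossings + 1  # derivative index i reflects v[i+1] - v[i]


@dataclass
class StimulusSetResult:
    passed_sweeps: list[VoltageSweep]
    failed_attempts: int
    aborted: bool
    verdicts: list[QCVerdict] = field(default_factory=list)


def run_stimulus_set(
    cell: Callable[[list[StimulusEpoch], float], VoltageSweep],
    sweeps: Sequence[StimulusEpoch],
    cfg: QCConfig = QCConfig(),
    max_repeats: int | None = None,
) -> StimulusSetResult:
    """Acquire a stimulus set with online QC, repeats, and the abort rule.

    ``cell`` is a responder callable: given an epoch list and a
    post-stimulus tail duration (s) it returns the recorded
    ``VoltageSweep``.  Each template sweep must pass baseline and
    recovery evaluation; a failing sweep is repeated.  Acquisition
    aborts exactly when the remaining required passes plus the
    accumulated failures exceed the total allotted sweeps
    (``len(sweeps) + max_repeats``; ``max_repeats`` defaults to the
    template count, i.e. each sweep may fail once on average).

    A ramp epoch is handled online: the stimulus is terminated as soon
    as ``cfg.ramp_spike_limit`` spikes are detected, and recording
    continues through the recovery assay.
    """
    templates = list(sweeps)
    if not templates:
        raise ValueError("stimulus set must contain at least one sweep template")
    required = len(templates)
    if max_repeats is None:
        max_repeats = required
    total_allotted = required + max_repeats

    passed: list[VoltageSweep] = []
    verdicts: list[QCVerdict] = []
    failures = 0
    for template in templates:
        while True:
            remaining = required - len(passed)
            if remaining + failures > total_allotted:
                return StimulusSetResult(passed, failures, aborted=True, verdicts=verdicts)
            sweep = _acquire(cell, template, cfg)
            verdict = evaluate_baseline(sweep, cfg)
            if verdict.passed:
                stim_end = max(ep.offset for ep in sweep.epochs)
                rec = evaluate_recovery(sweep, stim_end, cfg)
                verdict.measured.update(rec.measured)
                if not rec.passed:
                    verdict = QCVerdict(False, verdict.reasons + rec.reasons, verdict.measured)
            verdicts.append(verdict)
            if verdict.passed:
                passed.append(sweep)
                break
            failures += 1
    remaining = required - len(passed)
    aborted = remaining + failures > total_allotted
    return StimulusSetResult(passed, failures, aborted=aborted, verdicts=verdicts)


def _acquire(cell, template: StimulusEpoch, cfg: QCConfig) -> VoltageSweep:
    """Acquire one sweep, terminating a ramp online at the spike limit."""
    tail = cfg.recovery_max + cfg.recovery_eval * 1e-3
    if template.kind != "ramp":
        return cell([template], tail)
    # Dry run the full ramp, find the ramp_spike_limit-th detected spike,
    # then record with the stimulus cut at that time.
    probe = cell([template], tail)
    i0, i1 = probe.index_at(template.onset), probe.index_at(template.offset)
    events = detect_spikes_online(
        probe.voltage[i0:i1], probe.dt, cfg.spike_dvdt_threshold, cfg.smooth_samples
    )
    if len(events) < cfg.ramp_spike_limit:
        return probe
    cut_index = int(events[cfg.ramp_spike_limit - 1]) + 1  # terminate just past detection
    cut_time = template.onset + cut_index * probe.dt
    truncated = replace(template, offset=cut_time)
    return cell([truncated], tail)


def sweep_inclusion(
    meta: SweepMeta, baseline: QCVerdict, cfg: QCConfig = QCConfig()
) -> QCVerdict:
    """Per-sweep inclusion: bridge balance, bias current, and RMS criteria."""
    for name in ("bridge_balance", "bias_current", "input_resistance"):
        if getattr(meta, name) is None:
            raise ValueError(f"sweep metadata field {name!r} is missing")
    reasons = []
    if not meta.bridge_balance < cfg.bridge_abs_max:
        reasons.append("bridge_abs")
    if not meta.bridge_balance < cfg.bridge_frac_max * meta.input_resistance:
        reasons.append("bridge_frac")
    if abs(meta.bias_current) > cfg.leak_limit:
        reasons.append("leak")
    for r in ("rms_short", "rms_long"):
        if r in baseline.reasons:
            reasons.append(r)
    measured = dict(baseline.measured)
    measured.update(bridge_balance=meta.bridge_balance, bias_current=meta.bias_current)
    return QCVerdict(passed=not reasons, reasons=reasons, measured=measured)


def cell_inclusion(meta: SweepMeta, cfg: QCConfig = QCConfig()) -> QCVerdict:
    """Per-cell inclusion: seal before break-in and initial access resistance."""
    for name in ("seal_pre_breakin", "access_resistance", "input_resistance"):
        if getattr(meta, name) is None:
            raise ValueError(f"cell metadata field {name!r} is missing")
    reasons = []
    if not meta.seal_pre_breakin > cfg.seal_min:
        reasons.append("seal")
    if not meta.access_resistance < cfg.access_abs_max:
        reasons.append("access_abs")
    if not meta.access_resistance < cfg.access_frac_max * meta.input_resistance:
        reasons.append("access_frac")
    measured = {
        "seal_pre_breakin": meta.seal_pre_breakin,
        "access_resistance": meta.access_resistance,
        "input_resistance": meta.input_resistance,
    }
    return QCVerdict(passed=not reasons, reasons=reasons, measured=measured)
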