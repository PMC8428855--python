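"""Offline action-potential detection, shape features, and sparse PCA.

Detection finds samples where the smoothed derivative of the membrane
potential exceeds a threshold (default 20 mV/ms) and refines candidates
by threshold-to-peak height, time-to-peak and absolute peak height.
The AP threshold is then adjusted to where dV/dt reaches 5% of the
average maximal dV/dt across the sweep's APs.  Per-AP features (peak,
width at half-height, upstroke/downstroke ratio) feed six categories
of per-cell feature vectors — first-AP waveform, its derivative,
normalized interspike-interval shape, binned firing-rate (PSTH)
features at rheobase/+40/+80 pA, binned subthreshold responses, and
the largest hyperpolarizing step — which are reduced per category by
sparse PCA, keeping components whose adjusted explained variance
exceeds 1%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sweepqc import VoltageSweep

__all__ = [
    "APDetectParams",
    "APEvent",
    "FeatureConfig",
    "FeatureMatrix",
    "SparsePCResult",
    "detect_aps",
    "refine_thresholds",
    "refine_threshold",
    "ap_shape_features",
    "extract_aps",
    "build_feature_matrix",
    "sparse_pca",
]

log = logging.getLogger(__name__)

CATEGORIES = ("a", "b", "c", "d", "e", "f")


@dataclass(frozen=True)
class APDetectParams:
    dvdt_threshold: float = 20.0  # mV/ms
    min_height: float = 2.0  # mV, threshold-to-peak
    max_interval: float = 5.0  # ms, threshold-to-peak
    min_peak: float = -30.0  # mV, absolute
    smooth_samples: int = 5  # centered boxcar on the derivative
    threshold_fraction: float = 0.05  # of average maximal dV/dt


@dataclass
class APEvent:
    detect_index: int
    threshold_index: int
    peak_index: int
    trough_index: int
    threshold_v: float
    peak_v: float
    width_half_height: float | None = None  # ms
    upstroke: float | None = None  # mV/ms
    downstroke: float | None = None  # mV/ms
    upstroke_downstroke_ratio: float | None = None


def _smoothed_dvdt(voltage: np.ndarray, dt: float, smooth_samples: int) -> np.ndarray:
    """Centered-boxcar-smoothed derivative in mV/ms."""
    dvdt = np.gradient(np.asarray(voltage, dtype=float)) / (dt * 1e3)
    if smooth_samples <= 1:
        return dvdt
    kernel = np.ones(smooth_samples) / smooth_samples
    return np.convolve(dvdt, kernel, mode="same")


def detect_aps(
    voltage: np.ndarray, dt: float, params: APDetectParams = APDetectParams()
) -> list[APEvent]:
    """Detect APs by smoothed-dV/dt crossings with refinement filters.

    Candidates where the smoothed derivative reaches
    ``params.dvdt_threshold`` are kept only if the threshold-to-peak
    height is at least ``min_height``, the time to peak at most
    ``max_interval`` and the absolute peak at least ``min_peak``.
    Events are ordered and non-overlapping; an empty list is fine.
    """
    v = np.asarray(voltage, dtype=float)
    if len(v) < 3:
        return []
    sm = _smoothed_dvdt(v, dt, params.smooth_samples)
    above = sm >= params.dvdt_threshold
    crossings = list(np.flatnonzero(above[1:] & ~above[:-1]) + 1)
    if above[0]:
        crossings.insert(0, 0)

    max_ahead = max(1, int(round(params.max_interval * 1e-3 / dt)))
    events: list[APEvent] = []
    last_end = -1
    for idx in crossings:
        if idx <= last_end:
            continue
        stop = min(idx + max_ahead + 1, len(v))
        peak = idx + int(np.argmax(v[idx:stop]))
        if v[peak] - v[idx] < params.min_height:
            continue
        if v[peak] < params.min_peak:
            continue
        events.append(
            APEvent(
                detect_index=idx,
                threshold_index=idx,
                peak_index=peak,
                trough_index=peak,  # placeholder, fixed below
                threshold_v=v[idx],
                peak_v=v[peak],
            )
        )
        last_end = peak
    # trough: minimum between this peak and the next event (or trace end)
    for k, ev in enumerate(events):
        stop = events[k + 1].threshold_index if k + 1 < len(events) else len(v)
        ev.trough_index = ev.peak_index + int(np.argmin(v[ev.peak_index:stop]))
    return events


def refine_threshold(
    event: APEvent,
    voltage: np.ndarray,
    dt: float,
    avg_max_dvdt: float,
    params: APDetectParams = APDetectParams(),
) -> int:
    """Adjust one AP's threshold to the 5%-of-average-max-dV/dt point.

    Returns the last sample before the peak where the smoothed dV/dt
    rises through ``params.threshold_fraction`` of ``avg_max_dvdt``.
    The rule compares a ratio, so it is invariant to scaling the whole
    trace.  Falls back to the detection index if the derivative never
    drops below the target before the peak.
    """
    sm = _smoothed_dvdt(voltage, dt, params.smooth_samples)
    target = params.threshold_fraction * avg_max_dvdt
    j = event.peak_index
    while j > 0 and sm[j - 1] >= target:
        j -= 1
    if j == 0 and sm[0] >= target:
        return event.detect_index
    return j


def refine_thresholds(
    events: list[APEvent],
    voltage: np.ndarray,
    dt: float,
    params: APDetectParams = APDetectParams(),
) -> list[APEvent]:
    """Refine every event's threshold using the sweep-wide average max dV/dt."""
    if not events:
        return events
    v = np.asarray(voltage, dtype=float)
    sm = _smoothed_dvdt(v, dt, params.smooth_samples)
    avg_max = float(
        np.mean([sm[ev.threshold_index: ev.peak_index + 1].max() for ev in events])
    )
    for ev in events:
        ev.threshold_index = refine_threshold(ev, v, dt, avg_max, params)
        ev.threshold_v = float(v[ev.threshold_index])
    return events


def ap_shape_features(event: APEvent, voltage: np.ndarray, dt: float) -> APEvent:
    """Fill width at half-height, upstroke, downstroke and their ratio.

    Width is measured at half of (peak − threshold) with linear
    interpolation at the crossings; upstroke/downstroke are the extreme
    unsmoothed derivatives on the rising/falling phases.
    """
    v = np.asarray(voltage, dtype=float)
    dt_ms = dt * 1e3
    dvdt = np.gradient(v) / dt_ms
    thr, peak, trough = event.threshold_index, event.peak_index, event.trough_index

    event.upstroke = float(dvdt[thr: peak + 1].max())
    down_seg = dvdt[peak: trough + 1]
    event.downstroke = float(down_seg.min()) if len(down_seg) else None
    if event.downstroke not in (None, 0.0):
        event.upstroke_downstroke_ratio = abs(event.upstroke) / abs(event.downstroke)

    half = event.threshold_v + 0.5 * (event.peak_v - event.threshold_v)
    t_rise = _cross_time(v, thr, peak, half, dt_ms, rising=True)
    t_fall = _cross_time(v, peak, trough, half, dt_ms, rising=False)
    if t_rise is not None and t_fall is not None:
        event.width_half_height = t_fall - t_rise
    return event


def _cross_time(v, i0, i1, level, dt_ms, rising: bool) -> float | None:
    seg = v[i0: i1 + 1]
    if rising:
        idx = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
    else:
        idx = np.flatnonzero((seg[:-1] >= level) & (seg[1:] < level))
    if len(idx) == 0:
        return None
    i = idx[0] if rising else idx[-1]
    dv = seg[i + 1] - seg[i]
    frac = 0.5 if dv == 0 else (level - seg[i]) / dv
    return (i0 + i + frac) * dt_ms


def extract_aps(
    voltage: np.ndarray, dt: float, params: APDetectParams = APDetectParams()
) -> list[APEvent]:
    """Detect, refine thresholds, and compute shape features in one pass."""
    events = detect_aps(voltage, dt, params)
    events = refine_thresholds(events, voltage, dt, params)
    return [ap_shape_features(ev, voltage, dt) for ev in events]


# --------------------------------------------------------------------------
# feature-vector construction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureConfig:
    """Feature-vector layout.

    The six categories: (a) first-AP waveform on a fixed window around
    threshold, (b) its derivative, (c) trough-to-next-threshold ISI
    shapes resampled and averaged, (d) firing rate in 20 ms bins at
    rheobase/+40/+80 pA normalized to the per-step maximum, (e) mean
    voltage in 10 ms bins for the −10/−50/−90 pA steps, (f) the largest
    hyperpolarizing step min-max normalized between minimum and
    baseline.
    """

    ap_window_pre: float = 1.0  # ms before threshold
    ap_window_post: float = 4.0  # ms after threshold
    ap_points: int = 250
    isi_points: int = 100
    psth_bin: float = 20.0  # ms
    psth_offsets: tuple[float, ...] = (0.0, 40.0, 80.0)  # pA above rheobase
    sub_bin: float = 10.0  # ms
    sub_amplitudes: tuple[float, ...] = (-10.0, -50.0, -90.0)  # pA
    hyper_points: int = 100
    detect: APDetectParams = APDetectParams()


@dataclass
class FeatureMatrix:
    values: pd.DataFrame  # cells x features
    categories: pd.Series  # feature name -> category letter
    dropped: dict[str, str] = field(default_factory=dict)  # cell -> reason


def _step_epoch(sweep: VoltageSweep):
    for ep in sweep.epochs:
        if ep.kind == "long_square":
            return ep
    raise ValueError("sweep has no long_square epoch")


def _step_spikes(sweep: VoltageSweep, cfg: FeatureConfig) -> list:
    ep = _step_epoch(sweep)
    events = extract_aps(sweep.voltage, sweep.dt, cfg.detect)
    i0, i1 = sweep.index_at(ep.onset), sweep.index_at(ep.offset)
    return [ev for ev in events if i0 <= ev.threshold_index < i1]


def _resample(y: np.ndarray, n: int) -> np.ndarray:
    if len(y) == 1:
        return np.full(n, y[0])
    x = np.linspace(0.0, 1.0, len(y))
    return np.interp(np.linspace(0.0, 1.0, n), x, y)


def _bin_means(y: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.linspace(0, len(y), n_bins + 1).astype(int)
    return np.array([y[a:b].mean() if b > a else 0.0 for a, b in zip(edges[:-1], edges[1:])])


def _psth(sweep: VoltageSweep, cfg: FeatureConfig) -> np.ndarray:
    ep = _step_epoch(sweep)
    spikes = _step_spikes(sweep, cfg)
    n_bins = int(round((ep.offset - ep.onset) * 1e3 / cfg.psth_bin))
    rate = np.zeros(n_bins)
    for ev in spikes:
        t_ms = (ev.threshold_index * sweep.dt - ep.onset) * 1e3
        b = min(int(t_ms / cfg.psth_bin), n_bins - 1)
        rate[b] += 1.0
    if rate.max() > 0:
        rate = rate / rate.max()  # normalized to the per-step maximum
    return rate


def build_feature_matrix(
    cell_sweeps: dict[str, dict[float, VoltageSweep]],
    cfg: FeatureConfig = FeatureConfig(),
) -> FeatureMatrix:
    """Build the six-category per-cell feature matrix.

    ``cell_sweeps`` maps cell id -> {long-square amplitude (pA) ->
    sweep}.  Rheobase is the lowest tested amplitude eliciting at least
    one AP.  A missing amplitude at rheobase+40 (or +80) is
    interpolated as the mean of the nearest available neighbors'
    binned features; a cell whose requirements cannot be filled is
    dropped with a logged reason.
    """
    rows: dict[str, np.ndarray] = {}
    dropped: dict[str, str] = {}
    names: list[str] | None = None
    cats: list[str] | None = None
    for cell, sweeps in cell_sweeps.items():
        try:
            vec, names, cats = _cell_features(sweeps, cfg)
        except ValueError as exc:
            dropped[cell] = str(exc)
            log.warning("dropping cell %s: %s", cell, exc)
            continue
        rows[cell] = vec
    if not rows:
        raise ValueError("no cell produced a complete feature vector")
    values = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    return FeatureMatrix(values=values, categories=pd.Series(cats, index=names), dropped=dropped)


def _cell_features(sweeps: dict[float, VoltageSweep], cfg: FeatureConfig):
    amps = sorted(sweeps)
    spike_counts = {a: len(_step_spikes(sweeps[a], cfg)) for a in amps}
    supra = [a for a in amps if a > 0 and spike_counts[a] >= 1]
    if not supra:
        raise ValueError("no suprathreshold long square: rheobase undefined")
    rheobase = supra[0]

    # (a, b) first-AP waveform and derivative at the rheobase step
    sweep = sweeps[rheobase]
    first = _step_spikes(sweep, cfg)[0]
    n_pre = int(round(cfg.ap_window_pre * 1e-3 / sweep.dt))
    n_post = int(round(cfg.ap_window_post * 1e-3 / sweep.dt))
    i0 = max(0, first.threshold_index - n_pre)
    i1 = min(len(sweep.voltage), first.threshold_index + n_post)
    wave = _resample(sweep.voltage[i0:i1], cfg.ap_points)
    dwave = np.gradient(wave)

    # (c) averaged normalized ISI shape (trough -> next threshold)
    segs = []
    for a in supra:
        sw = sweeps[a]
        evs = _step_spikes(sw, cfg)
        for e0, e1 in zip(evs[:-1], evs[1:]):
            seg = sw.voltage[e0.trough_index: e1.threshold_index + 1]
            if len(seg) >= 2:
                segs.append(_resample(seg, cfg.isi_points))
    isi = np.mean(segs, axis=0) if segs else np.zeros(cfg.isi_points)

    # (d) PSTH bins at rheobase, +40, +80 pA with neighbor interpolation
    psth_parts = []
    for off in cfg.psth_offsets:
        want = rheobase + off
        if want in sweeps:
            psth_parts.append(_psth(sweeps[want], cfg))
        else:
            lo = [a for a in amps if a < want and a >= rheobase]
            hi = [a for a in amps if a > want]
            if not lo or not hi:
                raise ValueError(f"no neighbors to interpolate step at {want} pA")
            psth_parts.append(0.5 * (_psth(sweeps[lo[-1]], cfg) + _psth(sweeps[hi[0]], cfg)))
    psth = np.concatenate(psth_parts)

    # (e) binned subthreshold responses at -10, -50, -90 pA
    sub_parts = []
    for amp in cfg.sub_amplitudes:
        cand = [a for a in amps if a < 0]
        if not cand:
            raise ValueError("no hyperpolarizing steps available")
        a = amp if amp in sweeps else min(cand, key=lambda x: abs(x - amp))
        sw = sweeps[a]
        ep = _step_epoch(sw)
        seg = sw.voltage[sw.index_at(ep.onset): sw.index_at(ep.offset)]
        n_bins = int(round((ep.offset - ep.onset) * 1e3 / cfg.sub_bin))
        sub_parts.append(_bin_means(seg, n_bins))
    sub = np.concatenate(sub_parts)

    # (f) largest hyperpolarizing step, min-max normalized
    hyper_amp = min(a for a in amps if a < 0)
    sw = sweeps[hyper_amp]
    ep = _step_epoch(sw)
    i0, i1 = sw.index_at(ep.onset), sw.index_at(ep.offset)
    baseline = float(sw.voltage[max(0, i0 - int(0.1 / sw.dt)): i0].mean())
    seg = sw.voltage[i0:i1]
    vmin = float(seg.min())
    norm = (seg - vmin) / (baseline - vmin) if baseline != vmin else np.zeros_like(seg)
    hyper = _bin_means(norm, cfg.hyper_points)

    parts = {"a": wave, "b": dwave, "c": isi, "d": psth, "e": sub, "f": hyper}
    vec = np.concatenate(list(parts.values()))
    names = [f"{c}_{i:03d}" for c, arr in parts.items() for i in range(len(arr))]
    cats = [c for c, arr in parts.items() for _ in range(len(arr))]
    return vec, names, cats


# --------------------------------------------------------------------------
# sparse PCA
# --------------------------------------------------------------------------

@dataclass
class SparsePCResult:
    loadings: dict[str, np.ndarray]  # category -> p x k loading matrix
    adjusted_ev: dict[str, np.ndarray]  # category -> per-component fraction
    kept: dict[str, np.ndarray]  # category -> boolean mask
    scores: pd.DataFrame  # cells x kept components, z-scored


def _soft(x: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def _sparse_loadings(X: np.ndarray, n_comp: int, penalty: float, max_iter=500, tol=1e-9):
    """ℓ1-soft-thresholded power iteration with projection deflation."""
    R = X.copy()
    loadings = []
    for _ in range(n_comp):
        # deterministic init: leading right singular vector of the residual
        v = np.linalg.svd(R, full_matrices=False)[2][0]
        for _ in range(max_iter):
            u = R @ v
            nu = np.linalg.norm(u)
            if nu == 0:
                break
            u /= nu
            w = _soft(R.T @ u, penalty)
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            if np.linalg.norm(w - v) < tol:
                v = w
                break
            v = w
        if np.linalg.norm(v) == 0:
            break
        loadings.append(v)
        R = R - np.outer(R @ v, v)  # projection deflation
    return np.column_stack(loadings) if loadings else np.zeros((X.shape[1], 0))


def _adjusted_ev(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Adjusted explained variance per component via QR of the projections.

    With correlated sparse components, naive variances double-count;
    the QR decomposition of ``X V`` charges each component only the
    variance not already explained by its predecessors.
    """
    total = np.sum(X * X)
    if V.shape[1] == 0 or total == 0:
        return np.zeros(V.shape[1])
    R = np.linalg.qr(X @ V, mode="r")
    return np.diag(R) ** 2 / total


def sparse_pca(
    fm: FeatureMatrix,
    retention: float = 0.01,
    penalty: float = 0.0,
    seed: int = 0,
    max_components: int = 10,
) -> SparsePCResult:
    """Per-category sparse PCA with adjusted-explained-variance retention.

    Components are extracted per category by soft-thresholded power
    iteration with deflation; those whose adjusted explained variance
    exceeds ``retention`` are kept, their scores z-scored and
    concatenated across categories.  With ``penalty=0`` the loadings
    coincide with ordinary PCA up to sign.
    """
    if fm.values.shape[0] < 2:
        raise ValueError("sparse PCA needs at least 2 cells")
    if not np.isfinite(fm.values.to_numpy()).all():
        raise ValueError("feature matrix contains non-finite values")
    loadings, adj, kept = {}, {}, {}
    score_cols = {}
    for cat in CATEGORIES:
        cols = fm.categories.index[fm.categories == cat]
        if len(cols) == 0:
            continue
        X = fm.values[cols].to_numpy(dtype=float)
        X = X - X.mean(axis=0)
        n_comp = min(max_components, X.shape[0] - 1, X.shape[1])
        V = _sparse_loadings(X, n_comp, penalty)
        ev = _adjusted_ev(X, V)
        mask = ev > retention
        loadings[cat], adj[cat], kept[cat] = V, ev, mask
        S = X @ V[:, mask]
        sd = S.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (S - S.mean(axis=0)) / sd
        for j in range(Z.shape[1]):
            score_cols[f"{cat}_pc{j}"] = Z[:, j]
    scores = pd.DataFrame(score_cols, index=fm.values.index)
    return SparsePCResult(loadings=loadings, adjusted_ev=adj, kept=kept, scores=scores)
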