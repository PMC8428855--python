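"""Synthetic reference taxonomies, Patch-seq cells, sweeps and metadata.

Everything downstream of acquisition assumes a particular statistical
structure: a reference taxonomy with marker-gene blocks in log2(CPM+1)
space, query cells whose on-marker signal degrades with sample quality
and is mixed with glial contamination, current-clamp sweeps from a
passive membrane with stereotyped spikes, and experiment metadata in
which end-pipette resistance separates morphology outcomes.  This
module generates all four, as pure functions of (config, seed).

Counts for reference cells are drawn from a gamma-Poisson (negative
binomial) model in count space, CPM-normalized and log2(x+1)
transformed.  Glial contamination is mixed in linear CPM space before
the log transform — contamination is additive RNA, not additive log
signal.  Sample-quality degradation is modelled as a convex mixture of
the cell's true type profile with a marker-free baseline profile, so a
``quality_factor`` of 1 reproduces the type mean exactly and 0 leaves
every marker at baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sweepqc import StimulusEpoch, VoltageSweep
from .taxmap import ROOT, ReferenceTaxonomy

__all__ = [
    "SynthConfig",
    "CellSimSpec",
    "MembraneSpec",
    "make_ap_template",
    "make_reference",
    "make_patchseq_cells",
    "make_sweep",
    "make_metadata",
]


def _child_rng(seed: int | np.random.SeedSequence, key: int) -> np.random.Generator:
    """Independent stream derived from one global seed via a spawn key."""
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed.spawn(1)[0])
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass(frozen=True)
class SynthConfig:
    """Shape and effect sizes of the synthetic reference taxonomy.

    ``marker_effect`` is the elevation of a class's marker genes above
    baseline, in log2-expression units; ``noise_sd`` is the log2-scale
    biological spread of per-cell expression around the type mean.
    ``glia_classes`` of the ``n_classes`` classes are non-neuronal and
    serve as contamination sources.
    """

    seed: int = 0
    n_classes: int = 4
    types_per_class: int = 3
    n_genes: int = 2000
    markers_per_class: int = 50
    marker_effect: float = 10.0  # log2 units; markers are near-zero off-class
    n_ref_cells_per_type: int = 40
    noise_sd: float = 0.3  # log2 units
    glia_classes: int = 1
    type_markers_per_type: int = 10
    baseline_count: float = 20.0  # mean counts for an expressed gene
    depth: float | None = None  # library size; default 10 counts/gene

    def __post_init__(self) -> None:
        for name in ("n_classes", "types_per_class", "n_genes", "markers_per_class",
                     "n_ref_cells_per_type"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.type_markers_per_type < 0:
            raise ValueError("type_markers_per_type must be >= 0")
        if self.marker_effect < 0:
            raise ValueError("marker_effect must be non-negative")
        if not (0 <= self.glia_classes < self.n_classes):
            raise ValueError("glia_classes must leave at least one neuronal class")
        needed = self.n_classes * (
            self.markers_per_class + self.types_per_class * self.type_markers_per_type
        )
        if needed > self.n_genes:
            raise ValueError("not enough genes for the requested marker blocks")


@dataclass(frozen=True)
class CellSimSpec:
    """One simulated Patch-seq cell: identity, nucleus outcome, degradation."""

    true_type: str
    nucleus_plus: bool = True
    quality_factor: float = 1.0  # scales on-marker signal
    contamination_fraction: float = 0.0  # fraction of a glial profile mixed in

    def __post_init__(self) -> None:
        if not 0 <= self.quality_factor <= 1:
            raise ValueError("quality_factor must lie in [0, 1]")
        if not 0 <= self.contamination_fraction < 1:
            raise ValueError("contamination_fraction must lie in [0, 1)")


def _class_names(cfg: SynthConfig) -> list[str]:
    n_neuro = cfg.n_classes - cfg.glia_classes
    return [f"N{i}" for i in range(n_neuro)] + [f"G{i}" for i in range(cfg.glia_classes)]


def _mean_count_profiles(cfg: SynthConfig) -> tuple[pd.DataFrame, dict, dict, list[str]]:
    """True per-type mean count profiles plus the planted marker bookkeeping."""
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    classes = _class_names(cfg)
    class_markers: dict[str, list[str]] = {}
    type_markers: dict[str, list[str]] = {}
    cursor = 0
    types_of_class: dict[str, list[str]] = {}
    for cls in classes:
        class_markers[cls] = genes[cursor: cursor + cfg.markers_per_class]
        cursor += cfg.markers_per_class
        types_of_class[cls] = [f"{cls}_t{j}" for j in range(cfg.types_per_class)]
        for t in types_of_class[cls]:
            type_markers[t] = genes[cursor: cursor + cfg.type_markers_per_type]
            cursor += cfg.type_markers_per_type

    # Markers are expressed at the baseline level in their own class/type and
    # suppressed by marker_effect (log2 units) everywhere else, putting
    # off-class markers in the dropout regime as in real references.  With
    # marker_effect = 0 the suppression vanishes and markers carry no signal.
    idx = pd.Index(genes)
    off_level = cfg.baseline_count * 2.0 ** (-cfg.marker_effect)
    all_marker_pos = idx.get_indexer(
        [g for cls in classes for g in class_markers[cls]]
        + [g for ms in type_markers.values() for g in ms]
    )
    profiles = {}
    for cls in classes:
        for t in types_of_class[cls]:
            mu = np.full(cfg.n_genes, cfg.baseline_count)
            mu[all_marker_pos] = off_level
            mu[idx.get_indexer(class_markers[cls])] = cfg.baseline_count
            mu[idx.get_indexer(type_markers[t])] = cfg.baseline_count
            profiles[t] = mu
    mean_counts = pd.DataFrame(profiles, index=genes)
    return mean_counts, class_markers, type_markers, classes


def _to_log2cpm(counts: np.ndarray) -> np.ndarray:
    total = counts.sum(axis=0, keepdims=True)
    total = np.where(total == 0, 1.0, total)
    cpm = counts / total * 1e6
    return np.log2(cpm + 1.0)


def make_reference(cfg: SynthConfig) -> ReferenceTaxonomy:
    """Generate a synthetic dissociated-cell reference taxonomy.

    Classes carry disjoint marker blocks elevated by ``marker_effect``;
    each leaf type additionally carries its own smaller block so the
    type-level branch points are resolvable.  Per-cell counts are
    gamma-Poisson around the type mean with log2-scale spread
    ``noise_sd``; expression is returned in log2(CPM+1).
    """
    mean_counts, class_markers, type_markers, classes = _mean_count_profiles(cfg)
    rng = _child_rng(cfg.seed, 0)

    # gamma-Poisson: multiplicative gamma with unit mean whose log-scale
    # spread matches noise_sd (in log2 units)
    sigma_ln = cfg.noise_sd * np.log(2.0)
    shape = 1.0 / sigma_ln**2 if sigma_ln > 0 else None

    cells, labels, cols = [], [], []
    types_of_class = {
        cls: [t for t in mean_counts.columns if t.startswith(cls + "_")] for cls in classes
    }
    depth = cfg.depth if cfg.depth is not None else 10.0 * cfg.n_genes
    for cls in classes:
        for t in types_of_class[cls]:
            mu = mean_counts[t].to_numpy()
            scale = mu / mu.sum() * depth
            for j in range(cfg.n_ref_cells_per_type):
                lam = scale
                if shape is not None:
                    lam = scale * rng.gamma(shape, 1.0 / shape, size=len(scale))
                counts = rng.poisson(lam).astype(float)
                cells.append(counts)
                labels.append(t)
                cols.append(f"{t}_c{j}")

    expr = pd.DataFrame(
        _to_log2cpm(np.column_stack(cells)), index=mean_counts.index, columns=cols
    )
    branch_markers = {ROOT: [g for cls in classes for g in class_markers[cls]]}
    for cls in classes:
        tm = [g for t in types_of_class[cls] for g in type_markers[t]]
        # a class with no type-level markers falls back to its class block
        branch_markers[cls] = tm if tm else list(class_markers[cls])
    return ReferenceTaxonomy(
        expr=expr,
        cell_types=pd.Series(labels, index=cols),
        types_of_class=types_of_class,
        branch_markers=branch_markers,
        glial_classes=[c for c in classes if c.startswith("G")],
    )


def _type_mean_cpm(ref: ReferenceTaxonomy) -> pd.DataFrame:
    cpm = 2.0 ** ref.expr - 1.0
    out = {t: cpm.loc[:, ref.cells_of_type(t)].mean(axis=1) for t in ref.leaves}
    return pd.DataFrame(out)


def make_patchseq_cells(
    ref: ReferenceTaxonomy,
    specs: list[CellSimSpec],
    seed: int = 0,
    noise_sd: float = 0.0,
    depth: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate Patch-seq expression for cells of known identity and quality.

    In linear CPM space each cell is
    ``qf * type_profile + (1 - qf) * baseline + cf * glia_profile``
    with optional multiplicative log-normal noise (log2-sd
    ``noise_sd``), renormalized to CPM and log2(x+1) transformed.  The
    baseline is the per-gene minimum of the type mean profiles — i.e.
    every planted marker sits at its off-class level — so the
    quality factor scales exactly the on-marker signal.  With ``depth``
    set, Poisson counts are drawn at that library size before the CPM
    transform, adding realistic dropout of weakly expressed genes;
    ``depth=None`` keeps the mixture deterministic.  Returns
    (expression genes x cells, truth table).
    """
    type_cpm = _type_mean_cpm(ref)
    unknown = {s.true_type for s in specs} - set(type_cpm.columns)
    if unknown:
        raise KeyError(f"unknown type id(s): {sorted(unknown)}")
    baseline = type_cpm.min(axis=1).to_numpy()
    glial_types = [t for c in ref.glial_classes for t in ref.types_of_class[c]]
    glia = type_cpm[glial_types].mean(axis=1).to_numpy() if glial_types else None

    rng = _child_rng(seed, 1)
    profiles, rows = [], []
    for i, s in enumerate(specs):
        mix = (
            s.quality_factor * type_cpm[s.true_type].to_numpy()
            + (1.0 - s.quality_factor) * baseline
        )
        if s.contamination_fraction > 0:
            if glia is None:
                raise ValueError("contamination requested but reference has no glial class")
            mix = mix + s.contamination_fraction * glia
        if noise_sd > 0:
            mix = mix * 2.0 ** rng.normal(0.0, noise_sd, size=len(mix))
        if depth is not None:
            mix = rng.poisson(mix / mix.sum() * depth).astype(float)
        profiles.append(mix)
        rows.append(
            {
                "cell_id": f"ps_{i:04d}",
                "true_type": s.true_type,
                "nucleus_plus": s.nucleus_plus,
                "quality_factor": s.quality_factor,
                "contamination_fraction": s.contamination_fraction,
            }
        )
    truth = pd.DataFrame(rows).set_index("cell_id")
    expr = pd.DataFrame(
        _to_log2cpm(np.column_stack(profiles)), index=type_cpm.index, columns=truth.index
    )
    return expr, truth


# --------------------------------------------------------------------------
# electrophysiology
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneSpec:
    """Passive membrane with stereotyped spikes.

    First-order relaxation toward ``rmp + r_input * I`` with time
    constant ``tau``; when the voltage crosses ``spike_threshold`` a
    stereotyped action-potential template (relative to threshold) is
    pasted into the trace.  ``spike_threshold=None`` disables spiking.
    """

    rmp: float = -70.0  # mV
    r_input: float = 100.0  # MΩ
    tau: float = 20.0  # ms
    spike_threshold: float | None = None  # mV
    ap_template: np.ndarray | None = None  # mV, relative to threshold
    ap_peak_dvdt: float = 40.0  # mV/ms of the default template
    reset_drop: float = 10.0  # mV below threshold after a spike
    noise_rms: float = 0.0  # mV
    drift_rate: float = 0.0  # mV/s
    sampling_rate: float = 50.0  # kHz

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.sampling_rate <= 0:
            raise ValueError("tau and sampling_rate must be positive")

    def template(self) -> np.ndarray:
        if self.ap_template is not None:
            return np.asarray(self.ap_template, dtype=float)
        return make_ap_template(
            self.ap_peak_dvdt, sampling_rate=self.sampling_rate
        )


def make_ap_template(
    peak_dvdt: float,
    height: float = 60.0,
    trough: float = -10.0,
    fall_factor: float = 0.5,
    recover_dvdt: float = 2.0,
    sampling_rate: float = 50.0,
) -> np.ndarray:
    """Piecewise-linear spike waveform with an exactly known peak dV/dt.

    Rises from 0 to ``height`` mV at slope ``peak_dvdt`` (mV/ms), falls
    to ``trough`` at ``fall_factor * peak_dvdt``, then recovers to 0 at
    ``recover_dvdt``.  Values are relative to the spike threshold.  The
    linear segments make derivative-based detector boundaries exact.
    """
    dt_ms = 1.0 / sampling_rate
    t_rise = height / peak_dvdt
    t_fall = (height - trough) / (fall_factor * peak_dvdt)
    t_rec = -trough / recover_dvdt
    n1, n2, n3 = (max(2, int(round(t / dt_ms))) for t in (t_rise, t_fall, t_rec))
    rise = np.linspace(0.0, height, n1, endpoint=False)
    fall = np.linspace(height, trough, n2, endpoint=False)
    rec = np.linspace(trough, 0.0, n3)
    return np.concatenate([rise, fall, rec])


def _stimulus_array(epochs: list[StimulusEpoch], n: int, dt: float) -> np.ndarray:
    t = np.arange(n) * dt
    stim = np.zeros(n)
    for ep in epochs:
        mask = (t >= ep.onset) & (t < ep.offset)
        if ep.kind == "ramp":
            stim[mask] = ep.amplitude * (t[mask] - ep.onset)  # amplitude = slope pA/s
        else:
            stim[mask] = ep.amplitude
    return stim


def make_sweep(
    m: MembraneSpec,
    stimulus: list[StimulusEpoch],
    seed: int = 0,
    duration: float | None = None,
) -> VoltageSweep:
    """Simulate one current-clamp sweep.

    Exponential-Euler integration of the passive membrane; threshold
    crossings paste the spike template and hold the integrator
    refractory for the template's duration.  ``duration`` defaults to
    0.5 s past the last epoch.
    """
    if duration is None:
        duration = (max(ep.offset for ep in stimulus) if stimulus else 0.0) + 0.5
    dt = 1e-3 / m.sampling_rate  # s
    n = int(round(duration / dt))
    for ep in stimulus:
        if ep.onset < 0 or ep.offset > duration + 1e-12:
            raise ValueError("stimulus epoch lies outside the sweep")
    stim = _stimulus_array(stimulus, n, dt)

    rng = _child_rng(seed, 2)
    v = np.empty(n)
    v[0] = m.rmp
    alpha = 1.0 - np.exp(-(dt * 1e3) / m.tau)
    template = m.template() if m.spike_threshold is not None else None
    i = 0
    while i < n - 1:
        v_inf = m.rmp + m.r_input * stim[i] * 1e-3  # pA * MΩ = µV -> mV
        v[i + 1] = v[i] + (v_inf - v[i]) * alpha
        if m.spike_threshold is not None and v[i + 1] >= m.spike_threshold:
            seg = template[: n - (i + 1)]
            v[i + 1: i + 1 + len(seg)] = m.spike_threshold + seg
            i += len(seg)
            if i < n:  # post-spike reset: afterhyperpolarized restart
                v[i] = m.spike_threshold - m.reset_drop
        else:
            i += 1

    if m.drift_rate != 0.0:
        v = v + m.drift_rate * np.arange(n) * dt
    if m.noise_rms > 0:
        v = v + rng.normal(0.0, m.noise_rms, size=n)
    return VoltageSweep(start_time=0.0, dt=dt, voltage=v, stimulus=stim, epochs=list(stimulus))


# --------------------------------------------------------------------------
# experiment metadata
# --------------------------------------------------------------------------

def make_metadata(n: int, auc_target: float = 0.8, seed: int = 0) -> pd.DataFrame:
    """Outcome records whose endR separates morphology outcomes at a set AUC.

    End-pipette resistance is drawn from two Gaussians (failed vs
    good morphology, equal spread) whose analytic AUC,
    Φ(Δµ / (σ√2)), equals ``auc_target``; higher endR means a better
    chance of morphological recovery.  ``auc_target=1`` uses disjoint
    uniform supports.  cDNA quantity and quality are elevated for
    nucleus+ cells.
    """
    if not 0.5 <= auc_target <= 1.0:
        raise ValueError("auc_target must lie in [0.5, 1]")
    rng = _child_rng(seed, 3)
    good = rng.random(n) < 0.5
    sigma = 1.5
    if auc_target == 1.0:
        end_r = np.where(good, rng.uniform(10.0, 11.0, n), rng.uniform(1.0, 2.0, n))
    else:
        delta = sigma * np.sqrt(2.0) * norm.ppf(auc_target)
        end_r = rng.normal(5.0, sigma, n) + np.where(good, delta, 0.0)
    nucleus = rng.random(n) < 0.7
    quantity = np.clip(rng.normal(18.0, 4.0, n) + 10.0 * nucleus, 0.1, None)
    quality = np.clip(rng.normal(0.45, 0.08, n) + 0.2 * nucleus, 0.0, 1.0)
    outcome = np.where(
        good, rng.choice(["high", "medium"], n), "failed"
    )
    return pd.DataFrame(
        {
            "cell_id": [f"meta_{i:05d}" for i in range(n)],
            "end_pipette_resistance": end_r,
            "nucleus_plus": nucleus,
            "cdna_quantity": quantity,
            "cdna_quality": quality,
            "morphology_outcome": outcome,
            "recording_duration": rng.gamma(4.0, 2.0, n),
            "retrieval_duration": rng.gamma(2.0, 0.8, n),
            "extraction_duration": rng.gamma(2.0, 1.0, n),
            "health_rating": rng.integers(1, 6, n),
        }
    ).set_index("cell_id")
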