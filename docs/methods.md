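# Methods

This note documents the models behind `patchseqkit`, the parameter
conventions, the design choices made where the design was genuinely
open, and what the synthetic-data generators do and do not emulate.

## Sweep quality control

A sweep is a uniformly sampled voltage/stimulus pair with epoch markers
(`short_pulse`, `long_square` at a fixed amplitude in pA, or `ramp`
with a slope in pA/s, default 25 pA/s).

**Baseline evaluation** uses the window of `baseline_window` (500 ms)
immediately preceding the first stimulus epoch.  Three criteria are
combined as a product — the pass region is a box:

* the window mean is within `rmp_tolerance` (1 mV) of `target_vm`,
  boundary **inclusive** ("within 1 mV" reads naturally as ≤);
* the *short-window* RMS metric is strictly below `rms_short_max`
  (0.07 mV).  The protocol names a 1.5 ms window "to gauge high
  frequency noise" without a formula; we take the **maximum RMS over
  non-overlapping 1.5 ms sub-windows**, each individually
  mean-subtracted, so a single noisy transient cannot hide in a long
  average.  This choice is configurable (`rms_short_window`);
* the *long-window* RMS metric — RMS of the mean-subtracted full
  window — is strictly below `rms_long_max` (0.5 mV).

Strict inequalities at the RMS limits follow the "<" convention of the
inclusion criteria; "0 ± 100 pA" bias current is treated as
|I| ≤ 100 pA.

**Recovery evaluation** starts `recovery_min` (500 ms) after stimulus
end and assays consecutive non-overlapping `recovery_eval` (500 ms)
windows; the first window satisfying all three baseline criteria ends
the sweep, with `pass_time` at the window's end, so `pass_time −
stim_end − recovery_min` is always a multiple of the evaluation window.
If no window passes by `recovery_max` (10 s past stimulus end) the
sweep fails.  A failing recovery counts as one failed sweep toward the
set-abort rule.

**Autobias** is an Ohm's-law controller (no controller law is
prescribed by the protocol): ΔI = (V_target − V_measured)/R_input,
clipped to `autobias_max_step` (100 pA default).  Units: mV/MΩ = nA.

**Stimulus sets**: failed sweeps are repeated; acquisition aborts
exactly when remaining-required-passes + accumulated-failures exceeds
the total allotted sweeps.  The allotment is `required + max_repeats`
with `max_repeats` defaulting to the template count, which makes the
stated rule ("passes required plus failures exceeded the total") hold
with total = 2 × required.  A ramp sweep is first probed, the stimulus
is cut one sample after the `ramp_spike_limit`-th (5th) online spike
detection, and the recording continues through recovery — so the
recorded trace contains exactly the spike limit before stimulus offset.

**Online spike detection** smooths the sample derivative (mV/ms) with a
*causal* boxcar (5 samples) — an acquisition system cannot look ahead —
and reports upward crossings of the threshold (20 mV/ms).  Offline
detection in `apfeat` uses a *centered* boxcar instead; the two are
deliberately different and documented here.

## AP features

Offline detection marks samples where the centered-boxcar-smoothed
dV/dt reaches 20 mV/ms, then filters candidates by threshold-to-peak
height ≥ 2 mV, time-to-peak ≤ 5 ms, and absolute peak ≥ −30 mV.  The
named refinement filters carry no published values; these defaults
follow common practice in the field's feature-extraction toolchains and
are configurable.  The AP threshold is re-located at the last sample
before the peak where the smoothed dV/dt rises through 5% of the
average maximal dV/dt over the sweep's APs (per-sweep averaging chosen;
"across all APs" is ambiguous between sweep and cell).  Width is
measured at half of (peak − threshold) with linear interpolation at the
crossings; upstroke/downstroke are the extreme raw derivatives on the
rising/falling phases and their ratio is scale- and offset-invariant.

Feature vectors come in six categories: (a) the first AP of the
lowest-amplitude suprathreshold step on a fixed window (threshold
− 1 ms to + 4 ms, resampled to 250 points — the window length is our
choice); (b) its derivative; (c) trough-to-next-threshold interspike
segments resampled to 100 points and averaged; (d) firing rate in
20 ms bins (50 per 1 s step) at rheobase, +40 and +80 pA, normalized to
the per-step maximum, with a missing amplitude filled by the mean of
its nearest available neighbors; (e) mean voltage in 10 ms bins
(100 per step) for the −10/−50/−90 pA steps, concatenated (length
300); (f) the largest hyperpolarizing step min-max normalized between
its minimum and the pre-stimulus baseline.  Rheobase is the lowest
tested long-square amplitude eliciting at least one AP.  Cells whose
requirements cannot be filled are dropped with a logged reason.

**Sparse PCA** runs per category: soft-thresholded power iteration with
projection deflation (the solver is unspecified in the protocol; this
is the classic ℓ1 relaxation), initialized deterministically from the
residual's leading singular vector.  At zero penalty the loadings
coincide with ordinary PCA, which the tests verify against an
eigendecomposition.  Adjusted explained variance uses the QR
decomposition of the projected data, charging each component only the
variance not already explained by its predecessors; components above
the 1% retention threshold are kept, z-scored, and concatenated.

## Transcriptomic quality

All expression is log2(CPM+1), CPM = counts/column-sum × 10⁶.

**Marker selection** ranks genes per class by
(mean expression in class − max mean elsewhere) ×
(detection fraction in class − max detection fraction elsewhere), both
factors clipped at zero (two negative differences must not multiply
into a positive score) and the detection factor floored at 0.01 so the
ranking degrades gracefully to the mean difference in deeply sequenced
references where every gene is detected everywhere.  Ties break
lexicographically by gene name; a gene joins only its highest-scoring
class.  The top `n_markers` (default 50) per class become its "on"
markers; the "off" set of a class is the complement — every glial class
plus the other neuronal classes, which at subclass-level granularity is
simply all other classes.

**Scores** per cell: norm_c = mean on-marker expression / reference
class median (the median over reference cells of the per-cell mean —
"median of means" chosen where the wording is ambiguous).  NMS is the
maximum norm and assigns the class; by construction the median norm of
reference cells within their own class is exactly 1.  Contamination is
the sum of norm_c over the assigned class's off classes, without
clipping of per-class norms (no clipping is mentioned anywhere; the
divergence risk versus other implementations of this score family is
acknowledged).  The quality score is the Spearman correlation between
the cell's marker-union vector and the mean profile of the assigned
class's best-matching type ("correlation" is unqualified; rank
correlation is robust to the log-scale compression).  Pass/fail is
NMS ≥ 0.4, boundary inclusive.

## Taxonomy mapping

The reference taxonomy is a two-level tree (root → classes → leaf
t-types) with marker sets per branch point.  A descent correlates the
query (Pearson) with each child's mean profile over the branch markers
and follows the most correlated child; ties break by declared child
order.  Bootstrap confidence runs 100 full root-to-leaf descents, each
with a fresh 70% subsample of reference cells and 70% of markers ("100
iterations at each branch point" could also mean per-branch resampling
within one descent; full descents have the same probability semantics
and are simpler to reason about).  Leaf probabilities are therefore
multiples of 1/100.  A subsample that empties a cluster is resampled
(bounded retries).

The **reference probability matrix** bootstrap-maps every reference
cell and averages the distributions per true type (mean aggregation
chosen; configurable in principle to median).  Consistency
classification applies, in order: KL divergence (natural log, both
distributions floored at 1e-6 and renormalized) of the cell's
distribution from its assigned type's reference row > 2 ⇒ inconsistent;
Pearson correlation with the assigned type's mean profile over the
root-to-leaf path markers < 0.5 ⇒ inconsistent; top-two probability
sum > 0.70 **and** top1/top2 ratio > 2 ⇒ highly consistent (strict
inequalities, matching "exceeded" / "more than"; a zero second
probability passes the ratio test); otherwise moderately consistent.

## Outcome analysis

ROC curves are empirical over all thresholds with tied scores grouped
into single steps (delegated to scikit-learn's `roc_curve`); AUC is the
trapezoid integral and equals the concordant-pair (Mann–Whitney)
probability, which the tests verify against brute-force pair counting.
Score direction is always declared per analysis (endR: higher predicts
good morphology; NMS: higher predicts pass), never inferred.
`operating_point` reports, at a cutoff, the fraction of bad-outcome
cells excluded and of good-outcome cells lost.  Group comparisons
(Welch t-test) are a thin convenience over scipy.

## Synthetic data: what it emulates, and what it does not

`make_reference` plants disjoint marker blocks: each class has
`markers_per_class` genes (default 50) expressed at the baseline count
level in its own types and suppressed by `marker_effect` (default 10
log2 units — real subclass markers are near-zero off-class, which puts
off-class markers in the dropout regime) elsewhere; each leaf type
additionally carries a small private block so type-level branch points
are resolvable.  Reference counts are gamma-Poisson (negative binomial)
around the type mean with log2-scale spread `noise_sd` (default 0.3),
at a library depth of 10 counts/gene by default, then CPM-normalized
and log2(x+1)-transformed.  All generators are pure functions of
(config, seed); one global seed spawns independent child streams per
component.

`make_patchseq_cells` mixes, in linear CPM space (contamination is
additive RNA, not additive log signal):

    quality_factor × type_profile + (1 − quality_factor) × baseline
      + contamination_fraction × glia_profile

then renormalizes and log-transforms.  The baseline is the per-gene
minimum of type mean profiles — every marker at its off-class level —
so `quality_factor` scales exactly the on-marker signal: 1 reproduces
the type mean bit-exactly and 0 leaves no marker signal.  (A pure
scalar on the whole profile would be cancelled by CPM renormalization,
which would contradict the intended degradation semantics.)  Optional
`depth` draws Poisson counts at a finite library size, adding the
dropout that makes heavily degraded cells map inconsistently; the
dropout model of real Patch-seq degradation is unknown and this
two-knob stand-in (signal scaling + depth) is exactly that — a
stand-in.  The generator does not emulate batch effects, ambient-RNA
profiles beyond a single glial mixture, intron/exon split, or the
scale of real taxonomies (>100 leaf types); passing tests show the scoring
and mapping machinery behaves correctly under the planted model, not
that real data meets its assumptions.

`make_sweep` integrates a first-order passive membrane (exponential
Euler, exact for piecewise-constant input) with gain `r_input` and time
constant `tau`; threshold crossings paste a piecewise-linear AP
template with configurable peak dV/dt (analytic control of derivative
features makes detector boundary tests exact), followed by a reset
`reset_drop` below threshold.  Units: pA × MΩ = µV.  The default ramp
(25 pA/s) on the default membrane produces a regular spike train whose
first spike matches the closed-form threshold-crossing time of the
linear ODE.

`make_metadata` draws endR from two equal-variance Gaussians whose
analytic AUC Φ(Δµ/(σ√2)) equals `auc_target` (disjoint uniforms at
`auc_target = 1`), with cDNA quantity/quality elevated for nucleus+
cells.

## Problem sizes and numerical conventions

Tests and the acceptance script run on compact taxonomies (3–4 classes
× 1–3 types, 300–2000 genes, 15–40 reference cells per type) and
50 kHz sweeps of a few seconds — sizes chosen so every check completes
in seconds to a few minutes on one CPU while still exercising every
code path.  Bisections run to 1e-7 brackets; KL smoothing is 1e-6;
sparse-PCA power iteration converges to 1e-9 with at most 500
iterations.  Degenerate inputs (all-zero expression, spike-free cells,
zero-variance windows) return defined values or raise typed errors
rather than NaN.

## Known limitations

* The short-window RMS definition (max over sub-windows) and the
  stimulus-set allotment (2 × required) are interpretations of prose;
  both are configurable and their alternatives would shift only the
  corresponding boundary semantics, not the scores.
* Contamination sums unclipped norms and can exceed 1 for heavily
  contaminated cells.
* The sparse-PCA solver is a rank-one ℓ1 relaxation; with strong
  penalties and correlated blocks it can split variance differently
  from exact sparse formulations (adjusted explained variance accounts
  for the overlap).
* No NWB or acquisition-hardware I/O; sweeps travel as long-format CSV.
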