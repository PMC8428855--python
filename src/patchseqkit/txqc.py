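"""Transcriptomic quality scores for Patch-seq cells.

Three per-cell metrics, all in log2(CPM+1) space, against marker-gene
sets derived from a dissociated-cell (FACS) reference:

* **NMS** (normalized marker sum): the cell's mean "on"-marker
  expression divided by the reference median for the class with the
  highest such normalized value.  Cells at or above a cutoff (default
  0.4) pass.
* **Contamination**: the summed normalized marker expression over the
  assigned class's "off" classes — cell types whose markers should be
  absent and whose presence indicates ambient/adjacent-cell RNA.
* **Quality score**: rank correlation between the cell's on+off marker
  vector and the mean reference profile of the best-matching type of
  the assigned class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .taxmap import ReferenceTaxonomy

__all__ = [
    "MarkerSets",
    "FacsSummary",
    "TxQCScores",
    "select_markers",
    "compute_facs_summary",
    "score_cell",
    "score_cells",
    "classify_quality",
]

NMS_CUTOFF = 0.4


@dataclass
class MarkerSets:
    """On-markers per class and the off-class sets used for contamination."""

    on_markers: dict[str, list[str]]
    off_classes: dict[str, list[str]]

    @property
    def all_markers(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.on_markers.values():
            for g in genes:
                seen.setdefault(g)
        return list(seen)


@dataclass
class FacsSummary:
    """Reference (FACS) normalization constants.

    ``class_median``: per class, the median over reference cells of the
    mean on-marker log2(CPM+1) expression.  ``type_profiles``: per leaf
    type, the mean expression over the full marker union.
    """

    class_median: pd.Series
    type_profiles: pd.DataFrame  # markers x types
    class_of_type: dict[str, str]


@dataclass
class TxQCScores:
    nms: float
    assigned_class: str
    contamination: float
    quality_score: float
    passed: bool


def select_markers(ref: ReferenceTaxonomy, n_markers: int = 50) -> MarkerSets:
    """Choose ``n_markers`` on-marker genes per class by differential score.

    Score = (mean expression in class − max mean elsewhere) ×
    (detection fraction in class − max detection fraction elsewhere);
    ties break lexicographically by gene name, and a gene joins at most
    one class (its highest-scoring one).  Off classes for a neuronal
    class are every glial class plus the other neuronal classes; for a
    glial class, every other class.
    """
    if n_markers > ref.expr.shape[0]:
        raise ValueError("n_markers exceeds the number of genes")
    classes = ref.classes
    means = pd.DataFrame({c: ref.class_mean_profile(c) for c in classes})
    det = pd.DataFrame(
        {c: (ref.expr.loc[:, ref.cells_of_class(c)] > 0).mean(axis=1) for c in classes}
    )
    scores = pd.DataFrame(index=ref.expr.index, columns=classes, dtype=float)
    for c in classes:
        others = [o for o in classes if o != c]
        # both factors clipped at zero: a gene depleted in the class must not
        # earn a positive score from the product of two negative differences.
        # The small detection floor keeps the ranking driven by the mean
        # difference when detection saturates (deeply sequenced references).
        scores[c] = (means[c] - means[others].max(axis=1)).clip(lower=0) * (
            (det[c] - det[others].max(axis=1)).clip(lower=0) + 0.01
        )

    owner = scores.idxmax(axis=1)  # each gene belongs to its best class only
    on: dict[str, list[str]] = {}
    for c in classes:
        pool = scores.loc[owner == c, c]
        if len(pool) < n_markers:
            raise ValueError(
                f"class {c!r} has only {len(pool)} candidate markers, needs {n_markers}"
            )
        ranked = pool.sort_index().sort_values(ascending=False, kind="stable")
        on[c] = list(ranked.index[:n_markers])

    # with subclass-level classes, "every glial class plus the other neuronal
    # classes" is exactly the complement of the assigned class
    off = {c: [o for o in classes if o != c] for c in classes}
    return MarkerSets(on_markers=on, off_classes=off)


def compute_facs_summary(ref: ReferenceTaxonomy, markers: MarkerSets) -> FacsSummary:
    """Reference medians and per-type mean marker profiles."""
    med = {}
    for c, genes in markers.on_markers.items():
        per_cell_mean = ref.expr.loc[genes, ref.cells_of_class(c)].mean(axis=0)
        med[c] = float(per_cell_mean.median())
    union = markers.all_markers
    profiles = pd.DataFrame(
        {t: ref.type_mean_profile(t, genes=union) for t in ref.leaves}
    )
    return FacsSummary(
        class_median=pd.Series(med),
        type_profiles=profiles,
        class_of_type=ref.class_of_type,
    )


def _class_norms(expr: pd.Series, markers: MarkerSets, facs: FacsSummary) -> pd.Series:
    norms = {}
    for c, genes in markers.on_markers.items():
        med = facs.class_median[c]
        if med == 0:
            warnings.warn(f"FACS median for class {c!r} is zero; class excluded")
            continue
        norms[c] = float(expr.loc[genes].mean()) / med
    if not norms:
        raise ValueError("no class has a usable FACS median")
    return pd.Series(norms)


def score_cell(
    expr: pd.Series,
    markers: MarkerSets,
    facs: FacsSummary,
    cutoff: float = NMS_CUTOFF,
) -> TxQCScores:
    """NMS, contamination and quality score for one cell.

    Per class c, norm_c = mean on-marker expression / reference median;
    NMS is the maximum over classes and assigns the class; contamination
    sums norm_c over the assigned class's off classes; the quality score
    is the Spearman correlation of the cell's marker-union vector with
    the mean profile of the assigned class's best-matching type.
    """
    norms = _class_norms(expr, markers, facs)
    assigned = norms.idxmax()
    nms = float(norms.max())
    contamination = float(
        norms.reindex(markers.off_classes[assigned]).dropna().sum()
    )
    union = markers.all_markers
    x = expr.loc[union].to_numpy(dtype=float)
    types = [t for t, c in facs.class_of_type.items() if c == assigned]
    best = max(
        types,
        key=lambda t: np.corrcoef(x, facs.type_profiles.loc[union, t])[0, 1]
        if np.std(x) > 0
        else 0.0,
    )
    if np.std(x) > 0:
        quality = float(spearmanr(x, facs.type_profiles.loc[union, best]).statistic)
    else:
        quality = 0.0
    return TxQCScores(
        nms=nms,
        assigned_class=assigned,
        contamination=contamination,
        quality_score=quality,
        passed=classify_quality(nms, cutoff),
    )


def score_cells(
    expr: pd.DataFrame,
    markers: MarkerSets,
    facs: FacsSummary,
    cutoff: float = NMS_CUTOFF,
) -> pd.DataFrame:
    """Score every column of a genes x cells matrix; returns a per-cell table."""
    rows = {}
    for cell in expr.columns:
        s = score_cell(expr[cell], markers, facs, cutoff)
        rows[cell] = {
            "nms": s.nms,
            "assigned_class": s.assigned_class,
            "contamination": s.contamination,
            "quality_score": s.quality_score,
            "passed": s.passed,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_quality(nms: float | TxQCScores, cutoff: float = NMS_CUTOFF) -> bool:
    """Pass/fail on NMS: pass iff nms >= cutoff (boundary inclusive)."""
    value = nms.nms if isinstance(nms, TxQCScores) else nms
    return bool(value >= cutoff)
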