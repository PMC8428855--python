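"""Top-down correlation mapping of cells onto a reference taxonomy.

A reference taxonomy is a two-level tree (root -> cell classes -> leaf
transcriptomic types, "t-types") with a reference expression matrix of
dissociated cells in log2(CPM+1) space and marker-gene sets attached to
every branch point.  A query cell descends the tree: at each node its
Pearson correlation with every child's mean profile, restricted to that
node's markers, decides the branch.  Bootstrapping the descent over
subsampled reference cells and markers yields a probability distribution
over leaf types; comparing that distribution with the distribution seen
for reference cells of the assigned type (via KL divergence) plus
expression correlation and probability-concentration rules classifies
every cell as highly consistent, moderately consistent, or inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceTaxonomy",
    "MappingResult",
    "ConsistencyThresholds",
    "map_cell_once",
    "bootstrap_map",
    "reference_probability_matrix",
    "kl_divergence",
    "classify_consistency",
]

ROOT = "root"


@dataclass
class ReferenceTaxonomy:
    """Two-level hierarchy with reference expression.

    Parameters
    ----------
    expr
        Reference expression, genes x cells, log2(CPM+1).
    cell_types
        Leaf-type label per reference cell (index aligned with ``expr``
        columns).
    types_of_class
        Ordered mapping class -> list of leaf-type ids.  Child order is
        the declared tie-break order.
    branch_markers
        Marker genes per branch node: key ``"root"`` for the class-level
        branch point, and one key per class for its type-level branch
        point.
    glial_classes
        Subset of classes regarded as non-neuronal; used by the
        transcriptomic QC module to build contamination ("off") sets.
    """

    expr: pd.DataFrame
    cell_types: pd.Series
    types_of_class: dict[str, list[str]]
    branch_markers: dict[str, list[str]]
    glial_classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.expr.columns.equals(self.cell_types.index):
            raise ValueError("expr columns and cell_types index must align")
        for node, markers in self.branch_markers.items():
            if len(markers) == 0:
                raise ValueError(f"branch {node!r} has an empty marker set")
        counts = self.cell_types.value_counts()
        for leaf in self.leaves:
            if counts.get(leaf, 0) < 2:
                raise ValueError(f"leaf type {leaf!r} has fewer than 2 reference cells")

    @property
    def classes(self) -> list[str]:
        return list(self.types_of_class)

    @property
    def leaves(self) -> list[str]:
        return [t for ts in self.types_of_class.values() for t in ts]

    @property
    def class_of_type(self) -> dict[str, str]:
        return {t: c for c, ts in self.types_of_class.items() for t in ts}

    def cells_of_type(self, leaf: str) -> pd.Index:
        return self.cell_types.index[self.cell_types == leaf]

    def cells_of_class(self, cls: str) -> pd.Index:
        members = set(self.types_of_class[cls])
        return self.cell_types.index[self.cell_types.isin(members)]

    def type_mean_profile(self, leaf: str, genes=None) -> pd.Series:
        sub = self.expr.loc[:, self.cells_of_type(leaf)]
        if genes is not None:
            sub = sub.loc[genes]
        return sub.mean(axis=1)

    def class_mean_profile(self, cls: str, genes=None) -> pd.Series:
        sub = self.expr.loc[:, self.cells_of_class(cls)]
        if genes is not None:
            sub = sub.loc[genes]
        return sub.mean(axis=1)

    def path_markers(self, leaf: str) -> list[str]:
        """Union of branch markers along the root-to-leaf path (ordered, deduplicated)."""
        cls = self.class_of_type[leaf]
        seen: dict[str, None] = {}
        for g in self.branch_markers[ROOT] + self.branch_markers[cls]:
            seen.setdefault(g)
        return list(seen)

    def _cache(self) -> dict:
        """Integer-index views of the reference for the descent inner loop."""
        cache = getattr(self, "_idx_cache", None)
        if cache is None:
            genes = self.expr.index
            cache = {
                "G": self.expr.to_numpy(dtype=float),
                "marker_rows": {
                    node: genes.get_indexer(ms) for node, ms in self.branch_markers.items()
                },
                "member_mask": {
                    **{
                        c: self.expr.columns.isin(self.cells_of_class(c))
                        for c in self.classes
                    },
                    **{t: (self.cell_types == t).to_numpy() for t in self.leaves},
                },
            }
            object.__setattr__(self, "_idx_cache", cache)
        return cache


@dataclass
class MappingResult:
    """Bootstrap mapping distribution for one cell."""

    probabilities: pd.Series  # over leaf types, sums to 1
    assigned_type: str
    n_boot: int
    kl: float | None = None
    type_correlation: float | None = None
    consistency: str | None = None


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return 0.0
    return float(xc @ yc / denom)


def map_cell_once(
    expr: pd.Series,
    tax: ReferenceTaxonomy,
    cell_subset: pd.Index | None = None,
    marker_subset: set[str] | None = None,
) -> str:
    """Deterministic top-down descent; returns the winning leaf type.

    At each branch point the Pearson correlation between the query and
    each child's mean profile over the branch markers (optionally
    restricted to ``marker_subset``, with means recomputed on
    ``cell_subset``) is evaluated; the most-correlated child wins and
    ties break by declared child order.
    """
    xv = expr.reindex(tax.expr.index).to_numpy(dtype=float)
    cell_mask = (
        None if cell_subset is None else tax.expr.columns.isin(pd.Index(cell_subset))
    )
    marker_mask = (
        None
        if marker_subset is None
        else tax.expr.index.isin(list(marker_subset))
    )
    return _descend(xv, tax, cell_mask, marker_mask)


def _descend(
    xv: np.ndarray,
    tax: ReferenceTaxonomy,
    cell_mask: np.ndarray | None,
    marker_mask: np.ndarray | None,
) -> str:
    cache = tax._cache()
    G = cache["G"]

    def branch(node: str, children: list[str]) -> str:
        rows = cache["marker_rows"][node]
        if marker_mask is not None:
            rows = rows[marker_mask[rows]]
        if len(rows) == 0:
            raise ValueError(f"effective marker set at branch {node!r} is empty")
        x = xv[rows]
        best, best_r = None, -np.inf
        for child in children:
            mask = cache["member_mask"][child]
            if cell_mask is not None:
                mask = mask & cell_mask
            cols = np.flatnonzero(mask)
            if len(cols) == 0:
                raise ValueError(f"no reference cells for child {child!r} in subset")
            mu = G[np.ix_(rows, cols)].mean(axis=1)
            r = _pearson(x, mu)
            if r > best_r:
                best, best_r = child, r
        return best

    cls = branch(ROOT, tax.classes)
    return branch(cls, tax.types_of_class[cls])


def bootstrap_map(
    expr: pd.Series,
    tax: ReferenceTaxonomy,
    n_boot: int = 100,
    cell_frac: float = 0.7,
    marker_frac: float = 0.7,
    seed: int | np.random.SeedSequence = 0,
    max_retries: int = 10,
) -> MappingResult:
    """Bootstrap the descent ``n_boot`` times with subsampled cells/markers.

    Each iteration independently samples ``cell_frac`` of the reference
    cells and ``marker_frac`` of the marker genes (without replacement)
    and runs one full root-to-leaf descent.  The leaf probability is the
    fraction of descents ending at that leaf; every probability is a
    multiple of ``1/n_boot``.  Deterministic given ``seed``.
    """
    if not (0 < cell_frac <= 1 and 0 < marker_frac <= 1):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_total_cells = tax.expr.shape[1]
    marker_rows = np.unique(
        tax.expr.index.get_indexer(
            [g for ms in tax.branch_markers.values() for g in ms]
        )
    )
    n_cells = max(1, int(round(cell_frac * n_total_cells)))
    n_markers = max(1, int(round(marker_frac * len(marker_rows))))
    xv = expr.reindex(tax.expr.index).to_numpy(dtype=float)

    leaves = tax.leaves
    counts = dict.fromkeys(leaves, 0)
    for _ in range(n_boot):
        for attempt in range(max_retries):
            cell_mask = np.zeros(n_total_cells, dtype=bool)
            cell_mask[rng.choice(n_total_cells, size=n_cells, replace=False)] = True
            marker_mask = np.zeros(tax.expr.shape[0], dtype=bool)
            marker_mask[rng.choice(marker_rows, size=n_markers, replace=False)] = True
            try:
                leaf = _descend(xv, tax, cell_mask, marker_mask)
                break
            except ValueError:
                continue  # a cluster or branch emptied; resample
        else:
            raise ValueError("bootstrap subsampling repeatedly emptied a cluster")
        counts[leaf] += 1

    probs = pd.Series({k: v / n_boot for k, v in counts.items()}, dtype=float)
    assigned = max(leaves, key=lambda t: probs[t])  # first leaf in order wins ties
    return MappingResult(probabilities=probs, assigned_type=assigned, n_boot=n_boot)


def reference_probability_matrix(
    tax: ReferenceTaxonomy,
    n_boot: int = 100,
    cell_frac: float = 0.7,
    marker_frac: float = 0.7,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Bootstrap-map every reference cell; return per-type mean probability vectors.

    Rows are leaf types, columns are leaf types, each row sums to 1.
    Row t is the average bootstrap distribution of reference cells whose
    true label is t — the expected mapping ambiguity for good-quality
    cells of that type.
    """
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    child_seeds = ss.spawn(tax.expr.shape[1])
    rows: dict[str, list[pd.Series]] = {t: [] for t in tax.leaves}
    for cell, child in zip(tax.expr.columns, child_seeds):
        res = bootstrap_map(
            tax.expr[cell], tax, n_boot=n_boot, cell_frac=cell_frac,
            marker_frac=marker_frac, seed=child,
        )
        rows[tax.cell_types[cell]].append(res.probabilities)
    mat = pd.DataFrame(
        {t: pd.concat(v, axis=1).mean(axis=1) for t, v in rows.items()}
    ).T.loc[tax.leaves, tax.leaves]
    return mat


def kl_divergence(p, q, epsilon: float = 1e-6) -> float:
    """KL(p||q) in nats after flooring both at ``epsilon`` and renormalizing."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("probability vectors must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probabilities must be non-negative")
    p = np.maximum(p, epsilon)
    q = np.maximum(q, epsilon)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log(p / q)))


@dataclass(frozen=True)
class ConsistencyThresholds:
    kl_max: float = 2.0          # KL divergence above which a cell is inconsistent
    corr_min: float = 0.5        # expression correlation below which inconsistent
    toptwo_min: float = 0.70     # top-two probability sum must exceed this
    ratio_min: float = 2.0       # top1/top2 probability ratio must exceed this


def classify_consistency(
    result: MappingResult,
    refmat: pd.DataFrame,
    expr: pd.Series,
    tax: ReferenceTaxonomy,
    thresholds: ConsistencyThresholds = ConsistencyThresholds(),
) -> MappingResult:
    """Label a mapping as highly/moderately consistent or inconsistent.

    Rule order: (1) KL divergence from the assigned type's reference
    distribution greater than ``kl_max`` -> inconsistent; (2) Pearson
    correlation with the assigned type's mean profile (over the
    root-to-leaf path markers) less than ``corr_min`` -> inconsistent;
    (3) top-two probability sum exceeding ``toptwo_min`` AND top1/top2
    ratio more than ``ratio_min`` -> highly consistent; (4) otherwise
    moderately consistent.  A zero second-highest probability passes the
    ratio test.
    """
    assigned = result.assigned_type
    if assigned not in refmat.index:
        raise ValueError(f"assigned type {assigned!r} missing from reference matrix")
    q = refmat.loc[assigned, result.probabilities.index].to_numpy()
    kl = kl_divergence(result.probabilities.to_numpy(), q)

    markers = tax.path_markers(assigned)
    corr = _pearson(
        expr.loc[markers].to_numpy(dtype=float),
        tax.type_mean_profile(assigned, genes=markers).to_numpy(),
    )

    srt = np.sort(result.probabilities.to_numpy())[::-1]
    top1, top2 = srt[0], srt[1] if srt.size > 1 else 0.0
    ratio = np.inf if top2 == 0 else top1 / top2

    if kl > thresholds.kl_max:
        label = "inconsistent"
    elif corr < thresholds.corr_min:
        label = "inconsistent"
    elif (top1 + top2) > thresholds.toptwo_min and ratio > thresholds.ratio_min:
        label = "highly"
    else:
        label = "moderately"

    result.kl = kl
    result.type_correlation = corr
    result.consistency = label
    return result
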