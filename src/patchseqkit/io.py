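"""File formats, run configuration, and report writing.

Canonical on-disk formats are all plain text: expression as CSV
(genes x cells) or an MTX triplet (matrix.mtx + genes.txt +
cells.txt), sweeps as long-format CSV (time_s, voltage_mV,
stimulus_pA), reference taxonomies as a JSON tree next to the
expression files, and per-cell reports as CSV with a JSON run
manifest.  Every writer round-trips through its paired reader.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .sweepqc import QCConfig, StimulusEpoch, VoltageSweep
from .taxmap import ReferenceTaxonomy

__all__ = [
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_sweep_csv",
    "write_sweep_csv",
    "write_reference_bundle",
    "read_reference_bundle",
    "write_report",
]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults mirror the per-module defaults."""

    seed: int = 0
    expression_path: str | None = None
    sweeps_path: str | None = None
    metadata_path: str | None = None
    reference_path: str | None = None
    qc: dict = field(default_factory=lambda: asdict(QCConfig()))
    nms_cutoff: float = 0.4
    n_boot: int = 100
    cell_frac: float = 0.7
    marker_frac: float = 0.7
    spca_retention: float = 0.01
    spca_penalty: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _log2cpm(counts: pd.DataFrame) -> pd.DataFrame:
    total = counts.sum(axis=0).replace(0, 1.0)
    return np.log2(counts.div(total, axis=1) * 1e6 + 1.0)


def read_expression(path: str | Path, format: str = "auto"):
    """Read a genes x cells count matrix; returns (counts, log2(CPM+1)).

    ``format`` is ``csv``, ``mtx`` (a directory with matrix.mtx,
    genes.txt, cells.txt) or ``auto``.  CPM = counts / column sum x 1e6.
    """
    path = Path(path)
    if format == "auto":
        format = "mtx" if path.is_dir() else "csv"
    if format == "csv":
        try:
            counts = pd.read_csv(path, index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValueError(f"malformed expression CSV {path}: {exc}") from exc
        if counts.empty or counts.index.has_duplicates:
            raise ValueError(f"malformed expression CSV {path}: empty or duplicate genes")
    elif format == "mtx":
        mat = scipy.io.mmread(path / "matrix.mtx")
        genes = (path / "genes.txt").read_text().split()
        cells = (path / "cells.txt").read_text().split()
        mat = scipy.sparse.coo_matrix(mat).toarray()
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(genes)} genes x {len(cells)} cells"
            )
        counts = pd.DataFrame(mat, index=genes, columns=cells)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    return counts, _log2cpm(counts)


def write_expression(counts: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        counts.to_csv(path)
    elif format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", scipy.sparse.coo_matrix(counts.to_numpy()))
        (path / "genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
        (path / "cells.txt").write_text("\n".join(map(str, counts.columns)) + "\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def write_sweep_csv(sweep: VoltageSweep, path: str | Path) -> None:
    """Long-format CSV with an epoch manifest in a JSON sidecar header line."""
    path = Path(path)
    header = json.dumps(
        {
            "start_time": sweep.start_time,
            "dt": sweep.dt,
            "epochs": [asdict(e) for e in sweep.epochs],
        }
    )
    df = pd.DataFrame(
        {"time_s": sweep.time, "voltage_mV": sweep.voltage, "stimulus_pA": sweep.stimulus}
    )
    with open(path, "w") as fh:
        fh.write(f"#{header}\n")
        df.to_csv(fh, index=False)


def read_sweep_csv(path: str | Path) -> VoltageSweep:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}:1: missing sweep metadata header line")
        meta = json.loads(first[1:])
        df = pd.read_csv(fh)
    for col in ("time_s", "voltage_mV", "stimulus_pA"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return VoltageSweep(
        start_time=meta["start_time"],
        dt=meta["dt"],
        voltage=df["voltage_mV"].to_numpy(),
        stimulus=df["stimulus_pA"].to_numpy(),
        epochs=[StimulusEpoch(**e) for e in meta["epochs"]],
    )


def write_reference_bundle(ref: ReferenceTaxonomy, path: str | Path) -> None:
    """Taxonomy tree + branch markers as JSON, expression as CSV, labels as CSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tree = {
        "types_of_class": ref.types_of_class,
        "branch_markers": ref.branch_markers,
        "glial_classes": ref.glial_classes,
    }
    (path / "taxonomy.json").write_text(json.dumps(tree, indent=2))
    ref.expr.to_csv(path / "expression.csv")
    ref.cell_types.rename("cell_type").to_csv(path / "cell_types.csv")


def read_reference_bundle(path: str | Path) -> ReferenceTaxonomy:
    path = Path(path)
    tree = json.loads((path / "taxonomy.json").read_text())
    expr = pd.read_csv(path / "expression.csv", index_col=0)
    labels = pd.read_csv(path / "cell_types.csv", index_col=0)["cell_type"]
    return ReferenceTaxonomy(
        expr=expr,
        cell_types=labels,
        types_of_class=tree["types_of_class"],
        branch_markers=tree["branch_markers"],
        glial_classes=tree["glial_classes"],
    )


def write_report(
    tables: dict[str, pd.DataFrame],
    path: str | Path,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Join per-cell result tables on cell id and write CSV + JSON manifest.

    ``tables`` maps a module name to a per-cell DataFrame indexed by
    cell id; overlapping column names are prefixed.  Conflicting ids
    (duplicates within one table) raise with the offenders listed.
    """
    if not tables:
        raise ValueError("no module results to report")
    joined: pd.DataFrame | None = None
    for name, df in tables.items():
        if df.index.has_duplicates:
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"table {name!r} has conflicting cell ids: {dupes}")
        pref = df.add_prefix(f"{name}.")
        joined = pref if joined is None else joined.join(pref, how="outer")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joined.index.name = "cell_id"
    joined.to_csv(path / "report.csv")
    import patchseqkit

    manifest = {
        "version": patchseqkit.__version__,
        "config": asdict(config) if config is not None else None,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return joined
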