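"""Plain-text and NIfTI I/O.

TSV is the canonical exchange format: subject series as one header row
of node labels plus one row per timepoint; truth graphs and causal
graphs as edge lists; degree tables as node-indexed tables.  NIfTI
volumes and masks are an optional front-end (via nibabel) that
immediately reduces to :class:`~mgca.models.RoiTimeSeries`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import GroundTruthGraph, RoiTimeSeries
from .significance import CausalGraph

__all__ = [
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "write_truth_graph_tsv",
    "write_graph_tsv",
    "read_graph_tsv",
    "write_graphml",
    "load_nifti_roi_timeseries",
    "write_json",
]


def read_timeseries_tsv(
    path, dt: float = 2.0, subject_id: str = "", group: str = ""
) -> RoiTimeSeries:
    """Read a header + numeric-rows TSV into an ROI time series.

    Ragged rows and non-numeric cells are reported with their row and
    column; a header-only file is an error.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header:
            raise ValueError(f"{path}: empty file")
        labels = header.split("\t")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(labels):
                raise ValueError(
                    f"{path}: line {lineno} has {len(cells)} cells, "
                    f"expected {len(labels)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                for col, cell in enumerate(cells):
                    try:
                        float(cell)
                    except ValueError:
                        raise ValueError(
                            f"{path}: non-numeric cell at line {lineno}, "
                            f"column {col + 1} ({labels[col]!r}): {cell!r}"
                        ) from exc
                raise
    if not rows:
        raise ValueError(f"{path}: no data rows after the header")
    data = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[0]
        raise ValueError(
            f"{path}: non-finite value at data row {bad[0] + 1}, "
            f"column {bad[1] + 1} ({labels[bad[1]]!r})"
        )
    return RoiTimeSeries(
        data=data,
        dt=dt,
        node_labels=tuple(labels),
        subject_id=subject_id or path.stem,
        group=group,
    )


def write_timeseries_tsv(ts: RoiTimeSeries, path) -> None:
    """Write a series as a labeled TSV that round-trips bit-identically."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(ts.node_labels) + "\n")
        for row in ts.data:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def write_truth_graph_tsv(graph: GroundTruthGraph, path) -> None:
    """Write a ground-truth coupling graph as a (source, target, lag,
    coefficient) edge list."""
    rows = [
        {"source": src, "target": tgt, "lag": lag, "coefficient": coef}
        for (src, tgt), lags in sorted(graph.edges.items())
        for lag, coef in sorted(lags.items())
    ]
    pd.DataFrame(rows, columns=["source", "target", "lag", "coefficient"]).to_csv(
        path, sep="\t", index=False
    )


def write_graph_tsv(graph: CausalGraph, path) -> None:
    graph.edges.to_csv(path, sep="\t", index=False)


def read_graph_tsv(path, alpha: float = 0.01, statistic: str = "doi") -> CausalGraph:
    edges = pd.read_csv(path, sep="\t")
    labels = tuple(dict.fromkeys(list(edges["source"]) + list(edges["target"])))
    return CausalGraph(
        node_labels=labels, edges=edges, alpha=alpha, statistic=statistic
    )


def write_graphml(graph: CausalGraph, path) -> None:
    """Export the significant-edge graph for external viewers."""
    import networkx as nx

    nx.write_graphml(graph.to_networkx(), path)


def load_nifti_roi_timeseries(
    img_path, mask_paths: dict, dt: float | None = None, **kwargs
) -> RoiTimeSeries:
    """Extract ROI-mean series from a 4D NIfTI and a dict of mask NIfTIs.

    ``dt`` defaults to the TR recorded in the image header.
    """
    import nibabel as nib

    from .seed_fc import extract_roi_timeseries

    img = nib.load(str(img_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{img_path}: expected a 4D image, got {data.ndim}D")
    if dt is None:
        dt = float(img.header.get_zooms()[3])
    masks = {
        label: np.asanyarray(nib.load(str(p)).dataobj) > 0
        for label, p in mask_paths.items()
    }
    return extract_roi_timeseries(data, masks, dt=dt, **kwargs)


def write_stat_map_nifti(values: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a 3D statistic map (t, p, q or mask) as NIfTI."""
    import nibabel as nib

    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("stat maps must be 3D")
    nib.save(nib.Nifti1Image(values, affine if affine is not None else np.eye(4)), str(path))


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
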