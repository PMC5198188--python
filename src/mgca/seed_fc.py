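"""Seed-based functional connectivity maps and their group statistics.

The first stage of the analysis: correlate every unit (voxel or ROI)
with a seed region's mean time course, variance-stabilize with Fisher's
Z, and locate units with significant connectivity via one- or
two-sample t maps thresholded by Benjamini-Hochberg FDR and a minimum
cluster extent.  The surviving regions define the nodes of the directed
network analysed by :mod:`mgca.spectral`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .models import RoiTimeSeries

__all__ = [
    "FcMap",
    "GroupStatMap",
    "seed_correlation_map",
    "fisher_z",
    "inverse_fisher_z",
    "one_sample_t_map",
    "two_sample_t_map",
    "fdr_correct",
    "cluster_filter",
    "extract_roi_timeseries",
]


@dataclass(frozen=True)
class FcMap:
    """Per-unit seed correlation and its Fisher-Z transform.

    ``r`` is NaN (with ``valid`` False) for constant units, where the
    correlation is undefined; ``z`` is ``+/-inf`` where ``|r| == 1``.
    """

    r: np.ndarray
    z: np.ndarray
    valid: np.ndarray
    seed_label: str = "seed"
    unit_ids: tuple = ()


@dataclass(frozen=True)
class GroupStatMap:
    """Per-unit t statistic and two-sided p value for a group contrast."""

    t: np.ndarray
    p: np.ndarray
    df: int
    valid: np.ndarray
    q: np.ndarray | None = None
    mask: np.ndarray | None = None
    clusters: pd.DataFrame | None = field(default=None, compare=False)


def seed_correlation_map(
    units: np.ndarray, seed_ts: np.ndarray, seed_label: str = "seed"
) -> FcMap:
    """Pearson correlation of every unit's series with the seed series.

    Constant units yield NaN correlations and are flagged, never
    silently zeroed.
    """
    units = np.atleast_2d(np.asarray(units, dtype=float))
    seed = np.asarray(seed_ts, dtype=float).ravel()
    if units.shape[0] != seed.shape[0]:
        raise ValueError("units and seed series must share the time axis")
    if units.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    seed_c = seed - seed.mean()
    seed_norm = np.sqrt(np.sum(seed_c**2))
    if seed_norm == 0:
        raise ValueError("seed series is constant")
    unit_c = units - units.mean(axis=0, keepdims=True)
    unit_norm = np.sqrt(np.sum(unit_c**2, axis=0))
    valid = unit_norm > 0
    r = np.full(units.shape[1], np.nan)
    r[valid] = (seed_c @ unit_c[:, valid]) / (seed_norm * unit_norm[valid])
    np.clip(r, -1.0, 1.0, out=r)
    if not np.all(valid):
        warnings.warn(
            f"{np.count_nonzero(~valid)} constant unit(s): correlation undefined",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    return FcMap(r=r, z=z, valid=valid, seed_label=seed_label)


def fisher_z(r):
    """Fisher's variance-stabilizing transform ``0.5 * ln((1+r)/(1-r))``.

    Defined for ``|r| < 1``; raises otherwise.  Odd and strictly
    increasing; inverted exactly by :func:`inverse_fisher_z`.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def inverse_fisher_z(z):
    """Inverse of :func:`fisher_z` (tanh)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


def one_sample_t_map(zmaps: np.ndarray) -> GroupStatMap:
    """Two-sided one-sample t-test of each unit's Z values against zero."""
    zmaps = np.atleast_2d(np.asarray(zmaps, dtype=float))
    s = zmaps.shape[0]
    if s < 2:
        raise ValueError("need at least 2 subjects")
    mean = zmaps.mean(axis=0)
    sd = zmaps.std(axis=0, ddof=1)
    valid = sd > 0
    t = np.full(zmaps.shape[1], np.nan)
    t[valid] = mean[valid] / (sd[valid] / np.sqrt(s))
    df = s - 1
    p = np.full_like(t, np.nan)
    p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df)
    if not np.all(valid):
        warnings.warn(
            f"{np.count_nonzero(~valid)} zero-variance unit(s) flagged", stacklevel=2
        )
    return GroupStatMap(t=t, p=p, df=df, valid=valid)


def two_sample_t_map(zmaps_a: np.ndarray, zmaps_b: np.ndarray) -> GroupStatMap:
    """Pooled-variance two-sample t-test per unit (A minus B), two-sided."""
    a = np.atleast_2d(np.asarray(zmaps_a, dtype=float))
    b = np.atleast_2d(np.asarray(zmaps_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the unit axis")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    df = na + nb - 2
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    pooled = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    valid = se > 0
    t = np.full(a.shape[1], np.nan)
    p = np.full(a.shape[1], np.nan)
    t[valid] = mean_diff[valid] / se[valid]
    p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df)
    # zero pooled variance with equal means is a well-defined t = 0
    degenerate = (~valid) & (mean_diff == 0)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    valid = valid | degenerate
    if not np.all(valid):
        warnings.warn(
            f"{np.count_nonzero(~valid)} unit(s) with zero pooled variance "
            "and unequal means flagged",
            stacklevel=2,
        )
    return GroupStatMap(t=t, p=p, df=df, valid=valid)


def fdr_correct(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(reject, q_values)``.  NaN p values are never rejected and
    propagate as NaN adjusted values.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p values must lie in [0, 1]")
    reject = np.zeros(p.size, dtype=bool)
    qvals = np.full(p.size, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        rej, adj, *_ = multipletests(p[finite], alpha=q, method="fdr_bh")
        reject[finite] = rej
        qvals[finite] = adj
    return reject, qvals


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def cluster_filter(
    mask: np.ndarray, min_voxels: int = 10, connectivity: int = 18
) -> tuple[np.ndarray, pd.DataFrame]:
    """Remove connected components of ``min_voxels`` or fewer voxels.

    The extent rule is strict ("cluster > 10 voxels"): a component
    survives only if its size is at least ``min_voxels + 1``.  Returns
    the filtered mask and a cluster table (id, size, centroid).
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(
        mask.ndim, _CONNECTIVITY_RANK[connectivity]
    )
    labels, n_clusters = ndimage.label(mask, structure=structure)
    rows = []
    keep = np.zeros_like(mask)
    for cid in range(1, n_clusters + 1):
        component = labels == cid
        size = int(component.sum())
        if size > min_voxels:
            keep |= component
            centroid = tuple(np.round(c, 2) for c in ndimage.center_of_mass(component))
            rows.append({"cluster_id": cid, "size": size, "centroid": centroid})
    table = pd.DataFrame(rows, columns=["cluster_id", "size", "centroid"])
    return keep, table


def extract_roi_timeseries(
    img4d: np.ndarray,
    roi_masks: dict,
    dt: float,
    subject_id: str = "",
    group: str = "",
) -> RoiTimeSeries:
    """Average a 4D image over each ROI mask to form one series per ROI.

    ``img4d`` follows the NIfTI axis convention: spatial axes first,
    time last.  ``roi_masks`` maps ROI labels to boolean arrays on the
    spatial grid; an empty mask is an error naming the ROI.
    """
    img = np.asarray(img4d, dtype=float)
    spatial_shape = img.shape[:-1]
    columns = []
    labels = []
    for label, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != spatial_shape:
            raise ValueError(f"mask for ROI {label!r} does not match the image grid")
        if not mask.any():
            raise ValueError(f"ROI {label!r} has an empty mask")
        columns.append(img[mask].mean(axis=0))
        labels.append(label)
    return RoiTimeSeries(
        data=np.column_stack(columns),
        dt=dt,
        node_labels=tuple(labels),
        subject_id=subject_id,
        group=group,
    )
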