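"""Synthetic BOLD-like data from ground-truth directed VAR networks.

No public resting-state dataset accompanies the analysis this package
implements, so every downstream stage is exercised on simulated data
whose directed structure is known exactly.  The generator emulates the
study conditions of a typical resting-state group design: TR = 2 s,
~190 usable volumes per subject, 19 subjects per group, stationary
multichannel signals driven by directed VAR couplings, optional
hemodynamic blurring, and band-limited signal plus noise.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .models import GroundTruthGraph, RoiTimeSeries, VarModel

__all__ = [
    "simulate_var",
    "double_gamma_hrf",
    "apply_hemodynamics",
    "make_two_group_dataset",
    "make_seed_fc_phantom",
    "chain_model",
    "coupled_pair_model",
]

#: Default number of burn-in samples discarded before the recorded series.
DEFAULT_BURN_IN = 500


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_var(
    model: VarModel,
    n_timepoints: int,
    burn_in: int = DEFAULT_BURN_IN,
    seed=None,
    dt: float = 2.0,
    subject_id: str = "",
    group: str = "",
) -> RoiTimeSeries:
    """Draw one realization of a stationary VAR process.

    The recursion ``x_t = sum_k A_k x_{t-k} + e_t`` is run for
    ``burn_in + n_timepoints`` steps from a zero initial state with
    Gaussian innovations ``e_t ~ N(0, noise_cov)``; the burn-in
    samples are discarded so the retained block is (approximately)
    a draw from the stationary distribution.

    Parameters
    ----------
    model : VarModel
        Must be stationary with positive-definite innovation covariance.
    n_timepoints : int
        Number of retained samples ``T``.
    burn_in : int
        Transient samples discarded before recording.
    seed : int, Generator or None
        Randomness source; a fixed integer gives bit-identical output.
    dt : float
        Sampling interval attached to the output (seconds).
    """
    model.require_simulable()
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be positive")
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    rng = _as_rng(seed)
    p, n = model.order, model.n_nodes
    chol = model.noise_cholesky()
    total = burn_in + n_timepoints
    innovations = rng.standard_normal((total, n)) @ chol.T
    x = np.zeros((total + p, n))
    coeffs = model.coeffs
    for t in range(total):
        acc = innovations[t]
        for k in range(p):
            acc = acc + coeffs[k] @ x[t + p - 1 - k]
        x[t + p] = acc
    return RoiTimeSeries(
        data=x[p + burn_in :],
        dt=dt,
        node_labels=model.node_labels,
        subject_id=subject_id,
        group=group,
    )


def _gamma_pdf(t: np.ndarray, shape: float) -> np.ndarray:
    """Gamma density with unit rate, zero for t <= 0."""
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp((shape - 1) * np.log(tp) - tp - gammaln(shape))
    return out


def double_gamma_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit-sum normalized.

    Positive gamma lobe peaking near 5 s, undershoot gamma centred near
    16 s with 1/6 relative amplitude, sampled every ``dt`` seconds over
    ``duration`` seconds of support.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration + dt / 2, dt)
    kernel = _gamma_pdf(t, 6.0) - _gamma_pdf(t, 16.0) / 6.0
    total = kernel.sum()
    if total == 0:
        raise ValueError("degenerate HRF sampling grid")
    return kernel / total


def apply_hemodynamics(
    ts: RoiTimeSeries,
    native_dt: float,
    target_dt: float,
    discard_edge: bool = False,
) -> RoiTimeSeries:
    """Convolve each channel with the canonical HRF and decimate to the TR.

    The series is assumed sampled at ``native_dt``; each channel is
    convolved ("full" convolution truncated to the input length) with
    the double-gamma kernel sampled at ``native_dt`` and then decimated
    by the integer factor ``target_dt / native_dt``.  Hemodynamic
    blurring of this kind is the confound that motivates testing link
    direction with the difference-of-influence statistic downstream.

    With ``discard_edge=True`` the first kernel-length output samples
    (where the convolution is still filling) are dropped.
    """
    if target_dt < native_dt:
        raise ValueError("target_dt must be >= native_dt")
    factor = target_dt / native_dt
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("native_dt must divide target_dt")
    factor = int(round(factor))
    kernel = double_gamma_hrf(native_dt)
    t_in = ts.n_timepoints
    blurred = np.empty_like(ts.data)
    for j in range(ts.n_nodes):
        blurred[:, j] = np.convolve(ts.data[:, j], kernel)[:t_in]
    start = len(kernel) if discard_edge else 0
    blurred = blurred[start:]
    decimated = blurred[::factor]
    return RoiTimeSeries(
        data=decimated,
        dt=target_dt,
        node_labels=ts.node_labels,
        subject_id=ts.subject_id,
        group=ts.group,
    )


def make_two_group_dataset(
    model_a: VarModel,
    model_b: VarModel,
    n_per_group: int = 19,
    n_timepoints: int = 190,
    seed: int = 0,
    dt: float = 2.0,
    group_labels: tuple[str, str] = ("groupA", "groupB"),
    burn_in: int = DEFAULT_BURN_IN,
) -> tuple[list[RoiTimeSeries], tuple[GroundTruthGraph, GroundTruthGraph]]:
    """Simulate a two-group resting-state design with known ground truth.

    Defaults mirror a 19-versus-19 subject design with 190 usable
    volumes at TR = 2 s.  Per-subject seeds are ``seed + index`` so the
    streams are reproducible yet independent.

    Returns the flat subject list (group A first) and the pair of
    ground-truth coupling graphs.
    """
    if model_a.n_nodes != model_b.n_nodes or model_a.node_labels != model_b.node_labels:
        raise ValueError("the two group models must share nodes and labels")
    subjects: list[RoiTimeSeries] = []
    idx = 0
    for model, group in ((model_a, group_labels[0]), (model_b, group_labels[1])):
        for s in range(n_per_group):
            subjects.append(
                simulate_var(
                    model,
                    n_timepoints,
                    burn_in=burn_in,
                    seed=seed + idx,
                    dt=dt,
                    subject_id=f"{group}-{s + 1:02d}",
                    group=group,
                )
            )
            idx += 1
    truth = (GroundTruthGraph.from_model(model_a), GroundTruthGraph.from_model(model_b))
    return subjects, truth


def make_seed_fc_phantom(
    n_voxels: int,
    n_timepoints: int,
    loading_map: np.ndarray,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel phantom with known voxel-seed correlations.

    Each voxel is ``loading * latent + sqrt(1 - loading^2) * noise`` with
    a shared standard-normal latent series, so the expected correlation
    of voxel ``v`` with the returned seed series equals ``loading_v``.

    Returns ``(voxels, seed_series)`` with voxels of shape ``(T, V)``.
    """
    loadings = np.broadcast_to(np.asarray(loading_map, dtype=float), (n_voxels,))
    if np.any(np.abs(loadings) > 1):
        raise ValueError("loadings must lie in [-1, 1]")
    rng = _as_rng(seed)
    latent = rng.standard_normal(n_timepoints)
    noise = rng.standard_normal((n_timepoints, n_voxels))
    voxels = latent[:, None] * loadings[None, :] + noise * np.sqrt(
        1.0 - loadings[None, :] ** 2
    )
    return voxels, latent


def chain_model(
    coupling: float = 0.4,
    decay: float = 0.5,
    n_nodes: int = 3,
    noise_scale: float = 1.0,
) -> VarModel:
    """VAR(1) chain ``x1 -> x2 -> ... -> xN`` with uniform lag-1 coupling.

    A standard test-bed: the only directed influences are along the
    chain, so any apparent x1 -> x3 link is purely mediated and should
    be suppressed by partial-coherence weighting.
    """
    coeffs = np.zeros((1, n_nodes, n_nodes))
    np.fill_diagonal(coeffs[0], decay)
    for i in range(1, n_nodes):
        coeffs[0, i, i - 1] = coupling
    return VarModel(
        coeffs=coeffs,
        noise_cov=noise_scale * np.eye(n_nodes),
        node_labels=tuple(f"x{i + 1}" for i in range(n_nodes)),
    )


def coupled_pair_model(coupling: float = 0.4, decay: float = 0.5) -> VarModel:
    """Bivariate triangular VAR(1): node 1 drives node 2, never the reverse."""
    return chain_model(coupling=coupling, decay=decay, n_nodes=2)
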