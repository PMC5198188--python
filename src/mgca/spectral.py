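"""The multivariate Granger-causality core: VAR estimation and the
frequency-domain influence measures built on it.

Given a fitted VAR(p) with coefficient matrices ``A_1 ... A_p`` and
innovation covariance ``Sigma``, define at frequency ``f``

    A(f) = I - sum_k A_k exp(-i 2 pi f k dt),     H(f) = A(f)^{-1}.

From the transfer matrix ``H`` this module computes

* DTF     — ``dtf^2[f,i,j] = |H_ij|^2 / sum_m |H_im|^2`` (per-target,
  per-frequency normalization; rows of squared DTF sum to 1),
* ffDTF   — the same numerator normalized over the whole frequency
  grid, making values comparable across frequencies,
* partial coherence — from the inverse spectral matrix
  ``P = S(f)^{-1}`` with ``S(f) = H Sigma H*``:
  ``pcoh^2[f,i,j] = |P_ij|^2 / (P_ii P_jj)``,
* dDTF    — ``ffDTF * pcoh``, which suppresses influences mediated
  through third nodes, and
* doi     — the difference of influence ``ddtf_band[i,j] - ddtf_band[j,i]``
  on band-averaged dDTF, used to establish a dominant direction and to
  guard against spurious links from hemodynamic blurring.

Index convention: ``[frequency, target, source]`` — entry ``[f, i, j]``
quantifies the influence of source ``j`` on target ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import RoiTimeSeries, VarModel

__all__ = [
    "SpectralSet",
    "EdgeStats",
    "fit_var",
    "select_order",
    "default_freqs",
    "transfer_function",
    "dtf",
    "ffdtf",
    "spectral_density",
    "partial_coherence",
    "ddtf",
    "band_average",
    "doi",
    "edge_statistics",
]

#: Default frequency-grid size on (0, Nyquist].
DEFAULT_N_FREQS = 129
#: Default analysis band in Hz (matches the preprocessing filter band).
DEFAULT_BAND = (0.01, 0.08)


@dataclass(frozen=True)
class SpectralSet:
    """All frequency-domain quantities of one VAR model on one grid.

    Arrays are ``(F, N, N)`` indexed ``[frequency, target, source]``.
    """

    freqs: np.ndarray
    H: np.ndarray
    S: np.ndarray
    pcoh: np.ndarray
    dtf: np.ndarray
    ffdtf: np.ndarray
    ddtf: np.ndarray
    node_labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class EdgeStats:
    """Band-averaged directed-edge statistics of one subject/series."""

    ddtf_band: np.ndarray  # (N, N), [target, source], zero diagonal
    doi: np.ndarray  # (N, N), antisymmetric
    model: VarModel
    spectra: SpectralSet

    @property
    def node_labels(self) -> tuple[str, ...]:
        return self.model.node_labels


def _standardize(data: np.ndarray) -> np.ndarray:
    centered = data - data.mean(axis=0, keepdims=True)
    sd = centered.std(axis=0, ddof=0)
    # relative floor: catches channels that are constant up to fp residue
    floor = 1e-10 * max(1.0, float(np.abs(data).max(initial=0.0)))
    if np.any(sd <= floor):
        bad = [i for i, s in enumerate(sd) if s <= floor]
        raise ValueError(f"cannot standardize (near-)constant channel(s) {bad}")
    return centered / sd


def fit_var(ts: RoiTimeSeries, order: int, standardize: bool = True) -> VarModel:
    """Estimate a VAR(p) by equation-wise ordinary least squares.

    Channels are z-scored first (``standardize=True``, the default) so
    coefficients are comparable across ROIs with different signal
    scales.  The regression includes an intercept; the innovation
    covariance is the degrees-of-freedom-adjusted residual covariance.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    t, n = ts.data.shape
    n_params = n * order + 1
    if t <= n * order + 1:
        raise ValueError(
            f"insufficient data: T={t} must exceed N*p + 1 = {n * order + 1}"
        )
    data = _standardize(ts.data) if standardize else np.asarray(ts.data, dtype=float)
    y = data[order:]
    t_eff = t - order
    design = np.empty((t_eff, n_params))
    design[:, 0] = 1.0
    for k in range(1, order + 1):
        design[:, 1 + (k - 1) * n : 1 + k * n] = data[order - k : t - k]
    rank = np.linalg.matrix_rank(design)
    if rank < n_params:
        raise ValueError("singular regressor matrix in VAR fit")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    coeffs = np.stack(
        [beta[1 + (k - 1) * n : 1 + k * n, :].T for k in range(1, order + 1)]
    )
    resid = y - design @ beta
    dof = max(t_eff - n_params, 1)
    sigma = resid.T @ resid / dof
    return VarModel(coeffs=coeffs, noise_cov=sigma, node_labels=ts.node_labels)


def select_order(
    ts: RoiTimeSeries,
    max_order: int = 20,
    criterion: str = "bic",
    standardize: bool = True,
) -> int:
    """Pick the VAR order minimizing AIC or BIC over ``1 ... max_order``.

    All candidate orders are scored on the same effective sample
    (conditioning on the first ``max_order`` values) so the criteria are
    comparable.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    criterion = criterion.lower()
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    t, n = ts.data.shape
    data = _standardize(ts.data) if standardize else np.asarray(ts.data, dtype=float)
    t_eff = t - max_order
    if t_eff <= n * max_order + 1:
        raise ValueError("series too short for the requested max_order")
    y = data[max_order:]
    penalty_scale = 2.0 if criterion == "aic" else np.log(t_eff)
    best_order, best_score = 1, np.inf
    for p in range(1, max_order + 1):
        design = np.empty((t_eff, n * p + 1))
        design[:, 0] = 1.0
        for k in range(1, p + 1):
            design[:, 1 + (k - 1) * n : 1 + k * n] = data[max_order - k : t - k]
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        sigma = resid.T @ resid / t_eff  # ML estimate for the IC
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        score = logdet + penalty_scale * (p * n * n) / t_eff
        if score < best_score - 1e-12:
            best_order, best_score = p, score
    return best_order


def default_freqs(dt: float, n_freqs: int = DEFAULT_N_FREQS) -> np.ndarray:
    """Uniform frequency grid of ``n_freqs`` points on (0, Nyquist]."""
    nyq = 0.5 / dt
    return nyq * np.arange(1, n_freqs + 1) / n_freqs


def transfer_function(model: VarModel, freqs: np.ndarray, dt: float) -> np.ndarray:
    """Transfer matrices ``H(f) = (I - sum_k A_k e^{-i 2 pi f k dt})^{-1}``."""
    freqs = np.asarray(freqs, dtype=float)
    nyq = 0.5 / dt
    if np.any(freqs <= 0) or np.any(freqs > nyq + 1e-12):
        raise ValueError("frequencies must lie in (0, Nyquist]")
    p, n = model.order, model.n_nodes
    lags = np.arange(1, p + 1)
    phases = np.exp(-2j * np.pi * np.outer(freqs, lags) * dt)  # (F, p)
    a_f = np.eye(n)[None, :, :] - np.einsum("fk,kij->fij", phases, model.coeffs)
    try:
        return np.linalg.inv(a_f)
    except np.linalg.LinAlgError:
        for f, a in zip(freqs, a_f):
            if abs(np.linalg.det(a)) < 1e-300:
                raise ValueError(f"singular spectral matrix A(f) at f = {f} Hz")
        raise


def dtf(h: np.ndarray) -> np.ndarray:
    """Directed transfer function, normalized per target and frequency.

    ``dtf[f, i, j] = |H_ij| / sqrt(sum_m |H_im|^2)``; each target row of
    squared values sums to one at every frequency.
    """
    mag2 = np.abs(h) ** 2
    row = mag2.sum(axis=2, keepdims=True)
    if np.any(row == 0):
        raise ValueError("zero transfer-function row: DTF undefined")
    return np.sqrt(mag2 / row)


def ffdtf(h: np.ndarray) -> np.ndarray:
    """Full-frequency DTF: denominator pooled over the entire grid.

    ``ffdtf^2[f, i, j] = |H_ij(f)|^2 / sum_{f'} sum_m |H_im(f')|^2``.
    """
    mag2 = np.abs(h) ** 2
    denom = mag2.sum(axis=(0, 2))  # per target
    if np.any(denom == 0):
        raise ValueError("zero pooled transfer-function row: ffDTF undefined")
    return np.sqrt(mag2 / denom[None, :, None])


def spectral_density(h: np.ndarray, noise_cov: np.ndarray) -> np.ndarray:
    """Parametric spectral density ``S(f) = H(f) Sigma H(f)*`` (Hermitian)."""
    return h @ noise_cov @ np.conj(np.swapaxes(h, 1, 2))


def partial_coherence(s: np.ndarray) -> np.ndarray:
    """Partial coherence from the inverse spectral matrix.

    With ``P(f) = S(f)^{-1}``: ``pcoh[f,i,j] = |P_ij| / sqrt(P_ii P_jj)``
    — the frequency-domain association of i and j conditional on all
    other channels.  Symmetric in (i, j) with unit diagonal.
    """
    try:
        p = np.linalg.inv(s)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular spectral density matrix") from exc
    diag = np.real(np.einsum("fii->fi", p))
    if np.any(diag <= 0):
        raise ValueError("inverse spectral matrix has a non-positive diagonal")
    denom = np.sqrt(diag[:, :, None] * diag[:, None, :])
    return np.clip(np.abs(p) / denom, 0.0, 1.0)


def ddtf(
    model: VarModel, freqs: np.ndarray | None = None, dt: float = 2.0
) -> SpectralSet:
    """Compute the complete spectral set of a model: H, S, DTF, ffDTF,
    partial coherence and dDTF (= ffDTF * partial coherence)."""
    if freqs is None:
        freqs = default_freqs(dt)
    h = transfer_function(model, freqs, dt)
    s = spectral_density(h, model.noise_cov)
    pcoh = partial_coherence(s)
    dtf_ = dtf(h)
    ff = ffdtf(h)
    return SpectralSet(
        freqs=np.asarray(freqs, dtype=float),
        H=h,
        S=s,
        pcoh=pcoh,
        dtf=dtf_,
        ffdtf=ff,
        ddtf=ff * pcoh,
        node_labels=model.node_labels,
    )


def band_average(
    spec: SpectralSet | np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Arithmetic mean of dDTF over grid frequencies in the closed band.

    Accepts a :class:`SpectralSet` (its dDTF is averaged) or a raw
    ``(F, N, N)`` array with an explicit ``freqs`` grid.  The diagonal
    of the result is set to zero: self-influence is not an edge.
    """
    if isinstance(spec, SpectralSet):
        values, grid = spec.ddtf, spec.freqs
    else:
        if freqs is None:
            raise ValueError("freqs required when passing a raw array")
        values, grid = np.asarray(spec), np.asarray(freqs, dtype=float)
    low, high = band
    sel = (grid >= low) & (grid <= high)
    if not sel.any():
        raise ValueError(f"band {band} contains no grid frequency")
    out = values[sel].mean(axis=0)
    np.fill_diagonal(out, 0.0)
    return out


def doi(edge_matrix: np.ndarray) -> np.ndarray:
    """Difference of influence: ``doi[i, j] = edge[i, j] - edge[j, i]``.

    Antisymmetric by construction; a positive ``doi[i, j]`` means the
    influence of source j on target i dominates the reverse direction.
    """
    edge_matrix = np.asarray(edge_matrix, dtype=float)
    if np.any(edge_matrix < 0):
        raise ValueError("edge matrix entries must be non-negative")
    if np.any(np.diag(edge_matrix) != 0):
        raise ValueError("edge matrix diagonal must be zero")
    return edge_matrix - edge_matrix.T


def edge_statistics(
    ts: RoiTimeSeries,
    order: int | None = None,
    max_order: int = 20,
    n_freqs: int = DEFAULT_N_FREQS,
    band: tuple[float, float] = DEFAULT_BAND,
) -> EdgeStats:
    """Fit a VAR to one series and reduce it to band-averaged edge stats.

    ``order=None`` selects the order by BIC over ``1 ... max_order``.
    """
    if order is None:
        order = select_order(ts, max_order=max_order, criterion="bic")
    model = fit_var(ts, order)
    freqs = default_freqs(ts.dt, n_freqs)
    spec = ddtf(model, freqs, ts.dt)
    edges = band_average(spec, band)
    return EdgeStats(ddtf_band=edges, doi=doi(edges), model=model, spectra=spec)
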