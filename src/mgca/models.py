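"""Core containers shared by every stage of the pipeline.

The analysis operates on multichannel region-of-interest (ROI) time
series modelled as vector autoregressions.  Two containers carry the
data through the pipeline:

``VarModel``
    An order-``p`` vector autoregression: ``p`` coefficient matrices
    plus an innovation covariance.  It serves both as ground truth for
    simulation and as the estimate produced by :func:`mgca.spectral.fit_var`.

``RoiTimeSeries``
    One subject's ``T x N`` matrix of ROI signals together with the
    sampling interval (the scanner TR, in seconds).

Index convention, used everywhere in this package: coefficient and
spectral matrices are indexed ``[target, source]`` — entry ``[i, j]``
is the influence of source node ``j`` on target node ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class StationarityError(ValueError):
    """Raised when a VAR model is not stable enough to simulate from."""


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Stack VAR(p) lag matrices into the VAR(1) companion form."""
    p, n, _ = coeffs.shape
    top = np.concatenate(list(coeffs), axis=1)
    if p == 1:
        return top
    lower = np.eye(n * (p - 1), n * p)
    return np.vstack([top, lower])


@dataclass(frozen=True)
class VarModel:
    """Vector autoregression of order ``p`` on ``N`` nodes.

    Parameters
    ----------
    coeffs : ndarray, shape (p, N, N)
        Lag coefficient matrices; ``coeffs[k - 1, i, j]`` is the lag-``k``
        influence of node ``j`` on node ``i``.
    noise_cov : ndarray, shape (N, N)
        Symmetric positive-definite innovation covariance.
    node_labels : tuple of str
        One label per node.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        coeffs = np.atleast_3d(np.asarray(self.coeffs, dtype=float))
        if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
            raise ValueError("coeffs must have shape (p, N, N)")
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("coefficient matrices must be finite")
        noise_cov = np.asarray(self.noise_cov, dtype=float)
        n = coeffs.shape[1]
        if noise_cov.shape != (n, n):
            raise ValueError(f"noise_cov must be {n}x{n}")
        if not np.allclose(noise_cov, noise_cov.T, atol=1e-10):
            raise ValueError("noise_cov must be symmetric")
        labels = tuple(self.node_labels) or tuple(f"node{i}" for i in range(n))
        if len(labels) != n:
            raise ValueError("node_labels length must match N")
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "noise_cov", noise_cov)
        object.__setattr__(self, "node_labels", labels)

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.coeffs.shape[1]

    @property
    def spectral_radius(self) -> float:
        """Largest eigenvalue magnitude of the companion matrix."""
        return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(self.coeffs)))))

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0

    def noise_cholesky(self) -> np.ndarray:
        """Lower Cholesky factor of the innovation covariance.

        Raises ``ValueError`` if the covariance is not positive definite.
        """
        try:
            return np.linalg.cholesky(self.noise_cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("noise_cov must be positive definite") from exc

    def require_simulable(self) -> None:
        """Validate the invariants needed before simulating from the model."""
        if not self.is_stable:
            raise StationarityError(
                f"VAR model is not stationary (spectral radius "
                f"{self.spectral_radius:.4f} >= 1)"
            )
        self.noise_cholesky()


@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's ``T x N`` matrix of ROI signals sampled every ``dt`` seconds."""

    data: np.ndarray
    dt: float
    node_labels: tuple[str, ...] = ()
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(data)):
            bad = np.argwhere(~np.isfinite(data))[0]
            raise ValueError(
                f"time series contains a non-finite value at row {bad[0]}, "
                f"column {bad[1]}"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        labels = tuple(self.node_labels) or tuple(
            f"node{i}" for i in range(data.shape[1])
        )
        if len(labels) != data.shape[1]:
            raise ValueError("node_labels length must match the number of columns")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        """Copy of this series with the signal matrix replaced."""
        return replace(self, data=data)


@dataclass(frozen=True)
class GroundTruthGraph:
    """Truth table of directed lag couplings used in recovery tests.

    ``edges`` maps ``(source, target)`` pairs to ``{lag: coefficient}``;
    self-loops (diagonal coefficients) are not stored.
    """

    node_labels: tuple[str, ...]
    edges: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.node_labels)
        for (src, tgt) in self.edges:
            if src not in labels or tgt not in labels:
                raise ValueError(f"edge ({src}, {tgt}) references unknown node")
            if src == tgt:
                raise ValueError("self-loops are not stored in the truth graph")

    @classmethod
    def from_model(cls, model: VarModel) -> "GroundTruthGraph":
        """Collect every nonzero off-diagonal lag coefficient of a model."""
        edges: dict = {}
        labels = model.node_labels
        for k in range(model.order):
            for i in range(model.n_nodes):
                for j in range(model.n_nodes):
                    if i == j:
                        continue
                    coef = model.coeffs[k, i, j]
                    if coef != 0.0:
                        edges.setdefault((labels[j], labels[i]), {})[k + 1] = coef
        return cls(node_labels=labels, edges=edges)

    @property
    def edge_set(self) -> set:
        return set(self.edges)

    def __contains__(self, edge) -> bool:
        return tuple(edge) in self.edges
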