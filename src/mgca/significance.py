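"""Surrogate-data and permutation inference for directed links.

Link-level significance uses phase-randomized surrogates: each channel's
Fourier amplitude spectrum is kept exactly while its phases are drawn
uniformly at random, independently per channel.  This preserves every
channel's autocorrelation but destroys cross-channel lagged structure —
precisely the null hypothesis for a Granger-causal link.  Observed
band-averaged dDTF / doi values are compared against the surrogate null
with a one-tailed add-one p value, then Benjamini-Hochberg FDR is
applied across all directed links (default alpha 0.01).

Group-level inference permutes subject labels: the observed statistic is
the absolute difference of group means of per-subject dDTF (or doi)
values; all assignments are enumerated exactly when feasible, otherwise
a seeded Monte-Carlo sample (default 10000 draws, p <= 0.05 considered
reliable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from itertools import combinations

import numpy as np
import pandas as pd

from .models import RoiTimeSeries
from .seed_fc import fdr_correct
from .spectral import (
    DEFAULT_BAND,
    DEFAULT_N_FREQS,
    EdgeStats,
    band_average,
    ddtf,
    default_freqs,
    doi as doi_matrix,
    fit_var,
)

__all__ = [
    "SurrogateNull",
    "CausalGraph",
    "PermutationResult",
    "DensityComparison",
    "phase_randomize",
    "surrogate_null",
    "link_significance",
    "permutation_group_test",
    "compare_connection_density",
]


def phase_randomize(ts: RoiTimeSeries, rng=None) -> RoiTimeSeries:
    """One phase-randomized surrogate of every channel, independently.

    The real-FFT amplitude of each channel is preserved bin-for-bin; the
    phases of all non-DC, non-Nyquist bins are replaced by i.i.d.
    uniform(0, 2*pi) draws (conjugate symmetry is implicit in the
    real FFT).  DC and Nyquist bins are kept, so the mean is unchanged
    and the output is exactly real.
    """
    if ts.n_timepoints < 4:
        raise ValueError("need at least 4 timepoints to phase-randomize")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t = ts.n_timepoints
    spectrum = np.fft.rfft(ts.data, axis=0)
    n_bins = spectrum.shape[0]
    # bins to randomize: everything but DC, and but Nyquist when T is even
    stop = n_bins - 1 if t % 2 == 0 else n_bins
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(stop - 1, ts.n_nodes))
    randomized = spectrum.copy()
    randomized[1:stop] = np.abs(spectrum[1:stop]) * np.exp(1j * phases)
    return ts.with_data(np.fft.irfft(randomized, n=t, axis=0))


@dataclass(frozen=True)
class SurrogateNull:
    """Per-edge null distributions from phase-randomized surrogates.

    ``ddtf_band`` and ``doi`` have shape ``(n_surrogates, N, N)``.
    """

    ddtf_band: np.ndarray
    doi: np.ndarray
    n_surrogates: int
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise ValueError("need at least one surrogate")
        if not (
            np.all(np.isfinite(self.ddtf_band)) and np.all(np.isfinite(self.doi))
        ):
            raise ValueError("surrogate null contains non-finite values")


def surrogate_null(
    ts: RoiTimeSeries,
    n_surrogates: int = 2500,
    order: int = 1,
    n_freqs: int = DEFAULT_N_FREQS,
    band: tuple[float, float] = DEFAULT_BAND,
    rng=None,
) -> SurrogateNull:
    """Build the surrogate null for every directed edge of one series.

    For each of ``n_surrogates`` draws: phase-randomize every channel
    independently, refit the VAR at the same order used for the observed
    data, recompute band-averaged dDTF and doi.  Fit failures are
    re-raised with the surrogate index for diagnosis.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = ts.n_nodes
    freqs = default_freqs(ts.dt, n_freqs)
    null_edges = np.empty((n_surrogates, n, n))
    null_doi = np.empty((n_surrogates, n, n))
    for s in range(n_surrogates):
        surrogate = phase_randomize(ts, rng)
        try:
            model = fit_var(surrogate, order)
            spec = ddtf(model, freqs, ts.dt)
            edges = band_average(spec, band)
        except (ValueError, np.linalg.LinAlgError) as exc:
            raise RuntimeError(f"surrogate {s} failed: {exc}") from exc
        null_edges[s] = edges
        null_doi[s] = doi_matrix(edges)
    return SurrogateNull(
        ddtf_band=null_edges,
        doi=null_doi,
        n_surrogates=n_surrogates,
        node_labels=ts.node_labels,
    )


@dataclass(frozen=True)
class CausalGraph:
    """Directed causal graph with per-edge statistics and significance.

    ``edges`` is a DataFrame with one row per ordered node pair:
    source, target, ddtf_band, doi, p, q, significant.
    """

    node_labels: tuple[str, ...]
    edges: pd.DataFrame = field(compare=False)
    alpha: float = 0.01
    statistic: str = "doi"

    def __post_init__(self) -> None:
        if (self.edges["source"] == self.edges["target"]).any():
            raise ValueError("causal graphs carry no self-edges")

    @property
    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]]

    @property
    def connection_density(self) -> int:
        """Number of significant directed links (per-subject density)."""
        return int(self.edges["significant"].sum())

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.node_labels)
        for row in self.significant_edges.itertuples():
            g.add_edge(
                row.source,
                row.target,
                ddtf_band=float(row.ddtf_band),
                doi=float(row.doi),
                p=float(row.p),
                q=float(row.q),
            )
        return g


def link_significance(
    observed: EdgeStats,
    null: SurrogateNull,
    alpha: float = 0.01,
    statistic: str = "doi",
) -> CausalGraph:
    """Test every directed link against its surrogate null distribution.

    One-tailed add-one p value per ordered pair (i, j):
    ``p = (1 + #{null >= observed}) / (1 + n_surrogates)``, computed on
    the chosen statistic ("doi", the default, or "ddtf"), followed by
    Benjamini-Hochberg FDR across all N(N-1) directed links.
    """
    if observed.node_labels != null.node_labels:
        raise ValueError("observed statistics and null cover different node sets")
    if statistic not in ("doi", "ddtf"):
        raise ValueError("statistic must be 'doi' or 'ddtf'")
    labels = observed.node_labels
    n = len(labels)
    obs = observed.doi if statistic == "doi" else observed.ddtf_band
    null_values = null.doi if statistic == "doi" else null.ddtf_band
    rows = []
    for i in range(n):  # target
        for j in range(n):  # source
            if i == j:
                continue
            exceed = int(np.count_nonzero(null_values[:, i, j] >= obs[i, j]))
            p = (1.0 + exceed) / (1.0 + null.n_surrogates)
            rows.append(
                {
                    "source": labels[j],
                    "target": labels[i],
                    "ddtf_band": observed.ddtf_band[i, j],
                    "doi": observed.doi[i, j],
                    "p": p,
                }
            )
    edges = pd.DataFrame(rows)
    reject, qvals = fdr_correct(edges["p"].to_numpy(), q=alpha)
    edges["q"] = qvals
    edges["significant"] = reject
    return CausalGraph(
        node_labels=labels, edges=edges, alpha=alpha, statistic=statistic
    )


@dataclass(frozen=True)
class PermutationResult:
    p: float
    observed: float
    n_draws: int
    exact: bool


def permutation_group_test(
    values_a,
    values_b,
    n_perm: int = 10000,
    rng=None,
) -> PermutationResult:
    """Two-sided permutation test on the absolute difference of group means.

    Labels are permuted without replacement.  When the number of
    distinct assignments ``C(n_a + n_b, n_a)`` is at most ``n_perm`` the
    test enumerates them all and the p value is the exact fraction of
    assignments whose statistic is at least the observed one (the
    identity assignment guarantees p > 0).  Otherwise ``n_perm``
    random assignments are drawn and the add-one estimate
    ``(1 + #{>= observed}) / (1 + n_perm)`` is returned.  Ties count as
    "at least as extreme" (conservative).
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pool = np.concatenate([a, b])
    na, n_total = a.size, a.size + b.size
    observed = abs(a.mean() - b.mean())
    total_assignments = comb(n_total, na)
    if total_assignments <= n_perm:
        count = 0
        idx_all = np.arange(n_total)
        for combo in combinations(idx_all, na):
            sel = np.zeros(n_total, dtype=bool)
            sel[list(combo)] = True
            stat = abs(pool[sel].mean() - pool[~sel].mean())
            if stat >= observed - 1e-12:
                count += 1
        return PermutationResult(
            p=count / total_assignments,
            observed=observed,
            n_draws=total_assignments,
            exact=True,
        )
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    # vectorized label shuffles: argsort of uniforms is a uniform permutation
    order = np.argsort(rng.random((n_perm, n_total)), axis=1)
    shuffled = pool[order]
    stats_perm = np.abs(
        shuffled[:, :na].mean(axis=1) - shuffled[:, na:].mean(axis=1)
    )
    count = int(np.count_nonzero(stats_perm >= observed - 1e-12))
    return PermutationResult(
        p=(1.0 + count) / (1.0 + n_perm),
        observed=observed,
        n_draws=n_perm,
        exact=False,
    )


@dataclass(frozen=True)
class DensityComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float
    densities_a: tuple = ()
    densities_b: tuple = ()


def compare_connection_density(
    graphs_a: list[CausalGraph], graphs_b: list[CausalGraph]
) -> DensityComparison:
    """Compare per-subject counts of significant links between groups.

    Connection density is the number of significant directed links in a
    subject's causal graph; groups are compared with a pooled-variance
    two-sample t-test.
    """
    if len(graphs_a) < 2 or len(graphs_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    da = np.array([g.connection_density for g in graphs_a], dtype=float)
    db = np.array([g.connection_density for g in graphs_b], dtype=float)
    from .graphs import pooled_t_test

    t, p = pooled_t_test(da, db)
    return DensityComparison(
        mean_a=float(da.mean()),
        sd_a=float(da.std(ddof=1)),
        mean_b=float(db.mean()),
        sd_b=float(db.std(ddof=1)),
        t=float(t),
        p=float(p),
        densities_a=tuple(da),
        densities_b=tuple(db),
    )
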