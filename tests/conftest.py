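import numpy as np
import pandas as pd
import pytest

from mgca import chain_model, simulate_var
from mgca.models import VarModel
from mgca.significance import CausalGraph


@pytest.fixture(scope="session")
def chain3():
    """3-node VAR(1) chain x1 -> x2 -> x3, coupling 0.4."""
    return chain_model(coupling=0.4, n_nodes=3)


@pytest.fixture(scope="session")
def chain3_series(chain3):
    return simulate_var(chain3, 2000, seed=7)


@pytest.fixture(scope="session")
def stable_model_factory():
    """Draw a random stable VAR model (coefficients shrunk below radius 0.95)."""

    def factory(rng: np.random.Generator, n_nodes: int, order: int) -> VarModel:
        coeffs = rng.normal(scale=0.3, size=(order, n_nodes, n_nodes))
        model = VarModel(coeffs=coeffs, noise_cov=np.eye(n_nodes))
        while model.spectral_radius >= 0.95:
            coeffs = coeffs * 0.8
            model = VarModel(coeffs=coeffs, noise_cov=np.eye(n_nodes))
        return model

    return factory


@pytest.fixture
def graph_factory():
    """Build a CausalGraph from a list of significant (source, target) pairs."""

    def factory(node_labels, significant_edges, alpha=0.01):
        labels = tuple(node_labels)
        sig = {tuple(e) for e in significant_edges}
        rows = []
        for tgt in labels:
            for src in labels:
                if src == tgt:
                    continue
                is_sig = (src, tgt) in sig
                rows.append(
                    {
                        "source": src,
                        "target": tgt,
                        "ddtf_band": 0.1 if is_sig else 0.001,
                        "doi": 0.05 if is_sig else 0.0,
                        "p": 0.001 if is_sig else 0.9,
                        "q": 0.005 if is_sig else 0.95,
                        "significant": is_sig,
                    }
                )
        return CausalGraph(
            node_labels=labels, edges=pd.DataFrame(rows), alpha=alpha
        )

    return factory
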