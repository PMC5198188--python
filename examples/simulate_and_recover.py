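"""Simulate a directed 3-node chain and recover its edges with dDTF.

Builds the ground-truth VAR(1) chain x1 -> x2 -> x3 (coupling 0.4),
simulates 2000 BOLD-like samples at TR = 2 s, fits the VAR back and
prints the band-averaged dDTF edge matrix.  The two true edges should
carry by far the largest weights; the mediated x1 -> x3 entry is
suppressed by the partial-coherence weighting.
"""

import numpy as np

from mgca import chain_model, edge_statistics, simulate_var

model = chain_model(coupling=0.4, n_nodes=3)
print("ground-truth lag-1 coefficients [target, source]:")
print(model.coeffs[0])

ts = simulate_var(model, n_timepoints=2000, seed=1)
est = edge_statistics(ts, order=1, band=(0.01, 0.08))

print("\nband-averaged dDTF [target, source] (0.01-0.08 Hz):")
print(np.round(est.ddtf_band, 4))
print("\ndifference of influence (doi), positive = source dominates:")
print(np.round(est.doi, 4))
print(
    "\nThe entries (x2<-x1) and (x3<-x2) are the true directed edges; "
    "every other entry should be an order of magnitude smaller."
)
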