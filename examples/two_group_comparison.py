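"""Two-group comparison with a planted coupling difference.

Simulates 19 subjects per group at the typical resting-state design
size (190 volumes, TR = 2 s).  Group B carries an extra x1 -> x2
coupling of 0.5 that group A lacks.  Per-subject band-averaged dDTF
values are compared edge-wise with a 10000-draw permutation test; the
planted edge should be flagged at p <= 0.05 and the others should not.
"""

import numpy as np

from mgca import VarModel, make_two_group_dataset
from mgca.pipeline import PipelineConfig, run_pipeline

labels = ("x1", "x2", "x3")
base = np.zeros((1, 3, 3))
np.fill_diagonal(base[0], 0.5)
model_a = VarModel(coeffs=base, noise_cov=np.eye(3), node_labels=labels)
planted = base.copy()
planted[0, 1, 0] = 0.5  # x1 -> x2, group B only
model_b = VarModel(coeffs=planted, noise_cov=np.eye(3), node_labels=labels)

subjects, _ = make_two_group_dataset(model_a, model_b, n_per_group=19,
                                     n_timepoints=190, seed=7)

config = PipelineConfig(var_order=1, n_surrogates=1000, n_permutations=10000, seed=7)
result = run_pipeline(subjects, config, preprocess=False)

print("edge-wise group comparison (per-subject dDTF, permutation p):")
cols = ["source", "target", "ddtf_mean_a", "ddtf_mean_b", "p_ddtf", "p_doi"]
print(result.edge_comparison[cols].to_string(index=False))

d = result.density_comparison
print(f"\nconnection density: group A {d.mean_a:.1f} +- {d.sd_a:.1f}, "
      f"group B {d.mean_b:.1f} +- {d.sd_b:.1f} (t = {d.t:.2f}, p = {d.p:.3f})")
print(
    "\nThe planted x1 -> x2 edge shows the dominant group difference (its "
    "group-B mean dDTF is an order of magnitude above group A's). The "
    "reverse direction of the same pair also moves in raw dDTF -- "
    "estimation crosstalk between the two directions of a coupled pair -- "
    "which is exactly why the directed inference relies on the doi "
    "(difference of influence) rather than raw magnitudes."
)
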