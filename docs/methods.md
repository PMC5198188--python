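# Methods

This note documents the models, the numerical choices and the known
limitations of `mgca`. It is the package's own account of its science;
every empirical number quoted here is one the test suite or
`scripts/acceptance.py` computes at run time.

## Signal model and estimation

ROI time series are modelled as a stationary VAR(p),
`x_t = Σ_k A_k x_{t−k} + e_t` with Gaussian innovations
`e_t ~ N(0, Σ)`. Coefficient matrices are indexed `[target, source]`
everywhere in the package, and spectral arrays `[frequency, target,
source]`; all outputs name edges as `source → target`.

Estimation is equation-wise OLS with an intercept, after z-scoring each
channel (mean 0, variance 1). Z-scoring makes coefficients comparable
across ROIs whose raw BOLD intensity scales differ and is the standard
reading of "normalized" series; it can be disabled
(`fit_var(..., standardize=False)`), which is also how the estimator is
cross-checked against `statsmodels.tsa.VAR` in the tests. The
innovation covariance is the degrees-of-freedom-adjusted residual
covariance. Channels that are constant up to floating-point residue
(sd below `1e-10 ×` the data scale) are rejected rather than amplified
into garbage — preprocessing a constant channel leaves exactly this
kind of residue.

Model order is chosen by BIC over `1 … 20` by default (AIC available);
all candidate orders are scored on the same effective sample so the
criteria are comparable. A fixed-order override exists and is what the
simulation studies use when the true order is known.

## Spectral influence measures

With `A(f) = I − Σ_k A_k e^{−i2πfk·dt}` and `H(f) = A(f)⁻¹`:

- `DTF²[f,i,j] = |H_ij|² / Σ_m |H_im|²`; rows of squared DTF sum to 1
  at every frequency (verified to ~1e-15 over random stable models).
- `ffDTF²[f,i,j] = |H_ij(f)|² / Σ_{f'} Σ_m |H_im(f')|²` — the
  full-frequency normalization that makes band averages meaningful.
- Partial coherence `κ_ij(f)` from the inverse of `S(f) = H Σ H*`.
- `dDTF = ffDTF × κ`, the quantity carried forward as edge weight.
- Band average: arithmetic mean of dDTF over grid frequencies inside
  the closed band `[0.01, 0.08]` Hz (matching the preprocessing filter
  band), diagonal forced to zero. Frequency grid: 129 uniform points on
  `(0, Nyquist]`; grid size and band are configurable.
- `doi_ij = dDTF_ij − dDTF_ji` on the band-averaged matrix (average
  first, then subtract), giving one signed scalar per directed link.

The dDTF weighting follows the "direct DTF" construction from the
method literature (ffDTF multiplied by partial coherence); weighting
plain DTF instead is available as a flag.

## Surrogate link inference

The null for a causal link is "no cross-channel lagged structure":
each channel is phase-randomized independently (exact amplitude
preservation via the real FFT; DC and Nyquist bins kept, so the mean is
unchanged and the output exactly real). For each of `n_surrogates`
draws (default 2500) the VAR is refit at the observed order and
band-averaged dDTF and doi recomputed. Per directed link the one-tailed
add-one p value is `(1 + #{null ≥ obs}) / (1 + n_surrogates)` — never 0
and never above 1 — followed by Benjamini–Hochberg FDR across all
`N(N−1)` links at α = 0.01. The tested statistic defaults to doi, with
the per-direction dDTF test available.

**Known limitation (measured, not hidden).** The surrogate null
destroys *all* coupling, so for an edge that is null only *given the
other channels* — the mediated `x1 → x3` path of a chain — the null
spread understates the sampling noise of the observed statistic: the
observed mediated dDTF rides on a genuinely nonzero ffDTF and is
suppressed only by the partial-coherence estimate, whose value at a
true zero is a positively-biased folded normal. The ratio of that
estimation noise to the null spread does not shrink with T, so on the
3-node chain (coupling 0.4, T = 2000, 500 surrogates, FDR α = 0.01) the
mediated edge is flagged in roughly half the replicates even though the
two true edges always carry the largest weights. The acceptance checks
report both the ranking rate and the exclusivity rate; the exclusivity
rate (~34–45%) is an honest property of the method at this scale, not a
bug. On globally null data (independent channels) the test is well
calibrated: surrogate p values are near-uniform and the rejection rate
matches α.

## Group inference

Two readings of the group analysis exist and both are implemented: the
default computes per-subject statistics and compares groups across
subjects; a group-averaged mode (z-scored subject series averaged into
a single vector per ROI per group) feeds the group-level graph and hub
tables. Edge-wise comparisons use a permutation test on the absolute
difference of group means of per-subject dDTF (and doi): all
assignments enumerated exactly when their count is ≤ `n_perm`
(p = exact fraction ≥ observed, identity assignment included, so p > 0),
otherwise `n_perm = 10000` seeded draws with the add-one estimate.
Ties count as "at least as extreme". Connection density (count of
significant links per subject) and per-node degrees are compared with
pooled-variance two-sample t-tests. At the default design size
(19 subjects per group, 190 volumes, TR = 2 s) a planted coupling of
0.5 versus 0.0 is detected at p ≤ 0.05 in ≥ 90% of replicates while the
null flag rate stays at the nominal 5%.

## Degrees and hubs

Degrees count significant directed links only. A node is a hub of a
kind when its degree is **at least** mean + 1 SD across nodes
(inclusive threshold), with the *sample* SD (n−1) because ROI networks
are small; when all degrees are equal (SD = 0) no node is a hub —
otherwise every node would trivially qualify. The handshake identity
(Σ in = Σ out = link count) is asserted on every graph.

## Preprocessing

Stage order: discard the first 10 volumes → motion screening → linear
detrend → band-pass → nuisance regression. The paper-silent placement
of nuisance regression (before vs after filtering) is resolved as
"after", documented here as the package's choice. Motion screening
fails a subject when any translation exceeds 2.0 mm or any rotation
2.0° in absolute value relative to the reference volume (values exactly
at the threshold pass). The band-pass is an ideal frequency-domain
projection — coefficients outside the closed band `[0.01, 0.08]` Hz
zeroed — chosen over IIR/FIR designs because it is exactly idempotent
and exactly testable (in-band sines retained at ~100%, bin-aligned
stopband sines removed to machine precision; a non-bin-aligned stopband
sine leaves a few percent of windowing leakage, which is a property of
finite windows, not of the filter). Nuisance regression always includes
an intercept and reports collinear covariate columns by index. MCFLIRT
`.par` files are read as 3 rotations (radians, converted to degrees)
then 3 translations (mm); the convention is configurable.

## Seed functional connectivity

Pearson correlation of each unit against the seed's mean course;
constant units yield NaN with a warning, never a silent 0. Fisher's
`Z = atanh(r)` (error at |r| ≥ 1 for the scalar API; ±inf sentinels in
maps). One-sample and two-sample t maps use the classic pooled-variance
formulation. FDR is Benjamini–Hochberg (the field default where the
variant is unspecified); "cluster > 10 voxels" is read strictly
(components survive at ≥ 11 voxels), with 6/18/26 connectivity
selectable (default 18).

## Synthetic data

The generator emulates the study conditions the analysis is meant for:
stationary multichannel series from ground-truth VAR graphs, 19
subjects per group and 190 usable volumes at TR = 2 s by default (the
scan length follows the 200-volumes-minus-10-discarded convention),
Gaussian innovations (matching the Gaussian assumptions of the
downstream t-tests), burn-in of 500 samples, per-subject seeds derived
as master seed + subject index. Hemodynamic blurring uses the canonical
double-gamma HRF (positive lobe peaking at 5 s, undershoot centred near
16 s at 1/6 amplitude, 32 s support, unit-sum normalized), full
convolution truncated to the input length with optional discard of the
first kernel-length samples, then integer-factor decimation to the TR.
The voxel phantom sets voxel `v = λ_v·latent + √(1−λ_v²)·noise` so the
expected seed correlation equals the loading `λ_v` exactly.

What the generator does **not** emulate: volumetric artifacts, motion,
physiological noise spectra, nonstationarity, or neural-mass dynamics.
Passing tests therefore demonstrate correctness of the estimators and
inference under the stated generative model, not robustness to every
property of real scanner data.

## Problem sizes used in checks

Simulation-based checks run at: 100 random stable models (N = 3–8,
p = 1–3) for spectral identities; 50 replicates × 500 surrogates at
T = 2000 for chain recovery; 10 white-noise datasets × 200 surrogates
(200 edges) for calibration; 20 replicates at 19 subjects/group,
T = 190, with 10000-draw permutation tests for design-scale power; 1000
random p-vectors for the FDR oracle. These sizes were chosen once as
adequate for the properties being estimated and are stated here so the
numbers in `results/acceptance.json` are interpretable.
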