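# mocapfill

Recovery of missing markers in 3D skeletal motion-capture data by **locally
weighted PCA regression**.

Optical motion capture tracks reflective markers on a moving body; occlusion,
marker detachment and jitter leave *gaps* — frame intervals in which one or
more markers (or entire frames) are unobserved. Cleaning these gaps by hand is
routinely the most expensive step of a capture pipeline. `mocapfill` fills
them automatically from gap-free training motion, for users working with
marker trajectory matrices in TRC, CSV or C3D form (biomechanics, gait
analysis, animation).

## The method

A motion sample is a matrix `A ∈ R^{m×3n}` (m frames, n markers, columns
x,y,z per marker). Given training samples `A_1..A_K` and a test sample `M`
with gaps `g = 1..G`, all centered by pooled column means:

1. **Per-gap eigenspace mapping.** `U` is the top-k eigenbasis of the stacked
   training matrix (`AᵀA = UΣUᵀ`); applying gap `g` alone to every training
   sample gives a gap-group stack with its own basis `Ũ^g`, and a k×k mapping
   `T^g` solving `A_i U ≈ Ã_i^g Ũ^g T^g` aligns the two subspaces. The
   operator `P^g = Ũ^g T^g Uᵀ` reconstructs gap-g data from gapped input.
2. **Residual weighting (WPCA).** The accumulated residual
   `B = Σ_g Σ_i (A_i − Ã_i^g P^g)` yields eigenvalues `{δ_i}` of `BᵀB`; the
   diagonal weight `W = diag(1/max(δ_i, threshold))` downweights
   high-variance residual directions — weighted least squares against
   non-constant variance. Coefficients `α` minimize
   `Σ_i tr(R_i W R_iᵀ)`, `R_i = A_i − Ã_i Σ_g α_g P^g`, where `Ã_i` carries
   *all* G gaps. The fill is `M* = M(Σ_g α_g P^g)`, with only missing
   entries replaced.
3. **Local weighting (LWPCA).** Each gap gets a Gaussian taper mask
   `Q^g_{ij} = exp(−dist²((i,j), g)/σ²)`, where `dist` combines the temporal
   offset of frame `i` from the gap interval with the *skeleton* shortest-path
   distance of marker `j` from the gap marker. Multiplying the training
   stacks elementwise by `Q^g` tapers the effective covariance to a
   neighborhood of the gap (multivariate covariance tapering), so the per-gap
   eigenspaces become local; the residual and the α-solve are tapered the
   same way. This targets gaps in regions of sharp localized motion, where
   global least squares underfits. As σ → ∞ the fit reduces exactly to WPCA.
4. **Missing whole frames.** When entire frames are dropped, the same
   regression runs in frame space: Gram-matrix eigenbases `AAᵀ = VΣVᵀ` of the
   horizontally concatenated training stack, one temporal-only taper per
   missing frame, and a per-frame regressor that projects the observed rows
   onto the local frame subspace and evaluates it at the missing rows.

Error metric: `ε = ‖(M* − M_grd) .* Mask‖²_F / (#missing entries)`.

## Worked example

Synthetic articulated motion, 41 markers, ten 400-frame windows (nine for
training, one for testing), one 380-frame gap on a random marker:

```python
from mocapfill import (SynthConfig, generate_motion, make_training_windows,
                       simulate_gaps, apply_gaps, fit_wpca, fit_lwpca,
                       reconstruct, baseline_fill, mse)

cfg = SynthConfig(n_markers=41, m_frames=4000, latent_rank=8, noise_sd=0.02, seed=0)
sequence, skeleton = generate_motion(cfg)
windows = make_training_windows(sequence, window=400)
training, test = windows[:-1], windows[-1]

gaps = simulate_gaps((400, 41), protocol="single", gap_length=380, seed=0)
gapped = apply_gaps(test, gaps)
missing = (gapped.mask == 0).astype(float)

print(mse(reconstruct(gapped, fit_wpca(training, gaps)), test, missing))
print(mse(reconstruct(gapped, fit_lwpca(training, gaps, skeleton)), test, missing))
print(mse(baseline_fill(gapped, "linear"), test, missing))
```

Output (gap MSE, squared length units per missing entry):

```
wpca       gap MSE = 0.03433
lwpca      gap MSE = 0.15377
linear     gap MSE = 2.31403
plain-pca  gap MSE = 1.63716
```

The training-based regressors beat the training-free baselines by 1–2 orders
of magnitude. On this *smooth* sequence the plain weighted fit is already
near-optimal and the taper's locality bias costs a little accuracy; on data
with recurring sharp localized motion under the gap the ordering reverses —
see the burst scenario in `tests/test_acceptance.py`, where LWPCA has both
the lowest mean error and the lowest error variance.

The same operations are available from the shell:

```sh
mocapfill simulate --output-dir data --seed 3
mocapfill fill --input test.trc --train w1.trc --train w2.trc \
    --method lwpca --skeleton skeleton.yaml --output filled.trc
mocapfill evaluate --method lwpca --protocol multiple --n-gaps 3 \
    --trials 50 --seed 0 --report report.csv
```

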