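# Methods

## Model and assumptions

Marker trajectories of articulated motion are highly redundant: the body
moves as a small number of coordinated degrees of freedom, so the
`m × 3n` motion matrix is approximately low-rank, and a marker that
disappears for a stretch of frames can be predicted from the markers that
remain visible. The package exploits this through principal-component
regression trained on gap-free samples of the same kind of motion.

All fitting works on centered data. Column means are pooled over the
observed entries of all training samples; a test sample is centered with the
*training* means so that its missing entries sit consistently at the
training mean (zero after centering — mean imputation). Re-estimating means
from a heavily gapped test sample would be unstable, which is also why the
"marker missing throughout the session" case is out of scope: no mean can be
estimated for a column that is never observed.

### Weighted PCA regression (WPCA)

For each gap `g` of the test sample, the same gap is transplanted onto every
training sample (same marker, same relative frame interval), producing a
gap-group stack whose eigenbasis `Ũ^g` describes how the data looks *with
that gap*. The k×k mapping `T^g` is the least-squares alignment of gapped
projections with full-data projections over the training set, and
`P^g = Ũ^g T^g Uᵀ` is the resulting per-gap reconstruction operator. On
noiseless data of latent rank `r` whose test rows lie in the training row
span, a single-gap fill is exact to machine precision provided `k ≥ r + 3`
(the gapped stack spans up to three extra directions — the zeroed
coordinates of the gap marker).

The G operators are blended by coefficients `α` solving a weighted least
squares problem whose diagonal weight is built from the eigenvalues of the
accumulated residual covariance `BᵀB`, small eigenvalues floored at a
threshold. The quadratic form `Σ_i tr(R_i W R_iᵀ)` makes the objective
quadratic in `α` with a closed-form G×G normal-equation solution
(pseudo-inverse when singular); the package's solution matches a
derivative-free minimizer of the literal objective to 1e-5 and is invariant
to rescaling of `W`.

**Known limitation — multiple gaps.** Each `P^g` is trained on data carrying
only gap `g`, but is applied to input carrying all G gaps. The zeroed block
of gap `h` pushed through `P^g` (g ≠ h) leaves a cross-gap bias that no
choice of the G scalars `α` can cancel; multi-gap recovery is therefore
approximate even on noiseless subspace data (order 1e-2 relative MSE in our
synthetic experiments, independent of `k`). Single-gap recovery has no such
term and is exact.

### Locally weighted PCA (LWPCA)

Global least squares underfits when the gap sits in a region of sharp,
localized motion. LWPCA multiplies the training stacks, per gap, by a
Gaussian taper

    Q^g[i, j] = exp(−(d_t² + d_s²) / σ²),

with `d_t` the frame distance of `i` to the gap interval (0 inside, distance
to the nearest gap frame outside) divided by `temporal_scale`, and `d_s` the
skeleton shortest-path distance of marker `j` to the gap marker divided by
`spatial_scale`. Skeleton distance replaces Euclidean marker distance
because graph adjacency — not instantaneous position — determines which
markers move together. Masking the data tapers the effective covariance to a
neighborhood of the gap (the data-masking variant of multivariate covariance
tapering; applying the taper to the covariance itself is deliberately not
implemented). The per-gap bases `U^g`, `Ũ^g` are computed from the masked
stacks, the residual matrix is tapered per gap, and the α-solve is masked by
the normalized combined taper `Q̄ = Σ_g Q^g / max` (maximum entry exactly 1).

The taper is a locality *prior*: it biases the estimator towards structure
near the gap. On globally smooth low-rank data this costs accuracy relative
to WPCA; on data where a sharp localized oscillation recurs under the gap it
buys both lower mean error and lower error variance (the acceptance suite's
burst scenario). As σ → ∞ every mask tends to 1 and the fit coincides with
WPCA exactly — this limit is tested to 1e-6, and exact-recovery properties
are tested in the weak-taper regime, where the global-subspace assumption of
the recovery oracle actually holds.

### Missing whole frames

When entire frames are dropped, marker-space regression has nothing to
condition on, but frame-to-frame correlation does: the Gram matrix `AAᵀ` of
the horizontally concatenated training stack (all samples must share the
frame count) spans the frame-correlation space. Each missing frame is one
gap with a temporal-only taper multiplying the rows of the stack. For gap
`g`, the top-k left singular basis `V^g` of the tapered stack is split into
observed rows `V₁^g` and missing rows `V₂^g`, and the per-gap regressor

    D^g = V₂^g (V₁^gᵀ V₁^g)⁺ V₁^gᵀ Λ₁^g

(`Λ₁^g` = taper weights on observed rows) is the taper-weighted
least-squares projection of the observed rows onto the local frame subspace,
evaluated at the missing rows. Note the basis is taken from the *full*
(tapered) stack: an eigenbasis of the zero-filled gapped stack necessarily
vanishes on the missing rows and carries no information there, so the
gapped-basis change of variables is collapsed analytically into the
projection form above — on tapered data the two formulations coincide, and
the projection form additionally stays consistent when the test input is not
itself tapered. Weights come from the eigenvalues of `BBᵀ` of the stacked
per-gap residuals (one weight per missing frame), `α` from the same
weighted normal equations, and recovery is `M₂* = Σ_g α_g D^g M₁`.

On noiseless samples sharing their latent time courses this recovery is
exact to machine precision when `k` exceeds the latent rank by at least the
one extra direction the pooled de-meaning introduces (the constant frame).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `KRule` | variance 0.95 | retain the smallest k capturing ≥95% of the eigenvalue mass of the full stack; the same k is imposed on every per-gap basis so each `T^g` is k×k. `KRule.fixed(k)` overrides; k is capped at the number of singular vectors the matrix affords (min of its shape) — deliberately *not* at numerical rank, so exact-recovery settings with k above the data rank are expressible. |
| `DeltaThreshold.relative` | 1e-3 | floor for residual eigenvalues at `1e-3 × max δ` (absolute override available; a 1e-12 absolute floor always applies so a zero residual cannot divide by zero). |
| `TaperConfig.sigma` | 3 | Gaussian window in the dimensionless combined distance. |
| `TaperConfig.temporal_scale` | 10 frames | frames per unit of taper distance. Frames and skeleton hops are incommensurate; both are made dimensionless before the Euclidean combination. |
| `TaperConfig.spatial_scale` | 1 hop | skeleton-distance units per unit of taper distance. Skeleton edge weights default to 1 per bone (graph hops); bone-length weights are configurable. |
| `window` / `stride` | 400 / 400 | training samples are consecutive-frame windows cut from longer sequences, non-overlapping by default. |

The taper scales and σ are artifact choices, tuned once on synthetic data;
they are dimensionless conventions, not physical constants.

## Synthetic data

`generate_motion` drives `3n` coordinates by `latent_rank` smooth sinusoidal
time courses (frequencies 0.002–0.02 cycles/frame, i.e. 1–10 periods across
a 500-frame capture; amplitudes 0.5–2 in arbitrary length units) through a
random loading matrix, giving an exactly low-rank matrix before white
Gaussian noise (`noise_sd = 0.02`, a ~2% relative sensor noise). The
default geometry (41 markers, 400-frame windows) mirrors standard
full-body marker sets. An optional *burst* adds a Hann-windowed
high-frequency oscillation loaded on one marker and its skeleton neighbours,
optionally recurring with a fixed period — the sharp-local-motion regime the
taper targets. `generate_motion_family` instead shares the time courses
across samples with independent loadings, the regime in which frame-space
(Gram) recovery is well-posed.

What the generator does *not* emulate: bone-length rigidity constraints,
ground contact and other kinematic nonlinearities, heteroscedastic or
autocorrelated sensor noise, soft-tissue artifact, and real marker-label
noise. Passing tests therefore demonstrate the estimators' algebraic and
statistical properties under the low-rank-plus-noise model, not end-to-end
performance on a specific capture system; the file readers and the CLI
accept real TRC/CSV/C3D data for that purpose.

## Numerical choices

- Eigenbases come from thin SVD of the data matrix, not from forming the
  covariance — the same right singular vectors, better conditioning.
- SVD sign ambiguity is fixed by making each basis column's
  largest-magnitude entry positive (ties: lowest row index), so repeated
  fits are bit-identical.
- Gapped entries enter the decompositions as zeros after de-meaning
  (mean imputation), the fill that leaves column means unchanged.
- Taper masks are applied after de-meaning: tapering weights residual
  structure, not the mean level.
- Normal equations use `solve` with a pseudo-inverse fallback when the
  system is singular or extremely ill-conditioned (near-collinear per-gap
  regressors make α non-unique; the minimum-norm solution is taken).
- The mask underflows to exactly 0 beyond ~38σ of combined distance; this
  is harmless (the affected rows/columns simply drop out of the local fit).
- Degenerate inputs raise rather than guess: a column with no observed
  entries anywhere (no estimable mean), an all-masked α system, zero missing
  frames at fit time, a test gap pattern differing from the fitted one.

## Evaluation protocol

Recovery error is the squared Frobenius norm of the reconstruction error
restricted to originally missing entries, divided by the *number of missing
entries*. `run_trials` fixes one synthetic sequence, draws independent
seeded gap placements per trial (uniform over feasible starts —
chi-square-checked), fills with the chosen method and reports per-trial
errors; all randomness descends from one master seed through
`numpy.random.SeedSequence`, so reports are bit-reproducible. Tests and the
acceptance script run scaled-down geometries (8–20 markers, 120–400-frame
windows, 10–20 trials) chosen to keep the full suite fast while preserving
every qualitative regime; the CLI defaults to the full 50-trial protocol.
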