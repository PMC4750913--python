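# Methods

## Model and procedure

Registration is cast as mixture-density estimation: the model points are
centroids of an isotropic Gaussian mixture (shared variance σ²) plus a
uniform background component of weight ω and improper density 1/N, and the
scene points are i.i.d. draws.  EM alternates:

- **E-step** — membership posteriors with shape-context weights `C_nm` and
  row sums `S_n` in both the mixture and background terms (a uniform cost
  matrix reduces the expression to plain CPD exactly).
- **M-step** — (i) σ² as the posterior-weighted mean squared residual at
  the current transform; (ii) optionally ω via the damped closed-form
  update; (iii) the kernel coefficients `W` from the regularized linear
  system; (iv) the transform `T(Y) = Y + GW`.

The displacement field lives in the RKHS of the Gaussian kernel
`G_ij = exp(−‖y_i−y_j‖²/2β)`; its smoothness penalty is the induced norm
`tr(WᵀGW)` — the unique realization consistent with the stationarity
condition the coefficient system expresses.

Descriptors are computed **once** from the initial (normalized) point sets
and held fixed.  As σ² shrinks, the sharpening Gaussian distance term
dominates the fixed structure prior, so the descriptor mostly steers the
early iterations — which is where wrong nearest-neighbour pairings would
otherwise lock in.

### Objective monitoring

Two objectives are traced per iteration:

- `Q_trace` — the expected complete-data negative log-likelihood (data
  term, `(D·NP/2)·log σ²`, the two ω terms, and the `(λ/2)tr(WᵀGW)`
  penalty).  The E-step's posterior re-assignment can *increase* this
  quantity; it is reported for diagnostics, not used for control.
- `nll_trace` — the penalized observed-data negative log-likelihood
  `−Σ_n log p(x_n) + (λ/2)tr(WᵀGW)`.  With ω and `C` fixed this is the
  quantity EM provably never increases (the M-step is block descent in σ²
  then `W`), and it is the convergence monitor: the loop stops when its
  relative change falls below `tol` or at `max_iter`.

With the automatic ω update active the NLL guarantee no longer applies
(ω moves between the E-step and the evaluation); both traces are still
recorded.

## Parameters

| name | default | units / scale | role |
|---|---|---|---|
| `omega0` | 0.5 | — | initial (or frozen) outlier weight |
| `lambda_` | 2.0 | — | smoothness weight on the displacement field |
| `beta` | 2.0 | normalized units² | Gaussian kernel scale `exp(−d²/2β)` |
| `gamma` | 0.1 | — | shape-context cost bandwidth |
| `max_iter` | 100 | — | iteration cap |
| `tol` | 1e-8 | relative | NLL-change stopping threshold |
| `sigma2_floor` | 1e-8 | normalized units² | variance collapse guard |
| `working_scale` | 1.0 | — | coordinate scale multiplier (below) |

λ and β are the conventional CPD defaults on normalized coordinates; γ is
the conventional shape-context bandwidth.  The kernel divisor is `2β`
(β enters linearly, matching the expression the coefficient system is
derived from), so `beta` is a squared-length scale.

Both sets are independently translated to zero mean and scaled to unit RMS
radius before EM; the aligned model is mapped back into the scene frame on
output.  This makes degradation levels comparable across shapes and makes
the engine translation-equivariant.

## Outlier capture and the working scale

The background density is the improper constant 1/N — it does not depend
on the coordinate range of the data, while the Gaussian component
densities do.  Consequently whether an outlying point is actually won by
the background depends on the *absolute* scale the EM runs at: at the
default unit-RMS scale the mixture out-competes the background, the mean
outlier posterior stays small, and the damped fixed-point iteration drives
ω toward its lower clamp; multiplying the working coordinates by ~8
strengthens the background until ω settles near the true outlier fraction
and the error on heavy-outlier cases drops (see
`examples/03_automatic_outlier_ratio.py`, which prints both regimes).

`working_scale` exposes this calibration without touching any model
formula (scaling coordinates by `s` is equivalent to replacing the
background density 1/N by `s^D/N` at unit scale).  The default is kept at
1.0 — the registration itself is robust either way because structure
weighting, not background capture, carries most of the improvement — but
users who care about ω as an interpretable outlier-fraction estimate
should enlarge it until the scene's bounding-box area (in working units)
comfortably exceeds N.

## Numerical choices

- ω is clamped to `[1e-6, 1−1e-6]` so both log terms of the objective and
  the E-step denominator stay finite; `estep` rejects ω = 1 outright.
- σ² is floored at 1e-8 (normalized units²) to survive near-exact fits.
- Posterior row sums below 1e-10 in the coefficient solve get diagonal
  entries 1e10: centroids that explain no data follow the regularizer.
- The solve verifies its residual against `1e-8·‖rhs‖` and raises on
  failure rather than returning a silent bad step.
- Shape-context radii outside the `[0.125, 2.0]` (mean-distance units)
  log-binning range are clamped into the boundary bins, so raw histograms
  always sum to P−1 and normalization is well defined for any geometry.
- A point coinciding with the mass center takes the global +x axis as its
  reference direction.
- Correspondences are reported as `argmax_m P(m|x_n)` when that posterior
  beats the outlier posterior; scene points below that are left unmatched.
- Histograms are normalized to unit sum before the χ² cost, which keeps
  costs comparable when N ≠ M (occlusion/outlier cases).
- Bin-boundary ties: a neighbour lying exactly on an angular-bin edge
  (possible on perfectly symmetric shapes) can flip between adjacent bins
  under floating-point perturbation; generic configurations are unaffected
  and the invariance guarantees are stated for them.

## Synthetic benchmark generator

Templates (fish-like closed curve, three-stroke glyph, ring) are
deterministic contours at zero mean and unit RMS radius.  Degradations
emulate the classical four-axis protocol:

- **deformation** — Gaussian-RBF field on a 3×3 control grid over the
  bounding box, control displacements ~ N(0, degree²), kernel width half
  the bbox diagonal;
- **noise** — i.i.d. N(0, level²) jitter per coordinate;
- **occlusion** — one contiguous contour run of round(ratio·P) points
  removed at a seeded start index;
- **outliers** — round(ratio·P) uniform points over the 20%-inflated
  bounding box, appended after the genuine points.

Non-deformation cases receive a mild base warp (degree 0.02) so they stay
non-rigid.  Every case carries exact (scene index, model index) ground
truth, and all randomness flows from one seed through named sub-streams.

What the generator does **not** emulate: the original benchmark's
thin-plate-spline warp statistics (its construction is not recoverable
from published descriptions), image-derived contour noise structure, or
anatomically realistic shapes.  Passing tests therefore demonstrate
correct mechanics and relative robustness orderings on controlled data,
not absolute error levels on the historical benchmark or on clinical
contours.

## Problem sizes

The test suite and `scripts/acceptance.py` run at desk scale: templates of
60–98 points, scenes up to ~300 points, 10–20 trials per condition, chosen
to exercise every code path and the documented robustness orderings while
keeping a full run in seconds.  The engine itself is O(N·M) per iteration
plus an M×M solve and is comfortable to a few thousand points per set.

## Known limitations

- 2-D only for the structure descriptor; other dimensions fall back to
  uniform costs (i.e., baseline CPD behavior) with a warning.
- Fixed descriptors assume both sets describe the same overall shape;
  under heavy occlusion the survivors' mass center and mean pairwise
  distance shift, distorting their histograms — on half-occluded contours
  the structure weighting can *underperform* the uniform baseline, and the
  degradation sweeps expose this honestly.
- ω's damped fixed-point iteration is schedule-dependent (1/t damping has
  no analyzed optimum) and, at the default working scale, biased low; see
  the working-scale discussion above.
- The transform `Y + GW` is not constrained to be invertible or
  diffeomorphic.
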