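# structcpd

Structure-informed coherent point drift (CPD) for robust **non-rigid
point-set registration** in 2-D, aimed at contour alignment problems of the
kind that arise in biomedical image analysis (CT/MRI organ boundaries,
shape benchmarks), where the two point sets disagree through smooth
deformation, jitter, partial occlusion and spurious outliers.

## The model

The model set `Y = {y_m}` (M points) provides the centroids of a Gaussian
mixture that is fit to the scene set `X = {x_n}` (N points) by EM.  A
uniform background component with mixing weight ω absorbs outliers.  Two
ingredients extend plain CPD:

1. **Structure-weighted memberships.**  Every point gets a log-polar
   shape-context histogram `h(k)` (5 radial × 12 angular bins, radii in
   units of the mean pairwise distance, angles measured from the
   point-to-mass-center axis, hence invariant to translation, rotation and
   scaling).  Pairs are scored with

   `C_nm = exp( −(1/2γ) Σ_k [h_n(k)−h_m(k)]² / (h_n(k)+h_m(k)) )  ∈ (0,1]`

   and the membership posterior becomes

   `P(m|x_n) = C_nm e^{−‖x_n−T(y_m)‖²/2σ²} / [ Σ_k C_nk e^{−‖x_n−T(y_k)‖²/2σ²} + ω S_n (2πσ²)^{D/2} / ((1−ω)N) ]`

   with `S_n = Σ_k C_nk`.  A uniform cost matrix (`C ≡ 1`, `S_n = M`)
   recovers plain CPD exactly — that configuration is the built-in baseline.

2. **Automatic outlier ratio.**  Each iteration re-estimates
   `ω_new = 1 − (1/N) Σ_{mn} P_mn` and moves toward it with a damped step
   `ω ← ω + α(ω_new − ω)`, α = 1/t, so ω adapts quickly early and settles
   late.

The transform is `T(Y) = Y + GW` with Gaussian kernel
`G_ij = exp(−‖y_i−y_j‖²/2β)`; the coefficients solve
`[G + λσ² diag(P1)^{−1}] W = diag(P1)^{−1} P X − Y`, the Tikhonov-regularized
(RKHS-norm) update.  See `docs/methods.md` for assumptions, parameter
guidance, and known limitations.

## Worked example

```sh
python examples/01_basic_registration.py
```

```
iterations run      : 100 (converged=False)
final sigma^2       : 1.000e-08
point RMSE          : 4.14e-07 (warp magnitude was 0.03)
matched scene points: 60 of 60
```

A 60-point contour warped by a smooth random field of magnitude 0.03 (in
units of the shape's RMS radius) is recovered to RMSE 4×10⁻⁷ — five orders
below the warp — and every scene point is matched.  The run hits the
100-iteration cap with σ² pinned at its floor, which is the expected end
state of a near-exact fit.  The other examples demonstrate the descriptor
(`02`), the automatic outlier ratio and its coordinate-scale sensitivity
(`03`), and a structure-vs-baseline noise sweep (`04`).

The same engine is scriptable from the shell:

```sh
structcpd synth --kind outlier --level 1.0 --n-points 98 --out case/
structcpd register case/scene.txt case/model.txt -o out/
structcpd eval out/aligned.txt case/truth.tsv case/scene.txt
structcpd sweep --kind noise --levels 0.01,0.03,0.05 --trials 10
```

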