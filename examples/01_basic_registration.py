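"""Register a smoothly warped contour back onto its template.

Builds a 60-point fish-like contour, warps it with a smooth random
displacement field (degree 0.03), and runs the structure-informed engine.
The printed RMSE is the root-mean-square distance between each scene point
and its aligned ground-truth partner, in units of the template's RMS
radius — values well below the warp magnitude mean the deformation was
recovered, not just overlaid.
"""

from structcpd import DegradationSpec, RegistrationConfig, make_benchmark_case, register, rmse_points

case = make_benchmark_case(
    DegradationSpec(kind="deformation", level=0.03, seed=7, template="fishlike", n_points=60)
)
result = register(case.scene, case.model, RegistrationConfig())

err = rmse_points(result.transformed_model, case.truth_pairs, case.scene)
print(f"iterations run      : {result.n_iter} (converged={result.converged})")
print(f"final sigma^2       : {result.sigma2_trace[-1]:.3e}")
print(f"point RMSE          : {err:.2e} (warp magnitude was 0.03)")
print(f"matched scene points: {len(result.correspondences)} of {case.scene.shape[0]}")
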