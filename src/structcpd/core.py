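"""EM engine for non-rigid point-set registration.

The model set Y provides GMM centroids that drift onto the scene set X.
Memberships are re-weighted by shape-context similarity C_nm, an extra
uniform component absorbs outliers with mixing weight omega, and omega
itself is re-estimated each iteration under a 1/t learning-rate damping.
The displacement field lives in the RKHS of a Gaussian kernel, T(Y) = Y + GW,
with Tikhonov penalty (lambda/2) tr(W^T G W).

Baseline coherent point drift is the same engine with a uniform cost matrix
and a frozen outlier weight (``use_structure=False, auto_omega=False``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .shape_context import CostMatrix, sc_cost_matrix, sc_descriptors, uniform_cost_matrix

__all__ = [
    "RegistrationConfig",
    "EMState",
    "RegistrationResult",
    "initialize",
    "estep",
    "update_sigma2",
    "update_omega",
    "solve_coefficients",
    "transform",
    "objective_q",
    "observed_nll",
    "register",
    "gaussian_kernel",
]

logger = logging.getLogger(__name__)

OMEGA_EPS = 1e-6       # omega is confined to [OMEGA_EPS, 1 - OMEGA_EPS]
P1_FLOOR = 1e-10       # posterior row sums below this are guarded in the solve


@dataclass
class RegistrationConfig:
    """Tunable parameters of the registration.

    Parameters
    ----------
    omega0
        Initial outlier mixing weight in [0, 1).  With ``auto_omega`` the
        estimate moves away from this value; frozen otherwise.
    lambda_
        Tikhonov regularization weight (> 0) on the displacement field.
    beta
        Gaussian kernel scale of the displacement RKHS,
        ``G_ij = exp(-||y_i - y_j||^2 / (2*beta))`` on normalized coordinates.
    gamma
        Bandwidth of the shape-context cost ``exp(-chi2 / (2*gamma))``.
    max_iter, tol
        EM stops at ``max_iter`` or when ``|dQ| / |Q| < tol``.
    use_structure
        Shape-context cost matrix (2-D only) vs uniform costs.
    auto_omega
        Re-estimate omega each iteration (damped by ``alpha_schedule``) vs
        keep it at ``omega0``.
    alpha_schedule
        Learning-rate rule for the omega update: ``"1/t"`` (default) or a
        constant float (0 disables movement, 1 adopts the raw estimate).
    sigma2_floor
        Lower bound on the GMM variance, in normalized squared units.
    normalize
        Translate each set to zero mean and scale to unit RMS radius before
        EM; the output is mapped back into the scene frame.
    working_scale
        Multiplier applied to the normalized coordinates before EM (default
        1.0).  The outlier component's improper 1/N density competes with
        absolute-scale Gaussian densities, so enlarging the working scale
        strengthens outlier capture; see the methods note for calibration
        guidance.
    seed
        Reserved; the engine itself is deterministic.
    """

    omega0: float = 0.5
    lambda_: float = 2.0
    beta: float = 2.0
    gamma: float = 0.1
    max_iter: int = 100
    tol: float = 1e-8
    use_structure: bool = True
    auto_omega: bool = True
    alpha_schedule: str | float = "1/t"
    sigma2_floor: float = 1e-8
    normalize: bool = True
    working_scale: float = 1.0
    keep_states: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega0 < 1.0:
            raise ValueError(f"omega0 must lie in [0, 1), got {self.omega0}")
        for name in ("lambda_", "beta", "gamma", "tol"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class EMState:
    """Mutable EM quantities at one iteration."""

    sigma2: float
    omega: float
    P: np.ndarray                  # (M, N) posteriors P(m | x_n)
    P_outlier: np.ndarray          # (N,)   P(M+1 | x_n)
    W: np.ndarray                  # (M, D) kernel coefficients
    G: np.ndarray                  # (M, M) Gaussian kernel matrix
    t: int = 1
    Q: float = np.inf

    @property
    def NP(self) -> float:
        return float(self.P.sum())


@dataclass
class RegistrationResult:
    transformed_model: np.ndarray          # (M, D), in the scene frame
    P_final: np.ndarray                    # (M, N)
    P_outlier: np.ndarray                  # (N,)
    correspondences: list[tuple[int, int, float]]
    omega_trace: np.ndarray
    sigma2_trace: np.ndarray
    Q_trace: np.ndarray                    # Eq-style expected complete-data objective
    nll_trace: np.ndarray                  # penalized observed NLL (monotone monitor)
    n_iter: int
    converged: bool
    config: RegistrationConfig = field(repr=False, default=None)
    #: per-iteration (P, W) snapshots when cfg.keep_states is set
    P_states: list = field(repr=False, default=None)
    W_states: list = field(repr=False, default=None)


def gaussian_kernel(Y: np.ndarray, beta: float) -> np.ndarray:
    """Kernel matrix G_ij = exp(-||y_i - y_j||^2 / (2*beta))."""
    return np.exp(-cdist(Y, Y, "sqeuclidean") / (2.0 * beta))


def initialize(X: np.ndarray, Y: np.ndarray, cfg: RegistrationConfig) -> EMState:
    """Standard CPD start: pooled variance, identity transform, omega0."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.size == 0 or Y.size == 0:
        raise ValueError("point sets must be non-empty")
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: scene is {X.shape[1]}-D, model is {Y.shape[1]}-D")
    n, m, d = X.shape[0], Y.shape[0], X.shape[1]
    sigma2 = float(cdist(X, Y, "sqeuclidean").sum() / (d * n * m))
    sigma2 = max(sigma2, cfg.sigma2_floor)
    return EMState(
        sigma2=sigma2,
        omega=float(np.clip(cfg.omega0, OMEGA_EPS, 1.0 - OMEGA_EPS)),
        P=np.zeros((m, n)),
        P_outlier=np.ones(n),
        W=np.zeros((m, d)),
        G=gaussian_kernel(Y, cfg.beta),
    )


def estep(
    X: np.ndarray,
    TY: np.ndarray,
    C: CostMatrix,
    sigma2: float,
    omega: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Membership posteriors with structure weighting and an outlier row.

    P_mn = C_nm exp(-||x_n - T(y_m)||^2 / 2sigma2) /
           [ sum_k C_nk exp(-||x_n - T(y_k)||^2 / 2sigma2)
             + omega * S_n * (2 pi sigma2)^{D/2} / ((1-omega) N) ]

    and P(M+1 | x_n) = 1 - sum_m P_mn.  With a uniform cost matrix
    (C_nm = 1, S_n = M) this is exactly the plain-CPD posterior.
    """
    if omega >= 1.0:
        raise ValueError("omega must be < 1 in the E-step")
    n, d = X.shape
    sq = cdist(X, TY, "sqeuclidean")               # (N, M)
    num = C.values * np.exp(-sq / (2.0 * sigma2))  # (N, M)
    uniform = omega * C.row_sums * (2.0 * np.pi * sigma2) ** (d / 2.0) / ((1.0 - omega) * n)
    denom = num.sum(axis=1) + uniform              # (N,)
    P = (num / denom[:, None]).T                   # (M, N)
    return P, 1.0 - P.sum(axis=0)


def update_sigma2(
    P: np.ndarray, X: np.ndarray, TY: np.ndarray, floor: float = 1e-8
) -> float:
    """Posterior-weighted mean squared residual, floored."""
    np_ = P.sum()
    if np_ <= 0.0:
        raise ValueError("degenerate posterior: all scene points classified as outliers")
    d = X.shape[1]
    sq = cdist(X, TY, "sqeuclidean")
    sigma2 = float((P.T * sq).sum() / (d * np_))
    return max(sigma2, floor)


def update_omega(
    P: np.ndarray,
    omega_old: float,
    t: int,
    n_scene: int,
    schedule: str | float = "1/t",
) -> float:
    """Damped move toward the closed-form outlier weight.

    The Q-minimizer is ``omega_new = 1 - NP/N`` (the mean outlier
    posterior); adopting it outright overfits when the true outlier
    fraction is large, so the update is ``omega_old + alpha (omega_new -
    omega_old)`` with ``alpha = 1/t`` by default — full adoption at t = 1,
    then progressively smaller corrections.
    """
    omega_new = 1.0 - P.sum() / n_scene
    alpha = 1.0 / t if schedule == "1/t" else float(schedule)
    omega = omega_old + alpha * (omega_new - omega_old)
    return float(np.clip(omega, OMEGA_EPS, 1.0 - OMEGA_EPS))


def solve_coefficients(
    G: np.ndarray,
    P: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    lambda_: float,
    sigma2: float,
) -> np.ndarray:
    """Solve [G + lambda sigma2 diag(P1)^{-1}] W = diag(P1)^{-1} P X - Y.

    P1 is the vector of posterior row sums; rows with essentially no
    posterior mass get a huge diagonal entry, so those centroids follow
    the regularizer instead of noise.
    """
    p1 = P.sum(axis=1)
    dinv = np.where(p1 > P1_FLOOR, 1.0 / np.maximum(p1, P1_FLOOR), 1.0 / P1_FLOOR)
    A = G + lambda_ * sigma2 * np.diag(dinv)
    rhs = dinv[:, None] * (P @ X) - Y
    try:
        W = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise RuntimeError(f"kernel system singular after guarding: {exc}") from exc
    resid = np.linalg.norm(A @ W - rhs)
    scale = max(np.linalg.norm(rhs), 1.0)
    if resid > 1e-8 * scale:
        raise RuntimeError(
            f"kernel solve residual {resid:.3e} exceeds 1e-8 * ||rhs|| = {1e-8 * scale:.3e}"
        )
    return W


def transform(Y: np.ndarray, G: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Transformed model positions T(Y, W) = Y + G W."""
    return Y + G @ W


def objective_q(
    P: np.ndarray,
    X: np.ndarray,
    TY: np.ndarray,
    W: np.ndarray,
    G: np.ndarray,
    sigma2: float,
    omega: float,
    lambda_: float,
) -> float:
    """Penalized expected complete negative log-likelihood.

    Q = (1/2sigma2) sum_nm P_mn ||x_n - T(y_m)||^2 + (D NP / 2) log sigma2
        - NP log(1-omega) - (N-NP) log omega + (lambda/2) tr(W^T G W)

    The smoothness penalty ||Lv||^2 is realized as the RKHS norm
    tr(W^T G W) induced by the Gaussian kernel.
    """
    n, d = X.shape
    om = float(np.clip(omega, OMEGA_EPS, 1.0 - OMEGA_EPS))
    np_ = P.sum()
    sq = cdist(X, TY, "sqeuclidean")
    data = (P.T * sq).sum() / (2.0 * sigma2)
    return float(
        data
        + 0.5 * d * np_ * np.log(sigma2)
        - np_ * np.log(1.0 - om)
        - (n - np_) * np.log(om)
        + 0.5 * lambda_ * np.trace(W.T @ G @ W)
    )


def observed_nll(
    X: np.ndarray,
    TY: np.ndarray,
    C: CostMatrix,
    W: np.ndarray,
    G: np.ndarray,
    sigma2: float,
    omega: float,
    lambda_: float,
) -> float:
    """Penalized observed-data negative log-likelihood (constants dropped).

    -sum_n log[ omega/N + ((1-omega)/S_n) sum_m C_nm (2 pi sigma2)^{-D/2}
    exp(-||x_n - T(y_m)||^2 / 2 sigma2) ] + (lambda/2) tr(W^T G W).

    Unlike the expected complete-data objective of :func:`objective_q`,
    this is the quantity EM provably never increases (with omega and C
    fixed), so the engine uses it as the convergence monitor.
    """
    n, d = X.shape
    om = float(np.clip(omega, OMEGA_EPS, 1.0 - OMEGA_EPS))
    sq = cdist(X, TY, "sqeuclidean")
    gauss = (2.0 * np.pi * sigma2) ** (-d / 2.0) * np.exp(-sq / (2.0 * sigma2))
    mix = om / n + (1.0 - om) / C.row_sums * (C.values * gauss).sum(axis=1)
    return float(-np.log(mix).sum() + 0.5 * lambda_ * np.trace(W.T @ G @ W))


def _normalize(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    mu = points.mean(axis=0)
    centered = points - mu
    scale = float(np.sqrt((centered**2).sum(axis=1).mean()))
    if scale <= 0.0:
        scale = 1.0
    return centered / scale, mu, scale


def _extract_correspondences(
    P: np.ndarray, P_outlier: np.ndarray
) -> list[tuple[int, int, float]]:
    # scene point n -> argmax_m posterior, kept only when it beats the
    # outlier posterior; scene points below that are left unmatched
    out = []
    best = P.argmax(axis=0)
    for n in range(P.shape[1]):
        m = int(best[n])
        if P[m, n] > P_outlier[n]:
            out.append((n, m, float(P[m, n])))
    return out


def register(
    X: np.ndarray,
    Y: np.ndarray,
    cfg: RegistrationConfig | None = None,
    C: CostMatrix | None = None,
) -> RegistrationResult:
    """Register model Y onto scene X.

    Runs ``initialize`` then iterates E-step -> sigma2 -> omega (if
    ``auto_omega``) -> kernel solve -> transform -> objective, stopping on
    relative objective change or ``max_iter``.  Descriptor costs are built
    once from the initial (normalized) point sets and held fixed; the
    sharpening Gaussian distance term progressively dominates them as
    sigma2 shrinks, so the structure prior matters most early on.

    A precomputed ``C`` overrides the ``use_structure`` flag (expert use).
    """
    cfg = cfg or RegistrationConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must be 2-D arrays of matching dimension")
    d = X.shape[1]

    if cfg.normalize:
        Xn, mu_x, s_x = _normalize(X)
        Yn, _, _ = _normalize(Y)
        if cfg.working_scale != 1.0:
            Xn = Xn * cfg.working_scale
            Yn = Yn * cfg.working_scale
            s_x = s_x / cfg.working_scale
    else:
        Xn, mu_x, s_x = X, np.zeros(d), 1.0
        Yn = Y

    if C is None:
        if cfg.use_structure and d == 2:
            C = sc_cost_matrix(sc_descriptors(Xn), sc_descriptors(Yn), cfg.gamma)
        else:
            if cfg.use_structure and d != 2:
                warnings.warn(
                    "shape-context costs are 2-D only; falling back to uniform costs",
                    stacklevel=2,
                )
            C = uniform_cost_matrix(Xn.shape[0], Yn.shape[0])
    elif C.shape != (Xn.shape[0], Yn.shape[0]):
        raise ValueError(f"cost matrix shape {C.shape} does not match (N, M)")

    state = initialize(Xn, Yn, cfg)
    TY = Yn.copy()
    omega_trace, sigma2_trace, q_trace, nll_trace = [], [], [], []
    p_states = [] if cfg.keep_states else None
    w_states = [] if cfg.keep_states else None
    nll_prev = np.inf
    converged = False

    for t in range(1, cfg.max_iter + 1):
        state.t = t
        state.P, state.P_outlier = estep(Xn, TY, C, state.sigma2, state.omega)
        state.sigma2 = update_sigma2(state.P, Xn, TY, cfg.sigma2_floor)
        if cfg.auto_omega:
            state.omega = update_omega(
                state.P, state.omega, t, Xn.shape[0], cfg.alpha_schedule
            )
        state.W = solve_coefficients(
            state.G, state.P, Xn, Yn, cfg.lambda_, state.sigma2
        )
        TY = transform(Yn, state.G, state.W)
        state.Q = objective_q(
            state.P, Xn, TY, state.W, state.G, state.sigma2, state.omega, cfg.lambda_
        )
        nll = observed_nll(
            Xn, TY, C, state.W, state.G, state.sigma2, state.omega, cfg.lambda_
        )
        omega_trace.append(state.omega)
        sigma2_trace.append(state.sigma2)
        q_trace.append(state.Q)
        nll_trace.append(nll)
        if cfg.keep_states:
            p_states.append(state.P.copy())
            w_states.append(state.W.copy())
        logger.debug(
            "t=%d nll=%.6g Q=%.6g sigma2=%.3g omega=%.4f", t, nll, state.Q, state.sigma2, state.omega
        )
        if np.isfinite(nll_prev) and abs(nll - nll_prev) < cfg.tol * max(abs(nll), 1.0):
            converged = True
            break
        nll_prev = nll

    aligned = TY * s_x + mu_x  # model mapped into the scene frame
    return RegistrationResult(
        transformed_model=aligned,
        P_final=state.P,
        P_outlier=state.P_outlier,
        correspondences=_extract_correspondences(state.P, state.P_outlier),
        omega_trace=np.asarray(omega_trace),
        sigma2_trace=np.asarray(sigma2_trace),
        Q_trace=np.asarray(q_trace),
        nll_trace=np.asarray(nll_trace),
        n_iter=len(q_trace),
        converged=converged,
        config=cfg,
        P_states=p_states,
        W_states=w_states,
    )
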