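"""Independent scalar oracles for the EM equations.

Everything here is written as literal double loops over the printed
formulas, deliberately sharing no code with the package, so that agreement
with the vectorized implementation is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def estep_scalar(X, TY, C, S, sigma2, omega):
    """Membership posteriors by direct per-entry evaluation."""
    n, d = X.shape
    m = TY.shape[0]
    P = np.zeros((m, n))
    P_out = np.zeros(n)
    for j in range(n):
        denom = omega * S[j] * (2 * math.pi * sigma2) ** (d / 2) / ((1 - omega) * n)
        for k in range(m):
            denom += C[j, k] * math.exp(-sum((X[j, a] - TY[k, a]) ** 2 for a in range(d)) / (2 * sigma2))
        for i in range(m):
            num = C[j, i] * math.exp(-sum((X[j, a] - TY[i, a]) ** 2 for a in range(d)) / (2 * sigma2))
            P[i, j] = num / denom
        P_out[j] = 1.0 - P[:, j].sum()
    return P, P_out


def sigma2_scalar(P, X, TY):
    n, d = X.shape
    m = TY.shape[0]
    num = 0.0
    np_ = 0.0
    for i in range(m):
        for j in range(n):
            num += P[i, j] * sum((X[j, a] - TY[i, a]) ** 2 for a in range(d))
            np_ += P[i, j]
    return num / (d * np_)


def omega_scalar(P, omega_old, t, n_scene):
    omega_new = 1.0 - sum(P[i, j] for i in range(P.shape[0]) for j in range(P.shape[1])) / n_scene
    alpha = 1.0 / t
    return omega_old + alpha * (omega_new - omega_old)


def objective_scalar(P, X, TY, W, G, sigma2, omega, lam):
    n, d = X.shape
    m = TY.shape[0]
    data = 0.0
    np_ = 0.0
    for i in range(m):
        for j in range(n):
            data += P[i, j] * sum((X[j, a] - TY[i, a]) ** 2 for a in range(d))
            np_ += P[i, j]
    reg = 0.0
    for a in range(d):
        for i in range(m):
            for k in range(m):
                reg += W[i, a] * G[i, k] * W[k, a]
    return (
        data / (2 * sigma2)
        + d * np_ / 2 * math.log(sigma2)
        - np_ * math.log(1 - omega)
        - (n - np_) * math.log(omega)
        + lam / 2 * reg
    )


def transform_scalar(Y, G, W):
    m, d = Y.shape
    out = np.zeros_like(Y)
    for i in range(m):
        for a in range(d):
            out[i, a] = Y[i, a] + sum(G[i, k] * W[k, a] for k in range(m))
    return out


def reference_cpd_trace(X, Y, omega, lam, beta, max_iter):
    """Literal transcription of baseline coherent point drift.

    Plain-CPD posteriors (uniform memberships, fixed omega), the residual
    variance update and the kernel coefficient solve, iterated in the same
    order as the engine: posteriors -> variance (at the previous transform)
    -> coefficients (at the new variance) -> transform.

    Returns per-iteration lists of (P, sigma2, W).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, d = X.shape
    m = Y.shape[0]
    G = np.zeros((m, m))
    for i in range(m):
        for k in range(m):
            G[i, k] = math.exp(-sum((Y[i, a] - Y[k, a]) ** 2 for a in range(d)) / (2 * beta))
    sigma2 = sum(
        sum((X[j, a] - Y[i, a]) ** 2 for a in range(d)) for j in range(n) for i in range(m)
    ) / (d * n * m)
    TY = Y.copy()
    trace = []
    for _ in range(max_iter):
        # plain-CPD posterior: uniform memberships, M in the outlier term
        P = np.zeros((m, n))
        for j in range(n):
            denom = omega * m * (2 * math.pi * sigma2) ** (d / 2) / ((1 - omega) * n)
            for k in range(m):
                denom += math.exp(-sum((X[j, a] - TY[k, a]) ** 2 for a in range(d)) / (2 * sigma2))
            for i in range(m):
                P[i, j] = math.exp(
                    -sum((X[j, a] - TY[i, a]) ** 2 for a in range(d)) / (2 * sigma2)
                ) / denom
        sigma2 = sigma2_scalar(P, X, TY)
        p1 = P.sum(axis=1)
        dinv = np.array([1.0 / v if v > 1e-10 else 1e10 for v in p1])
        A = G + lam * sigma2 * np.diag(dinv)
        rhs = np.diag(dinv) @ P @ X - Y
        W = np.linalg.solve(A, rhs)
        TY = transform_scalar(Y, G, W)
        trace.append((P.copy(), sigma2, W.copy()))
    return trace
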