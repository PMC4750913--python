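"""Log-polar shape-context descriptors and the pairwise matching-cost matrix.

The shape context of a point is a 2-D log-polar histogram of the relative
positions of every other point in the set.  Radii are normalized by the mean
pairwise distance of the set (scale invariance) and angles are measured
relative to the direction from the point to the mass center of the shape
(rotation invariance); translation invariance is inherent in relative
coordinates.  Two descriptors are compared with a chi-square statistic turned
into a similarity ``C_nm = exp(-chi2 / (2*gamma))`` in (0, 1], which the
registration engine uses to re-weight GMM membership probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ShapeDescriptorSet",
    "CostMatrix",
    "sc_descriptors",
    "sc_cost_matrix",
    "uniform_cost_matrix",
]

#: default radial binning, in units of the mean pairwise distance
R_INNER = 0.125
R_OUTER = 2.0
N_RADIAL = 5
N_ANGULAR = 12


@dataclass
class ShapeDescriptorSet:
    """Per-point log-polar histograms for one point set.

    ``histograms`` holds the normalized descriptors (each row sums to 1);
    ``raw_counts`` the integer bin counts (each row sums to P-1, because
    out-of-range radii are clamped into the boundary bins rather than
    discarded).
    """

    histograms: np.ndarray          # (P, K), rows sum to 1
    raw_counts: np.ndarray          # (P, K), rows sum to P-1
    bin_edges_radial: np.ndarray    # (n_radial + 1,), mean-distance units
    bin_edges_angular: np.ndarray   # (n_angular + 1,), radians in [0, 2pi]
    reference_axis: np.ndarray      # (P, 2), unit vector point -> mass center

    @property
    def n_bins(self) -> int:
        return self.histograms.shape[1]


@dataclass
class CostMatrix:
    """Structure-similarity weights between a scene set (rows) and a model set.

    ``values[n, m]`` lies in (0, 1] and equals 1 iff the two histograms are
    identical.  ``row_sums[n] = sum_m values[n, m]`` is the S_n appearing in
    the outlier term of the membership posterior.
    """

    values: np.ndarray                      # (N, M)
    gamma: float
    row_sums: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.row_sums = self.values.sum(axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def uniform_cost_matrix(n_scene: int, n_model: int) -> CostMatrix:
    """All-ones cost matrix (S_n = M): recovers plain CPD memberships."""
    return CostMatrix(values=np.ones((n_scene, n_model)), gamma=np.inf)


def sc_descriptors(
    points: np.ndarray,
    n_radial: int = N_RADIAL,
    n_angular: int = N_ANGULAR,
    r_inner: float = R_INNER,
    r_outer: float = R_OUTER,
) -> ShapeDescriptorSet:
    """Compute one K = ``n_radial * n_angular`` histogram per point.

    Parameters
    ----------
    points
        (P, 2) coordinates, P >= 3.  Only 2-D sets are supported; the
        rotation normalization via the mass-center axis has no canonical
        3-D analogue here.
    n_radial, n_angular
        Log-radial and angular bin counts (default 5 x 12 = 60 bins, the
        classical shape-context layout).
    r_inner, r_outer
        Radial range in mean-pairwise-distance units; radii outside are
        clamped into the boundary bins so every histogram keeps all P-1
        neighbours.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError(
            f"shape-context descriptors require 2-D points, got shape {points.shape}"
        )
    n_pts = points.shape[0]
    if n_pts < 3:
        raise ValueError(f"need at least 3 points, got {n_pts}")

    center = points.mean(axis=0)
    dists = squareform(pdist(points))
    mean_dist = dists[np.triu_indices(n_pts, k=1)].mean()
    if mean_dist <= 0.0:
        raise ValueError("all points coincide; descriptors undefined")

    radial_edges = np.logspace(np.log10(r_inner), np.log10(r_outer), n_radial + 1)
    angular_edges = np.linspace(0.0, 2.0 * np.pi, n_angular + 1)

    # reference axis: point -> mass center; degenerate points fall back to +x
    to_center = center[None, :] - points
    axis_norm = np.linalg.norm(to_center, axis=1)
    degenerate = axis_norm < 1e-12 * mean_dist
    axis = np.where(degenerate[:, None], [1.0, 0.0], to_center / np.where(degenerate, 1.0, axis_norm)[:, None])
    axis_angle = np.arctan2(axis[:, 1], axis[:, 0])

    k_bins = n_radial * n_angular
    raw = np.zeros((n_pts, k_bins))
    log_edges = np.log(radial_edges)
    for i in range(n_pts):
        rel = np.delete(points, i, axis=0) - points[i]
        r = np.delete(dists[i], i) / mean_dist
        theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]) - axis_angle[i], 2.0 * np.pi)
        # clamp into [0, n_radial-1]: under/overflow radii land in boundary bins
        r_bin = np.clip(np.searchsorted(log_edges[1:-1], np.log(r), side="right"), 0, n_radial - 1)
        a_bin = np.minimum((theta / (2.0 * np.pi) * n_angular).astype(int), n_angular - 1)
        np.add.at(raw, (i, r_bin * n_angular + a_bin), 1.0)

    hist = raw / raw.sum(axis=1, keepdims=True)
    return ShapeDescriptorSet(
        histograms=hist,
        raw_counts=raw,
        bin_edges_radial=radial_edges,
        bin_edges_angular=angular_edges,
        reference_axis=axis,
    )


def sc_cost_matrix(
    desc_scene: ShapeDescriptorSet,
    desc_model: ShapeDescriptorSet,
    gamma: float = 0.1,
) -> CostMatrix:
    """Exponentiated chi-square similarity between two descriptor sets.

    ``C_nm = exp(-(1/(2*gamma)) * sum_k (h_n(k)-h_m(k))^2 / (h_n(k)+h_m(k)))``
    with 0/0 bins contributing 0.  Smaller gamma sharpens the similarity;
    the conventional default is 0.1.
    """
    if gamma <= 0.0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    if desc_scene.n_bins != desc_model.n_bins:
        raise ValueError(
            f"descriptor binning mismatch: {desc_scene.n_bins} vs {desc_model.n_bins} bins"
        )
    h_n = desc_scene.histograms[:, None, :]   # (N, 1, K)
    h_m = desc_model.histograms[None, :, :]   # (1, M, K)
    num = (h_n - h_m) ** 2
    den = h_n + h_m
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
    chi2 = terms.sum(axis=2)
    return CostMatrix(values=np.exp(-chi2 / (2.0 * gamma)), gamma=gamma)
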