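"""The five transfer-entropy estimators.

All estimators consume an :class:`~tebench.core.EmbeddedData` point cloud and
return a :class:`~tebench.core.TEResult` in nats.  They differ only in how
they approximate the entropies entering

    TE = H(Y | Y-) - H(Y | X-, Y-)
       = H(Y, Y-) - H(Y-) - H(Y, X-, Y-) + H(X-, Y-)

* ``LIN``  -- linear-Gaussian: conditional entropies from the residual
  variances of least-squares regressions; equivalent to half the log ratio
  of restricted to full residual variance (Granger causality / 2).
* ``KNN``  -- Kozachenko-Leonenko / Kraskov k-nearest-neighbor entropy with
  maximum-norm distances; the only estimator that may return negative TE.
* ``FBR``  -- fixed binning with ranking: plug-in entropies on Q equal-width
  bins per dimension after ordinal (rank) sampling, i.e. equal-frequency
  bins in value space.
* ``KDE``  -- product-Gaussian kernel density plug-in entropies with the
  Silverman-style bandwidth ``h = 1.06 * alpha * sigma * n**(-1/5)``.
* ``DVP``  -- Darbellay-Vajda adaptive partitioning of the ranked joint
  space: a cell is split into 2^d equal subcells only while a chi-square
  test rejects an even occupancy, and plug-in conditional entropies are
  read off the final cells.

Every estimator is a function of the embedded point cloud only, hence
invariant to a joint permutation of its rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma
from scipy.stats import chi2, rankdata

from .core import EmbeddedData, TEResult

__all__ = [
    "rank_transform",
    "te_linear",
    "te_knn",
    "knn_entropy",
    "te_fbr",
    "binned_entropy",
    "binned_conditional_entropy",
    "te_kde",
    "kde_entropy",
    "kde_bandwidth",
    "chi2_split_stat",
    "PartitionCell",
    "dv_partition",
    "partition_conditional_entropy",
    "te_dvp",
]


# ---------------------------------------------------------------------------
# ordinal sampling
# ---------------------------------------------------------------------------

def rank_transform(s) -> np.ndarray:
    """Replace observations by their ranks ``1..N`` (ordinal sampling).

    Ties are resolved by first-occurrence order, so the ranks are always a
    permutation of ``1..N``.  Ranking makes any estimator applied afterwards
    exactly invariant under strictly increasing transforms of the input.
    """
    arr = np.asarray(s, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cannot rank an empty series")
    return rankdata(arr, method="ordinal").astype(float)


# ---------------------------------------------------------------------------
# LIN: linear-Gaussian estimator
# ---------------------------------------------------------------------------

def _residual_variance(dep: np.ndarray, regressors: np.ndarray | None) -> float:
    """Residual variance (SSR / R) of an OLS fit with intercept."""
    R = dep.shape[0]
    if regressors is None:
        design = np.ones((R, 1))
    else:
        design = np.column_stack([np.ones(R), regressors])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                "singular regression design (constant or collinear columns)"
            )
    coef, *_ = np.linalg.lstsq(design, dep, rcond=None)
    resid = dep - design @ coef
    return float(resid @ resid) / R


def te_linear(e: EmbeddedData) -> TEResult:
    """Linear-Gaussian TE from regression residual variances.

    Under a joint Gaussian assumption ``H(Y|Z) = 0.5*log(2*pi*e*var(eps))``
    with ``eps`` the residuals of the regression of Y on Z, so the constants
    cancel and

        TE = 0.5 * log(var(resid restricted) / var(resid full))

    where the restricted model regresses the target present on the target
    past only and the full model adds the driver past.  Nonnegative up to
    numerical round-off.
    """
    v_restricted = _residual_variance(e.target_present, e.target_past)
    v_full = _residual_variance(
        e.target_present, np.column_stack([e.driver_past, e.target_past])
    )
    if v_full <= 0.0 or v_restricted <= 0.0:
        raise ValueError("zero residual variance: degenerate (noise-free) input")
    value = 0.5 * np.log(v_restricted / v_full)
    return TEResult(value, "LIN", {})


# ---------------------------------------------------------------------------
# KNN: Kozachenko-Leonenko / Kraskov estimator
# ---------------------------------------------------------------------------

def knn_entropy(points: np.ndarray, k: int) -> float:
    """Kozachenko-Leonenko differential entropy with max-norm distances.

    ``H = -psi(k) + psi(R) + (d/R) * sum_i log(eps_i)`` where ``eps_i`` is
    twice the maximum-norm distance from point ``i`` to its k-th nearest
    neighbor.  Under the max norm the unit-diameter ball has volume one, so
    no volume term appears.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    R, d = points.shape
    if not 1 <= k < R:
        raise ValueError(f"k must satisfy 1 <= k < R; got k={k}, R={R}")
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=k + 1, p=np.inf)
    eps = 2.0 * dist[:, -1]
    if np.any(eps <= 0.0):
        raise ValueError(
            "duplicate points give zero k-NN distance; enable jitter"
        )
    return float(-digamma(k) + digamma(R) + d * np.mean(np.log(eps)))


def _deterministic_jitter(points: np.ndarray, amplitude: float = 1e-10) -> np.ndarray:
    """Add tiny reproducible noise to break exact distance ties.

    Amplitude is ``1e-10`` times each column's standard deviation (or the
    bare amplitude for constant columns); the generator seed is fixed so the
    estimator stays a pure function of its input.
    """
    rng = np.random.default_rng(181081)
    scale = np.std(points, axis=0)
    scale = np.where(scale > 0, scale, 1.0) * amplitude
    return points + rng.uniform(-1.0, 1.0, size=points.shape) * scale


def _chebyshev_counts(sub: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Per-point count of neighbors strictly within ``radii`` (max norm)."""
    diff = np.abs(sub[:, None, :] - sub[None, :, :]).max(axis=-1)
    np.fill_diagonal(diff, np.inf)
    return (diff < radii[:, None]).sum(axis=1)


def te_knn(e: EmbeddedData, k: int = 5, jitter: bool = True) -> TEResult:
    """k-nearest-neighbor TE as a Kraskov-type conditional mutual information.

    TE(X -> Y) equals ``I(Y ; X- | Y-)``, estimated with the
    Frenzel-Pompe/Kraskov neighbor-counting scheme under the maximum norm:
    for each point the distance ``eps_i`` to its k-th nearest neighbor in
    the full joint space ``(Y, X-, Y-)`` sets a search radius, and the
    digamma-weighted counts of neighbors strictly inside that radius in the
    marginal subspaces combine as

        TE = psi(k) - < psi(n_{Y,Y-}+1) + psi(n_{X-,Y-}+1) - psi(n_{Y-}+1) >

    Evaluating every term at a shared per-point radius cancels the bias of
    the individual entropy terms, but single estimates may still come out
    negative on weakly coupled data.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError(f"k must be a positive integer, got {k!r}")
    if k >= e.rows:
        raise ValueError(f"k={k} must be smaller than the number of rows R={e.rows}")
    joint = e.full_joint()
    if jitter:
        joint = _deterministic_jitter(joint)
    m = e.driver_past.shape[1]
    y = joint[:, :1]
    xpast = joint[:, 1 : 1 + m]
    ypast = joint[:, 1 + m :]

    diff = np.abs(joint[:, None, :] - joint[None, :, :]).max(axis=-1)
    np.fill_diagonal(diff, np.inf)
    eps = np.partition(diff, k - 1, axis=1)[:, k - 1]
    if np.any(eps <= 0.0):
        raise ValueError("duplicate points give zero k-NN distance; enable jitter")

    n_y_ypast = _chebyshev_counts(np.column_stack([y, ypast]), eps)
    n_pasts = _chebyshev_counts(np.column_stack([xpast, ypast]), eps)
    n_ypast = _chebyshev_counts(ypast, eps)
    value = float(
        digamma(k)
        - np.mean(digamma(n_y_ypast + 1) + digamma(n_pasts + 1)
                  - digamma(n_ypast + 1))
    )
    return TEResult(value, "KNN", {"k": int(k)})


# ---------------------------------------------------------------------------
# FBR: fixed binning with ranking
# ---------------------------------------------------------------------------

def _bin_indices(col: np.ndarray, Q: int) -> np.ndarray:
    """Quantize one coordinate into Q equal-width bins over its range."""
    lo, hi = col.min(), col.max()
    if hi == lo:
        return np.zeros(col.shape[0], dtype=np.int64)
    edges = np.linspace(lo, hi, Q + 1)
    return np.clip(np.searchsorted(edges, col, side="right") - 1, 0, Q - 1)


def binned_entropy(points: np.ndarray, Q: int) -> float:
    """Plug-in entropy of a point cloud on a Q-per-dimension uniform grid.

    Empty bins contribute zero by the convention ``0*log(0) = 0``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    R, d = points.shape
    code = np.zeros(R, dtype=np.int64)
    for j in range(d):
        code = code * Q + _bin_indices(points[:, j], Q)
    counts = np.bincount(code)
    counts = counts[counts > 0]
    p = counts / R
    return float(-np.sum(p * np.log(p)))


def binned_conditional_entropy(target: np.ndarray, cond: np.ndarray, Q: int) -> float:
    """Plug-in conditional entropy ``H(target | cond)`` on the uniform grid.

    Equals ``-(1/R) * sum_ij r_ij * log(r_ij / r_j)`` over joint bins ``ij``
    with ``r_j`` the marginal count of the conditioning bin.
    """
    target = np.atleast_2d(np.asarray(target, dtype=float).reshape(len(cond), -1))
    cond = np.atleast_2d(np.asarray(cond, dtype=float))
    joint = np.column_stack([target, cond])
    return binned_entropy(joint, Q) - binned_entropy(cond, Q)


def te_fbr(e: EmbeddedData, Q: int = 4) -> TEResult:
    """Fixed-binning TE on Q equal-width bins per dimension.

    Intended to run on rank-transformed series (the dispatcher in
    :func:`tebench.core.estimate_te` ranks each full series first), in which
    case the equal-width bins are equal-frequency bins of the raw values.
    """
    if not isinstance(Q, (int, np.integer)) or Q < 2:
        raise ValueError(f"Q must be an integer >= 2, got {Q!r}")
    if Q > e.rows:
        raise ValueError(f"Q={Q} exceeds the number of embedded rows R={e.rows}")
    h_restricted = binned_conditional_entropy(
        e.target_present, e.target_past, Q
    )
    h_full = binned_conditional_entropy(e.target_present, e.both_pasts(), Q)
    return TEResult(h_restricted - h_full, "FBR", {"Q": int(Q)})


# ---------------------------------------------------------------------------
# KDE: Gaussian kernel density estimator
# ---------------------------------------------------------------------------

def kde_bandwidth(sigma: float, n: int, alpha: float = 1.0) -> float:
    """Per-dimension Gaussian kernel bandwidth ``1.06 * alpha * sigma * n**(-1/5)``."""
    return 1.06 * alpha * sigma * n ** (-0.2)


def kde_entropy(points: np.ndarray, alpha: float = 1.5) -> float:
    """Resubstitution entropy from a product-Gaussian kernel density.

    The density at each sample is the average of product Gaussian kernels
    centered on all samples (including itself), one bandwidth per dimension;
    the entropy is the empirical average of ``-log`` density.  The leave-in
    (resubstitution) form slightly inflates the density at each sample,
    which is the source of this estimator's positive TE bias.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    R, d = points.shape
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha!r}")
    sigma = points.std(axis=0, ddof=1)
    if np.any(sigma <= 0):
        raise ValueError("zero-variance dimension in KDE input")
    h = kde_bandwidth(sigma, R, alpha)
    u = (points[:, None, :] - points[None, :, :]) / h
    log_norm = d * 0.5 * np.log(2.0 * np.pi) + np.sum(np.log(h))
    kernels = np.exp(-0.5 * np.einsum("ijk,ijk->ij", u, u))
    dens = kernels.mean(axis=1) / np.exp(log_norm)
    return float(-np.mean(np.log(dens)))


def te_kde(e: EmbeddedData, alpha: float = 1.5) -> TEResult:
    """Kernel-density TE from the four joint-entropy terms."""
    h_y_ypast = kde_entropy(e.present_and_target_past(), alpha)
    h_ypast = kde_entropy(e.target_past, alpha)
    h_full = kde_entropy(e.full_joint(), alpha)
    h_pasts = kde_entropy(e.both_pasts(), alpha)
    value = h_y_ypast - h_ypast - h_full + h_pasts
    return TEResult(value, "KDE", {"alpha": float(alpha)})


# ---------------------------------------------------------------------------
# DVP: Darbellay-Vajda adaptive partitioning
# ---------------------------------------------------------------------------

def chi2_split_stat(counts: Sequence[int]) -> float:
    """Evenness statistic ``s = sum_i (M_i - mu)^2`` over subcell counts.

    ``counts`` holds the occupancies of the 2^d equal subcells of a cell
    (4 quadrants or 8 octants) and ``mu`` is the total count divided by the
    number of subcells.  The split test in :func:`dv_partition` rejects an
    even distribution when ``s`` exceeds ``mu`` times the chi-square
    critical value at the 5% level with ``2^d - 1`` degrees of freedom
    (i.e. ``s / mu`` is referred to the chi-square distribution).
    """
    arr = np.asarray(counts)
    if arr.ndim != 1 or arr.shape[0] not in (4, 8):
        raise ValueError(
            f"counts must be a vector of 4 or 8 subcell occupancies, "
            f"got shape {arr.shape}"
        )
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    mu = arr.sum() / arr.shape[0]
    return float(np.sum((arr - mu) ** 2))


@dataclass
class PartitionCell:
    """Axis-aligned half-open box ``lower <= coord < upper`` with its count."""

    lower: np.ndarray
    upper: np.ndarray
    count: int

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.lower >= self.upper):
            raise ValueError("cell bounds require lower < upper in every dimension")
        if self.count < 0:
            raise ValueError("cell count must be nonnegative")


def dv_partition(
    points: np.ndarray,
    significance: float = 0.05,
    min_points: int = 8,
    on_accept: str = "parent",
    initial_split: bool = False,
) -> List[PartitionCell]:
    """Recursive Darbellay-Vajda partition of a 2-D or 3-D point cloud.

    The box covering all points is first divided at its coordinate
    mid-points into 2^d equal subcells (``initial_split``); from there each
    cell is subdivided further only while the chi-square evenness test
    rejects a uniform occupancy of its subcells (see
    :func:`chi2_split_stat`).  Recursion stops in cells holding fewer than
    ``min_points`` points, below which the evenness test has less than one
    expected point per subcell.  ``on_accept`` controls what is kept when
    the test does not reject: the undivided parent cell (``"parent"``, the
    default) or the 2^d children (``"children"``).

    Returns the list of final non-empty cells; they are disjoint and their
    counts sum to the number of points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    R, d = pts.shape
    if R == 0:
        raise ValueError("cannot partition an empty point cloud")
    if d < 2:
        raise ValueError(f"partition requires at least 2 dimensions, got {d}")
    if on_accept not in ("parent", "children"):
        raise ValueError(f"on_accept must be 'parent' or 'children', got {on_accept!r}")
    n_sub = 2 ** d
    crit = chi2.ppf(1.0 - significance, df=n_sub - 1)
    root_lo = pts.min(axis=0) - 0.5
    root_hi = pts.max(axis=0) + 0.5
    cells: List[PartitionCell] = []
    # iterative stack to avoid recursion limits on pathological inputs;
    # the flag marks the initial cell, which is always subdivided once
    stack = [(np.arange(R), root_lo, root_hi, initial_split)]
    while stack:
        idx, lo, hi, force = stack.pop()
        n_here = idx.shape[0]
        if n_here < min_points:
            if n_here > 0:
                cells.append(PartitionCell(lo, hi, n_here))
            continue
        mid = 0.5 * (lo + hi)
        sub = pts[idx]
        code = np.zeros(n_here, dtype=np.int64)
        for j in range(d):
            code |= (sub[:, j] >= mid[j]).astype(np.int64) << j
        counts = np.bincount(code, minlength=n_sub)
        stat = chi2_split_stat(counts)
        mu = n_here / n_sub
        children = []
        for c in range(n_sub):
            bits = np.array([(c >> j) & 1 for j in range(d)], dtype=bool)
            lo_c = np.where(bits, mid, lo)
            hi_c = np.where(bits, hi, mid)
            children.append((idx[code == c], lo_c, hi_c))
        if stat > mu * crit:
            stack.extend((ci, lc, hc, False) for ci, lc, hc in children)
        elif force or on_accept == "children":
            for child_idx, lo_c, hi_c in children:
                if child_idx.shape[0] > 0:
                    cells.append(PartitionCell(lo_c, hi_c, child_idx.shape[0]))
        else:
            cells.append(PartitionCell(lo, hi, n_here))
    return cells


def partition_conditional_entropy(
    points: np.ndarray, cells: Sequence[PartitionCell]
) -> float:
    """Plug-in conditional entropy of the first coordinate given the rest.

    For each final cell with joint count ``r`` the conditioning count is the
    number of points whose conditioning coordinates (all but the first) fall
    inside the cell's conditioning bounds, regardless of the first
    coordinate.  Then ``H = -(1/R) * sum_cells r * log(r / r_cond)``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    R = pts.shape[0]
    h = 0.0
    for cell in cells:
        if cell.count == 0:
            continue
        mask = np.ones(R, dtype=bool)
        for j in range(1, pts.shape[1]):
            mask &= (pts[:, j] >= cell.lower[j]) & (pts[:, j] < cell.upper[j])
        r_cond = int(mask.sum())
        h -= cell.count * np.log(cell.count / r_cond)
    return float(h / R)


def _box_count(pts: np.ndarray, cell: PartitionCell, dims: Sequence[int]) -> int:
    """Number of points inside the cell's bounds along the given dimensions."""
    mask = np.ones(pts.shape[0], dtype=bool)
    for j in dims:
        mask &= (pts[:, j] >= cell.lower[j]) & (pts[:, j] < cell.upper[j])
    return int(mask.sum())


def te_dvp(
    e: EmbeddedData,
    significance: float = 0.05,
    min_points: int = 8,
    on_accept: str = "parent",
    initial_split: bool = False,
) -> TEResult:
    """Adaptive-partitioning TE on the ranked embedded blocks.

    Each embedded column is first replaced by its ranks (ordinal sampling),
    making the estimate exactly invariant under strictly increasing
    transforms of either series.  A single Darbellay-Vajda partition of the
    joint space ``(V, U-, V-)`` is built (chi-square evenness test with
    ``2^d - 1`` degrees of freedom), and all plug-in probabilities are read
    off each final cell and its axis-aligned projections:

        TE = (1/R) * sum_cells r * log( (r * r_{V-}) / (r_{U-,V-} * r_{V,V-}) )

    with ``r`` the cell count and ``r_S`` the count of points inside the
    cell's bounds along the dimension subset ``S``.  Evaluating both
    conditional entropies of ``TE = H(V|V-) - H(V|U-,V-)`` on the same
    partition keeps their resolutions comparable; the estimate is exactly
    zero for a single-cell partition.
    """
    joint = e.full_joint()
    ranked = np.column_stack(
        [rank_transform(joint[:, j]) for j in range(joint.shape[1])]
    )
    m = e.driver_past.shape[1]
    d = ranked.shape[1]
    dims_v_past = list(range(1 + m, d))          # V-
    dims_pasts = list(range(1, d))               # U-, V-
    dims_present_vpast = [0] + dims_v_past       # V, V-

    cells = dv_partition(ranked, significance, min_points, on_accept,
                         initial_split)
    R = e.rows
    te = 0.0
    for cell in cells:
        r = cell.count
        if r == 0:
            continue
        r_vpast = _box_count(ranked, cell, dims_v_past)
        r_pasts = _box_count(ranked, cell, dims_pasts)
        r_v_vpast = _box_count(ranked, cell, dims_present_vpast)
        te += r * (np.log(r) + np.log(r_vpast)
                   - np.log(r_pasts) - np.log(r_v_vpast))
    return TEResult(
        te / R,
        "DVP",
        {"significance": float(significance), "min_points": int(min_points),
         "on_accept": on_accept, "initial_split": bool(initial_split)},
    )
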