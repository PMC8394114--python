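"""Core containers, uniform time-delay embedding, and estimator dispatch.

Transfer entropy (TE) from a driver process ``X`` to a target process ``Y``
measures the reduction in uncertainty about the present sample of ``Y``
provided by the past of ``X`` over and above what the past of ``Y`` already
provides:

    TE(X -> Y) = H(Y | Y-) - H(Y | X-, Y-)

with all entropies in nats.  ``Y`` denotes the present sample of the target
and ``X-``, ``Y-`` are past-state vectors built by *uniform embedding*: the
driver past is ``(x[t-tau], x[t-2*tau], ..., x[t-m*tau])`` and the target
past is ``(y[t-tau], ..., y[t-n*tau])``, where ``tau`` is the embedding lag
and ``m``, ``n`` the embedding dimensions.

This module defines the shared data types (:class:`EmbeddingSpec`,
:class:`EmbeddedData`, :class:`TEResult`), input validation, the embedding
constructor :func:`build_embedding`, and the estimator dispatch
:func:`estimate_te` that routes to the five entropy estimators implemented
in :mod:`tebench.estimators`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "MIN_SERIES_LENGTH",
    "ESTIMATORS",
    "EmbeddingSpec",
    "EmbeddedData",
    "TEResult",
    "as_series",
    "build_embedding",
    "estimate_te",
]

#: Shortest series accepted for TE estimation.  Below this every estimator's
#: probability-mass approximation is meaningless and the KNN preconditions
#: (k < number of embedded rows) start to fail.
MIN_SERIES_LENGTH = 20

#: Names of the supported entropy estimators.
ESTIMATORS = ("LIN", "KNN", "FBR", "KDE", "DVP")


def as_series(values, name: str = "series") -> np.ndarray:
    """Validate and convert ``values`` to a 1-D float array.

    Raises ``ValueError`` for empty, multi-dimensional, or non-finite input.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values (NaN or Inf)")
    return arr


@dataclass(frozen=True)
class EmbeddingSpec:
    """Uniform-embedding parameters.

    Parameters
    ----------
    tau : int
        Embedding lag in samples (>= 1).
    m : int
        Driver embedding dimension: number of lagged driver samples.
    n : int
        Target embedding dimension: number of lagged target samples.

    The defaults ``m = n = 1`` use a single lagged sample per process, the
    configuration under which the adaptive-partitioning estimator operates
    in its native three-dimensional joint space.
    """

    tau: int = 1
    m: int = 1
    n: int = 1

    def __post_init__(self):
        for attr in ("tau", "m", "n"):
            v = getattr(self, attr)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{attr} must be a positive integer, got {v!r}")

    @property
    def depth(self) -> int:
        """Number of leading samples consumed by the embedding."""
        return max(self.m, self.n) * self.tau


@dataclass
class EmbeddedData:
    """Aligned embedded blocks: the target present and both pasts.

    Row ``t`` of every block refers to the same time index, so the blocks can
    be concatenated column-wise to form joint point clouds.
    """

    target_present: np.ndarray  # shape (R,)
    driver_past: np.ndarray     # shape (R, m)
    target_past: np.ndarray     # shape (R, n)

    def __post_init__(self):
        self.target_present = np.asarray(self.target_present, dtype=float).ravel()
        self.driver_past = np.atleast_2d(np.asarray(self.driver_past, dtype=float))
        self.target_past = np.atleast_2d(np.asarray(self.target_past, dtype=float))
        R = self.target_present.shape[0]
        if self.driver_past.shape[0] != R or self.target_past.shape[0] != R:
            raise ValueError("embedded blocks have mismatched row counts")
        if R == 0:
            raise ValueError("embedding produced no rows")

    @property
    def rows(self) -> int:
        return self.target_present.shape[0]

    # -- joint point clouds used by the estimators ----------------------
    def present_and_target_past(self) -> np.ndarray:
        """Columns ``[Y, Y-]``."""
        return np.column_stack([self.target_present, self.target_past])

    def both_pasts(self) -> np.ndarray:
        """Columns ``[X-, Y-]``."""
        return np.column_stack([self.driver_past, self.target_past])

    def full_joint(self) -> np.ndarray:
        """Columns ``[Y, X-, Y-]``."""
        return np.column_stack(
            [self.target_present, self.driver_past, self.target_past]
        )


@dataclass
class TEResult:
    """A transfer-entropy estimate in nats.

    ``value`` may be negative for the k-nearest-neighbor estimator, which is
    not constrained to return nonnegative estimates.
    """

    value: float
    estimator: str
    params: Mapping[str, object] = field(default_factory=dict)
    spec: Optional[EmbeddingSpec] = None

    def __post_init__(self):
        self.value = float(self.value)
        if not np.isfinite(self.value):
            raise ValueError("TE value is not finite")
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}")


def build_embedding(x, y, spec: EmbeddingSpec) -> EmbeddedData:
    """Build aligned uniform-embedding blocks from two equal-length series.

    The first usable sample is at index ``max(m, n) * tau`` (0-based), so the
    number of embedded rows is ``R = N - max(m, n) * tau``.

    Raises
    ------
    ValueError
        If the series lengths differ or the embedding exhausts the series.
    """
    x = as_series(x, "x")
    y = as_series(y, "y")
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"series length mismatch: len(x)={x.shape[0]}, len(y)={y.shape[0]}"
        )
    N = x.shape[0]
    p = spec.depth
    if p >= N:
        raise ValueError(
            f"embedding exhausts the series: max(m,n)*tau={p} >= N={N}"
        )
    target_present = y[p:]
    driver_past = np.column_stack(
        [x[p - j * spec.tau : N - j * spec.tau] for j in range(1, spec.m + 1)]
    )
    target_past = np.column_stack(
        [y[p - j * spec.tau : N - j * spec.tau] for j in range(1, spec.n + 1)]
    )
    return EmbeddedData(target_present, driver_past, target_past)


def estimate_te(
    x,
    y,
    spec: Optional[EmbeddingSpec] = None,
    estimator: str = "DVP",
    params: Optional[Mapping[str, object]] = None,
) -> TEResult:
    """Estimate TE from driver ``x`` to target ``y``.

    Parameters
    ----------
    x, y : array-like
        Equal-length series of at least ``MIN_SERIES_LENGTH`` samples.
    spec : EmbeddingSpec, optional
        Embedding lag and dimensions; defaults to ``tau=1, m=n=1``.
    estimator : str
        One of ``LIN``, ``KNN``, ``FBR``, ``KDE``, ``DVP`` (case-insensitive).
    params : mapping, optional
        Estimator parameters, e.g. ``{"k": 5}`` for KNN, ``{"Q": 4}`` for
        FBR, ``{"alpha": 1.5}`` for KDE.

    Notes
    -----
    The fixed-binning estimator is applied after replacing each full series
    by its ranks (ordinal sampling), making its equal-width bins in rank
    space equal-frequency bins in value space.  The adaptive-partitioning
    estimator performs its own ranking of the embedded blocks.
    """
    from . import estimators as _est

    name = str(estimator).upper()
    if name not in ESTIMATORS:
        raise ValueError(
            f"unknown estimator {estimator!r}; expected one of {ESTIMATORS}"
        )
    x = as_series(x, "x")
    y = as_series(y, "y")
    if x.shape[0] != y.shape[0]:
        raise ValueError("series length mismatch")
    if x.shape[0] < MIN_SERIES_LENGTH:
        raise ValueError(
            f"series too short for TE estimation: N={x.shape[0]} < "
            f"{MIN_SERIES_LENGTH}"
        )
    if spec is None:
        spec = EmbeddingSpec()
    params = dict(params or {})

    if name == "FBR":
        x_in = _est.rank_transform(x)
        y_in = _est.rank_transform(y)
    else:
        x_in, y_in = x, y
    e = build_embedding(x_in, y_in, spec)

    fn = {
        "LIN": _est.te_linear,
        "KNN": _est.te_knn,
        "FBR": _est.te_fbr,
        "KDE": _est.te_kde,
        "DVP": _est.te_dvp,
    }[name]
    try:
        result = fn(e, **params)
    except TypeError as exc:
        raise ValueError(f"invalid parameters for {name}: {params!r}") from exc
    return replace(result, spec=spec)
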