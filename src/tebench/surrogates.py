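"""Surrogate-data significance testing for transfer entropy.

Two surrogate constructions separate linear from nonlinear coupling:

* **IRS** (iteratively refined surrogates): the classic univariate IAAFT
  scheme applied to one signal at a time.  Each surrogate preserves that
  signal's amplitude distribution exactly (the final step is a rank remap
  onto the sorted original values) and its power spectrum approximately,
  while destroying every dependence on the other signal.
* **IMS** (iterative multivariate surrogates): the Schreiber-Schmitz
  multivariate extension.  A single phase rotation per frequency is applied
  to both channels, preserving the phase differences and hence the
  cross-spectrum (linear coupling), while any nonlinear dependence is
  destroyed.  Per-channel distributions are again preserved exactly.

The one-sided test computes TE on the original pair and on ``n_surr``
surrogate pairs; the original is significant iff it strictly exceeds every
surrogate value.  With 19 surrogates this is a 5% level test (1/20), and 20
surrogates give a rejection probability of 1/21 under the null.  Combining
the IRS and IMS outcomes classifies the interaction: significance under IRS
alone indicates a (mostly) linear interaction; significance under IMS
indicates a nonlinear component; significance under both leaves the linear
component inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np

from .core import EmbeddingSpec, MIN_SERIES_LENGTH, as_series, estimate_te

__all__ = [
    "MIN_SURROGATES",
    "generate_irs",
    "generate_ims",
    "SurrogateTestResult",
    "test_significance",
    "InteractionClass",
    "classify_interaction",
]

#: Minimum surrogate count for a one-sided test at the 5% level.
MIN_SURROGATES = 19


def _spectral_discrepancy(amp: np.ndarray, target_amp: np.ndarray) -> float:
    norm = np.linalg.norm(target_amp)
    if norm == 0:
        return 0.0
    return float(np.linalg.norm(amp - target_amp) / norm)


def _rank_remap(values: np.ndarray, sorted_target: np.ndarray) -> np.ndarray:
    """Replace values by the sorted target values with the same rank order."""
    out = np.empty_like(sorted_target)
    out[np.argsort(values, kind="stable")] = sorted_target
    return out


def generate_irs(
    s,
    seed: Optional[int] = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> np.ndarray:
    """Univariate IAAFT surrogate of one series.

    Alternately enforces the original amplitude spectrum (substitute the
    original Fourier magnitudes, keep the current phases) and the original
    value distribution (rank remap onto the sorted original values) until
    the relative spectral discrepancy falls below ``tol`` or ``max_iter``
    iterations are reached.  The surrogate's sorted values equal the sorted
    originals exactly.
    """
    s = as_series(s, "series")
    if s.shape[0] < MIN_SERIES_LENGTH:
        raise ValueError(f"series too short for surrogate generation: N={s.shape[0]}")
    rng = np.random.default_rng(seed)
    n = s.shape[0]
    sorted_vals = np.sort(s)
    target_amp = np.abs(np.fft.rfft(s))
    surrogate = rng.permutation(s)
    for _ in range(max_iter):
        spec = np.fft.rfft(surrogate)
        phases = np.angle(spec)
        surrogate = np.fft.irfft(target_amp * np.exp(1j * phases), n=n)
        surrogate = _rank_remap(surrogate, sorted_vals)
        err = _spectral_discrepancy(np.abs(np.fft.rfft(surrogate)), target_amp)
        if err < tol:
            break
    return surrogate


def generate_ims(
    x,
    y,
    seed: Optional[int] = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> Tuple[np.ndarray, np.ndarray]:
    """Multivariate IAAFT surrogate pair preserving the cross-spectrum.

    Every iteration rotates both channels' original Fourier phases by one
    common per-frequency angle -- chosen as the circular mean of the
    channels' current phase offsets from the original phases, the common
    rotation closest to the current state -- then remaps each channel onto
    its sorted original values.  Phase *differences* between channels are
    preserved exactly at the spectral step, so linear cross-correlation
    survives while nonlinear dependence does not.
    """
    x = as_series(x, "x")
    y = as_series(y, "y")
    if x.shape[0] != y.shape[0]:
        raise ValueError("series length mismatch")
    if x.shape[0] < MIN_SERIES_LENGTH:
        raise ValueError(f"series too short for surrogate generation: N={x.shape[0]}")
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    channels = [x, y]
    sorted_vals = [np.sort(c) for c in channels]
    orig_spec = [np.fft.rfft(c) for c in channels]
    amp = [np.abs(sp) for sp in orig_spec]
    phase0 = [np.angle(sp) for sp in orig_spec]
    n_freq = amp[0].shape[0]

    def _constrain(rot: np.ndarray) -> np.ndarray:
        # keep the surrogate exactly real-valued: DC stays untouched and,
        # for even n, so does the Nyquist bin
        rot = rot.copy()
        rot[0] = 0.0
        if n % 2 == 0:
            rot[-1] = 0.0
        return rot

    rot = _constrain(rng.uniform(0.0, 2.0 * np.pi, n_freq))
    surr = [
        np.fft.irfft(amp[c] * np.exp(1j * (phase0[c] + rot)), n=n)
        for c in range(2)
    ]
    surr = [_rank_remap(surr[c], sorted_vals[c]) for c in range(2)]
    for _ in range(max_iter):
        offsets = np.zeros(n_freq, dtype=complex)
        for c in range(2):
            cur_phase = np.angle(np.fft.rfft(surr[c]))
            offsets += np.exp(1j * (cur_phase - phase0[c]))
        rot = _constrain(np.angle(offsets))
        surr = [
            np.fft.irfft(amp[c] * np.exp(1j * (phase0[c] + rot)), n=n)
            for c in range(2)
        ]
        surr = [_rank_remap(surr[c], sorted_vals[c]) for c in range(2)]
        err = max(
            _spectral_discrepancy(np.abs(np.fft.rfft(surr[c])), amp[c])
            for c in range(2)
        )
        if err < tol:
            break
    return surr[0], surr[1]


@dataclass
class SurrogateTestResult:
    """Outcome of a one-sided surrogate significance test."""

    original_te: float
    surrogate_te: np.ndarray
    significant: bool
    surrogate_kind: str

    def __post_init__(self):
        self.surrogate_te = np.asarray(self.surrogate_te, dtype=float)
        if self.surrogate_te.shape[0] < MIN_SURROGATES:
            raise ValueError(
                f"at least {MIN_SURROGATES} surrogates are required, got "
                f"{self.surrogate_te.shape[0]}"
            )
        if self.surrogate_kind not in ("IRS", "IMS"):
            raise ValueError(f"surrogate_kind must be IRS or IMS, got {self.surrogate_kind!r}")


def test_significance(
    x,
    y,
    spec: Optional[EmbeddingSpec] = None,
    estimator: str = "DVP",
    params: Optional[Mapping] = None,
    surrogate_kind: str = "IRS",
    n_surr: int = 20,
    seed: Optional[int] = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> SurrogateTestResult:
    """One-sided surrogate test of TE from driver ``x`` to target ``y``.

    For IRS surrogates only the driver is replaced (the target keeps its
    own predictable structure, matching the null of no driver-to-target
    transfer); for IMS both channels are jointly surrogated.  Significant
    iff the original TE strictly exceeds every surrogate TE -- ties count
    against significance.
    """
    kind = str(surrogate_kind).upper()
    if kind not in ("IRS", "IMS"):
        raise ValueError(f"surrogate_kind must be 'IRS' or 'IMS', got {surrogate_kind!r}")
    if n_surr < MIN_SURROGATES:
        raise ValueError(
            f"a one-sided 5% test needs at least {MIN_SURROGATES} surrogates, "
            f"got n_surr={n_surr}"
        )
    original = estimate_te(x, y, spec, estimator, params).value
    rng = np.random.default_rng(seed)
    te_surr = np.empty(n_surr)
    for i in range(n_surr):
        child = int(rng.integers(0, 2 ** 31))
        if kind == "IRS":
            xs = generate_irs(x, seed=child, max_iter=max_iter, tol=tol)
            ys = np.asarray(y, dtype=float)
        else:
            xs, ys = generate_ims(x, y, seed=child, max_iter=max_iter, tol=tol)
        te_surr[i] = estimate_te(xs, ys, spec, estimator, params).value
    significant = bool(original > te_surr.max())
    return SurrogateTestResult(original, te_surr, significant, kind)


@dataclass(frozen=True)
class InteractionClass:
    """Linear/nonlinear interaction classification from the two tests."""

    linear: str     # "yes" | "no" | "inconclusive"
    nonlinear: str  # "yes" | "no"


def classify_interaction(
    irs: SurrogateTestResult, ims: SurrogateTestResult
) -> InteractionClass:
    """Combine IRS and IMS test outcomes into an interaction class.

    ======  ======  ==============  =========
    IRS     IMS     linear          nonlinear
    ======  ======  ==============  =========
    NS      NS      no              no
    S       NS      yes             no
    S       S       inconclusive    yes
    NS      S       no              yes
    ======  ======  ==============  =========

    IMS preserves linear coupling, so IMS significance can only come from a
    nonlinear component; IRS significance alone indicates a mostly linear
    interaction.  The (NS, S) row does not arise in the three canonical
    outcomes but follows the same rule: IMS significance implies a
    nonlinear component.
    """
    if irs.surrogate_kind != "IRS" or ims.surrogate_kind != "IMS":
        raise ValueError("expected an IRS result and an IMS result, in that order")
    if irs.significant and ims.significant:
        return InteractionClass("inconclusive", "yes")
    if irs.significant:
        return InteractionClass("yes", "no")
    if ims.significant:
        return InteractionClass("no", "yes")
    return InteractionClass("no", "no")
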