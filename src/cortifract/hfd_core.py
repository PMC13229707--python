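"""Higuchi fractal dimension.

For a series ``X(1..N)`` and scale ``k``, the normalized curve length at
offset ``m`` (1-based, ``1 <= m <= k``) is

    L_m(k) = (N - 1) / (q_m * k^2) * sum_{i=1..q_m} |X(m + i k) - X(m + (i-1) k)|,

with ``q_m = floor((N - m) / k)`` increments, and the scale-level length
is the offset average ``L(k) = mean_m L_m(k)``.  For a fractal series
``L(k) ~ k^(-D)``, so the fractal dimension is the ordinary
least-squares slope of ``log L(k)`` against ``log(1/k)`` over
``k = 1..k_max``.  A smooth curve gives D near 1, uncorrelated noise
near 2, and fractional Brownian motion with Hurst exponent H gives
D = 2 - H, which is the analytic target used to validate the estimator.

The choice of ``k_max`` matters; :mod:`cortifract.scaling_region`
selects it from the onset of the linear scaling region of the
log-log curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSignalError, ParameterError

__all__ = [
    "HFDCurve",
    "HFDEstimate",
    "curve_length_lm",
    "aggregate_length",
    "hfd_curve",
    "fit_loglog",
    "hfd_profile",
    "higuchi_fd",
]


@dataclass
class HFDCurve:
    """Curve lengths L(k) for k = 1..K_eval of one series."""

    k_values: np.ndarray  # strictly increasing integers
    L_of_k: np.ndarray  # one non-negative length per k
    N: int  # length of the originating series
    lm_table: dict[int, np.ndarray] | None = None  # optional per-(k, m) lengths

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.L_of_k = np.asarray(self.L_of_k, dtype=float)
        if self.k_values.size != self.L_of_k.size:
            raise ParameterError("k_values and L_of_k must have equal length")
        if np.any(np.diff(self.k_values) <= 0):
            raise ParameterError("k_values must be strictly increasing")
        if np.any(self.L_of_k < 0):
            raise ParameterError("curve lengths must be non-negative")


@dataclass
class HFDEstimate:
    """Result of one log-log fit: the fractal dimension and diagnostics."""

    fd: float  # slope of log L(k) on log(1/k); the Higuchi dimension
    k_max: int  # largest scale included in the fit
    r2: float  # coefficient of determination of the fit
    intercept: float


def _validate_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ParameterError("series must have at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ParameterError("series contains non-finite values")
    return x


def curve_length_lm(x, k: int, m: int) -> float:
    """Normalized curve length at scale ``k`` and offset ``m`` (1-based).

    Direct transcription of the definition; the vectorized path in
    :func:`aggregate_length` is tested against this reference.
    """
    x = _validate_series(x)
    n = x.size
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if not 1 <= m <= k:
        raise ParameterError(f"offset m={m} out of range 1..{k}")
    q = (n - m) // k
    if q < 1:
        raise ParameterError(
            f"k={k} too large for offset m={m} with N={n}: no increments"
        )
    # 1-based X(j) is x[j-1]
    idx = m + k * np.arange(q + 1)  # X(m), X(m+k), ..., X(m+qk)
    total = float(np.abs(np.diff(x[idx - 1])).sum())
    return (n - 1) / (q * k * k) * total


def aggregate_length(x, k: int) -> float:
    """Offset-averaged curve length ``L(k) = mean_{m=1..k} L_m(k)``.

    Requires every offset to contribute at least one increment
    (``N >= 2k``); raises otherwise, naming the largest feasible scale.
    """
    x = _validate_series(x)
    n = x.size
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if n < 2 * k:
        raise ParameterError(
            f"k={k} infeasible for N={n}: offsets m>{n - k} have no "
            f"increments (max feasible k is {n // 2})"
        )
    # |X(j+k) - X(j)| for every j; the increment at 0-based position p
    # belongs to offset m = (p mod k) + 1.
    y = np.abs(x[k:] - x[:-k])
    ny = y.size
    full = ny // k
    per_offset = y[: full * k].reshape(full, k).sum(axis=0)
    rem = ny - full * k
    if rem:
        per_offset[:rem] += y[full * k :]
    m = np.arange(1, k + 1)
    q = (n - m) // k
    lm = (n - 1) / (q * k * k) * per_offset
    return float(lm.mean())


def hfd_curve(x, k_eval_max: int = 100, keep_lm: bool = False) -> HFDCurve:
    """Compute L(k) for every k = 1..k_eval_max on one series."""
    x = _validate_series(x)
    n = x.size
    if k_eval_max < 2:
        raise ParameterError("k_eval_max must be >= 2")
    if n < 2 * k_eval_max:
        raise ParameterError(
            f"series too short (N={n}) for k_eval_max={k_eval_max}; "
            f"max feasible is {n // 2}"
        )
    ks = np.arange(1, k_eval_max + 1)
    lengths = np.array([aggregate_length(x, int(k)) for k in ks])
    lm_table = None
    if keep_lm:
        lm_table = {
            int(k): np.array([curve_length_lm(x, int(k), m) for m in range(1, k + 1)])
            for k in ks
        }
    return HFDCurve(k_values=ks, L_of_k=lengths, N=n, lm_table=lm_table)


def fit_loglog(curve: HFDCurve, k_max: int) -> HFDEstimate:
    """OLS fit of log L(k) on log(1/k) over k = 1..k_max.

    Natural logs; the slope is base-invariant.  The estimate is not
    clamped to [1, 2]: finite-sample drift outside the idealized range
    is informative, and clamping would hide estimator bugs.
    """
    if k_max < 2:
        raise ParameterError("k_max must be >= 2 (at least two points to fit)")
    mask = curve.k_values <= k_max
    ks = curve.k_values[mask]
    if ks.size < 2 or ks.max() < k_max:
        raise ParameterError(
            f"curve covers k up to {curve.k_values.max()}, need {k_max}"
        )
    L = curve.L_of_k[mask]
    if np.any(L <= 0):
        raise DegenerateSignalError(
            "L(k) = 0 in the fit range (constant or dead signal); "
            "log-log fit undefined"
        )
    xlog = np.log(1.0 / ks)
    ylog = np.log(L)
    res = stats.linregress(xlog, ylog)
    r2 = float(res.rvalue**2) if np.ptp(ylog) > 0 else 1.0
    return HFDEstimate(
        fd=float(res.slope), k_max=int(k_max), r2=r2, intercept=float(res.intercept)
    )


def hfd_profile(x, k_eval_max: int = 100) -> list[HFDEstimate]:
    """One estimate per candidate ``k_max`` in 2..k_eval_max.

    L(k) is computed once per k and reused across all fits, so scanning
    the whole candidate range costs barely more than a single estimate.
    """
    curve = hfd_curve(x, k_eval_max=k_eval_max)
    return [fit_loglog(curve, k) for k in range(2, k_eval_max + 1)]


def higuchi_fd(x, k_max: int) -> HFDEstimate:
    """Convenience: curve lengths up to ``k_max`` plus the log-log fit."""
    curve = hfd_curve(x, k_eval_max=k_max)
    return fit_loglog(curve, k_max)
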