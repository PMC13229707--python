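"""Objective selection of k_max from the linear scaling region.

The log-log curve of L(k) against 1/k is only linear where the series is
self-similar; at small k preprocessing (band-pass smoothing, anti-alias
filtering) bends the curve.  The detector finds the smallest scale
``k_onset`` from which the remaining suffix of the curve is linear
(suffix R^2 >= threshold, default 0.99), and group-specific onsets are
harmonized to a single per-study value by taking their upper bound, so
one fit range is comparable across all groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .errors import ParameterError, ScalingDetectionError
from .hfd_core import HFDCurve

__all__ = ["ScalingRegion", "detect_onset", "harmonize_kmax", "group_mean_curve"]


@dataclass
class ScalingRegion:
    """Detected linear scaling region of one (group) log-log curve."""

    k_onset: int  # first scale of the linear segment; the group k_max
    r2_segment: float  # R^2 of the line fitted over the segment
    segment_range: tuple[int, int]  # (k_onset, k_eval)


def detect_onset(
    curve: HFDCurve,
    r2_threshold: float = 0.99,
    k_eval: int = 100,
    min_segment: int = 10,
) -> ScalingRegion:
    """Smallest ``k_onset`` whose suffix fit reaches the R^2 threshold.

    Scans candidates ``k_onset = 2 .. k_eval - min_segment + 1`` and fits
    a least-squares line to ``(log 1/k, log L(k))`` for
    ``k = k_onset..k_eval``; the first candidate with R^2 >= threshold
    wins (first crossing gives the widest usable scaling region).
    ``min_segment`` guards against vacuously linear short suffixes (any
    2-point fit has R^2 = 1); a segment shorter than ~10 scales is not
    evidence of self-similarity.

    Raises :class:`ScalingDetectionError`, carrying the best candidate,
    when no suffix qualifies.
    """
    if not 0 < r2_threshold <= 1:
        raise ParameterError("r2_threshold must be in (0, 1]")
    if min_segment < 2:
        raise ParameterError("min_segment must be >= 2")
    mask = curve.k_values <= k_eval
    ks = curve.k_values[mask]
    if ks.size == 0 or ks.max() < k_eval:
        raise ParameterError(
            f"curve covers k up to {curve.k_values.max()}, need k_eval={k_eval}"
        )
    L = curve.L_of_k[mask]
    if np.any(L <= 0):
        raise ParameterError("detect_onset requires positive L(k) everywhere")
    xlog = np.log(1.0 / ks)
    ylog = np.log(L)

    best_k, best_r2 = -1, -np.inf
    last_candidate = k_eval - min_segment + 1
    for k_onset in range(2, last_candidate + 1):
        sel = ks >= k_onset
        res = stats.linregress(xlog[sel], ylog[sel])
        r2 = float(res.rvalue**2)
        if r2 > best_r2:
            best_k, best_r2 = k_onset, r2
        if r2 >= r2_threshold:
            return ScalingRegion(
                k_onset=k_onset, r2_segment=r2, segment_range=(k_onset, k_eval)
            )
    raise ScalingDetectionError(
        f"no scaling-region onset with R^2 >= {r2_threshold} "
        f"(best: k={best_k}, R^2={best_r2:.4f})",
        best_k=best_k,
        best_r2=best_r2,
    )


def harmonize_kmax(
    regions: Mapping[str, ScalingRegion | int] | Iterable[ScalingRegion | int],
) -> int:
    """Common k_max for a study: the upper bound of group-specific onsets.

    Accepts a mapping ``{group: region}`` or a plain iterable of regions
    (or bare integers).  Using the maximum guarantees every group's
    linear region is fully inside the common fit range.
    """
    if isinstance(regions, Mapping):
        values = list(regions.values())
    else:
        values = list(regions)
    if not values:
        raise ParameterError("harmonize_kmax needs at least one group onset")
    onsets = [v.k_onset if isinstance(v, ScalingRegion) else int(v) for v in values]
    return max(onsets)


def group_mean_curve(curves: Iterable[HFDCurve]) -> HFDCurve:
    """Point-wise geometric mean of L(k) across a group's epochs.

    Averaging in log space matches the log-log domain in which the onset
    is detected; all curves must share the same k grid.
    """
    curves = list(curves)
    if not curves:
        raise ParameterError("group_mean_curve needs at least one curve")
    k0 = curves[0].k_values
    logs = []
    for c in curves:
        if c.k_values.shape != k0.shape or np.any(c.k_values != k0):
            raise ParameterError("all curves must share the same k grid")
        if np.any(c.L_of_k <= 0):
            raise ParameterError("group_mean_curve requires positive L(k)")
        logs.append(np.log(c.L_of_k))
    mean_log = np.mean(logs, axis=0)
    return HFDCurve(
        k_values=k0.copy(),
        L_of_k=np.exp(mean_log),
        N=int(np.mean([c.N for c in curves])),
    )
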