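"""Variance-accounted-for (VAF) curves and the three classical criteria.

VAF is the uncentered coefficient of determination between the envelope
matrix M and its reconstruction R = W @ C, in percent:

    VAF = (1 - sum((M - R)**2) / sum(M**2)) * 100

The criteria operating on the VAF-vs-order curve:

* T-VAF: first order whose VAF exceeds a threshold (90% or 95%);
* E-VAF: the elbow, i.e. the interior point of largest perpendicular
  distance from the chord joining the curve's endpoints;
* P-VAF: the first order from which the remaining curve is flat, judged
  by the mean squared error of a straight-line fit (< 1e-2 on the
  percent scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateElbowError, NoSelectionError, UndefinedVafError

__all__ = ["VafCurve", "vaf", "tvaf", "evaf", "pvaf", "build_vaf_curve"]


@dataclass
class VafCurve:
    """VAF (percent) as a function of candidate order, one value per n."""

    n_values: np.ndarray
    vaf_percent: np.ndarray

    def __post_init__(self):
        self.n_values = np.asarray(self.n_values)
        self.vaf_percent = np.asarray(self.vaf_percent, dtype=float)
        if len(self.n_values) != len(self.vaf_percent):
            raise ValueError("n_values and vaf_percent lengths differ")


def vaf(M: np.ndarray, R: np.ndarray) -> float:
    """Uncentered variance accounted for, in percent."""
    M = np.asarray(M, dtype=float)
    R = np.asarray(R, dtype=float)
    if M.shape != R.shape:
        raise ValueError("M and R must have the same shape")
    denom = float((M * M).sum())
    if denom == 0.0:
        raise UndefinedVafError("VAF undefined for an all-zero matrix")
    return float((1.0 - ((M - R) ** 2).sum() / denom) * 100.0)


def build_vaf_curve(vaf_per_subgroup: dict[int, list[float]]) -> VafCurve:
    """Average the per-subgroup VAF values into one curve over orders."""
    ns = sorted(vaf_per_subgroup)
    vals = [float(np.mean(vaf_per_subgroup[n])) for n in ns]
    return VafCurve(n_values=np.array(ns), vaf_percent=np.array(vals))


def tvaf(curve: VafCurve, threshold_percent: float) -> int:
    """Smallest order whose VAF reaches the threshold."""
    if not 0.0 < threshold_percent < 100.0:
        raise ValueError("threshold must be in (0, 100)")
    ok = np.where(curve.vaf_percent >= threshold_percent)[0]
    if ok.size == 0:
        raise NoSelectionError(
            f"no order reaches VAF >= {threshold_percent}%")
    return int(curve.n_values[ok[0]])


def evaf(curve: VafCurve) -> int:
    """Elbow: interior order with maximum distance from the endpoint chord.

    Ties resolve to the smaller order; an exactly linear curve has no
    elbow and raises.
    """
    x = curve.n_values.astype(float)
    y = curve.vaf_percent
    if len(x) < 3:
        raise ValueError("elbow needs at least 3 points")
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    # perpendicular distance of interior points from the chord
    d = np.abs(dy * (x[1:-1] - x[0]) - dx * (y[1:-1] - y[0])) / norm
    if np.all(d < 1e-12):
        raise DegenerateElbowError("VAF curve is linear: no elbow")
    return int(curve.n_values[1:-1][int(np.argmax(d))])


def pvaf(curve: VafCurve, mse_threshold: float = 1e-2) -> int:
    """Plateau onset: first order whose tail admits a near-perfect line fit.

    For each candidate order n, an ordinary least-squares line is fitted
    through the points at orders >= n (at least 3 of them, on the percent
    scale); the first n with fit MSE below the threshold is selected.
    """
    x = curve.n_values.astype(float)
    y = curve.vaf_percent
    if len(x) < 3:
        raise ValueError("plateau detection needs at least 3 points")
    for start in range(len(x) - 2):
        xs, ys = x[start:], y[start:]
        coef = np.polyfit(xs, ys, 1)
        mse = float(np.mean((np.polyval(coef, xs) - ys) ** 2))
        if mse < mse_threshold:
            return int(curve.n_values[start])
    raise NoSelectionError(
        f"no plateau with line-fit MSE < {mse_threshold}")
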