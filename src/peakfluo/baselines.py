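"""Classical amplification-curve quantification points.

All estimators operate on a 4-parameter logistic fitted to the raw trace:

    F(c) = F_b + F_max / (1 + exp(-(c - c_half) / k))

- ``ct_threshold``: fractional cycle where the baseline-subtracted, 0-1
  scaled fitted curve crosses a preset fraction of the amplitude;
- ``ct_derivative``: cycle of the maximum first or second derivative of the
  fitted curve (for a pure logistic, c_half and c_half - k*ln(2 + sqrt(3)));
- ``cy0``: intersection of the inflection-point tangent with the cycle axis;
- ``f0_backproject``: the curve fitted up to a cutoff cycle, evaluated at
  cycle 0 (baseline-subtracted by default, so it is proportional to the
  starting template amount).

Derivative and tangent quantities are computed from the fitted model rather
than raw finite differences, which would amplify noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitConvergenceError
from .trace import FluorescenceTrace

__all__ = [
    "SigmoidFit",
    "CtEstimate",
    "fit_logistic",
    "ct_threshold",
    "ct_derivative",
    "cy0",
    "f0_backproject",
]

CtMethod = Literal["threshold", "d1max", "d2max", "cy0", "f0"]

DEFAULT_THRESHOLD_FRACTION = 0.1

#: offset (in units of k) of the second-derivative maximum below c_half
D2MAX_OFFSET = float(np.log(2.0 + np.sqrt(3.0)))


@dataclass(frozen=True)
class SigmoidFit:
    F_b: float
    F_max: float
    c_half: float
    k: float
    residual_norm: float

    def __call__(self, c):
        return self.F_b + self.F_max / (1.0 + np.exp(-(np.asarray(c, float) - self.c_half) / self.k))

    def amplitude_at(self, c):
        """Baseline-subtracted fitted curve."""
        return self.F_max / (1.0 + np.exp(-(np.asarray(c, float) - self.c_half) / self.k))

    def derivative_at(self, c):
        s = 1.0 / (1.0 + np.exp(-(np.asarray(c, float) - self.c_half) / self.k))
        return self.F_max * s * (1.0 - s) / self.k


@dataclass(frozen=True)
class CtEstimate:
    method: CtMethod
    value: float


def _logistic(c, F_b, F_max, c_half, k):
    return F_b + F_max / (1.0 + np.exp(-(c - c_half) / k))


def fit_logistic(
    trace: FluorescenceTrace,
    min_dynamic_range: float = 1e-9,
) -> SigmoidFit:
    """Bounded least-squares 4-parameter logistic fit.

    Initialization: baseline = min, amplitude = range, c_half = first
    half-range crossing, k = 2 cycles.
    """
    c = trace.cycles.astype(float)
    f = trace.fluorescence
    rng = float(f.max() - f.min())
    if rng <= min_dynamic_range * max(1.0, abs(float(f.max()))):
        raise FitConvergenceError(
            f"trace {trace.well_id!r} has no dynamic range to fit", residual=rng
        )
    half = f.min() + 0.5 * rng
    above = np.nonzero(f >= half)[0]
    c_half0 = float(c[above[0]]) if len(above) else float(c[len(c) // 2])
    p0 = [float(f.min()), rng, c_half0, 2.0]
    lo = [-np.inf, min_dynamic_range, c[0] - 5 * len(c), 1e-3]
    hi = [np.inf, np.inf, c[-1] + 5 * len(c), 10.0 * len(c)]
    try:
        popt, _ = curve_fit(_logistic, c, f, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"logistic fit failed for {trace.well_id!r}: {exc}"
        ) from exc
    resid = float(np.linalg.norm(f - _logistic(c, *popt)))
    if not np.isfinite(resid):
        raise FitConvergenceError(
            f"non-finite residual for {trace.well_id!r}", residual=resid
        )
    return SigmoidFit(float(popt[0]), float(popt[1]), float(popt[2]), float(popt[3]), resid)


def ct_threshold(
    trace: FluorescenceTrace,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    fit: SigmoidFit | None = None,
    grid_step: float = 1e-3,
) -> CtEstimate:
    """Crossing cycle of the scaled fitted curve through ``threshold_fraction``.

    The fitted curve is baseline-subtracted, scaled to [0, 1], sampled on a
    dense cycle grid and the crossing linearly interpolated.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    if fit is None:
        fit = fit_logistic(trace)
    grid = np.arange(trace.cycles[0], trace.cycles[-1] + grid_step, grid_step)
    scaled = fit.amplitude_at(grid) / fit.F_max
    above = np.nonzero(scaled >= threshold_fraction)[0]
    if len(above) == 0 or above[0] == 0:
        if len(above) and above[0] == 0:
            return CtEstimate("threshold", float(grid[0]))
        raise ValueError(
            f"scaled curve never crosses threshold {threshold_fraction} within the trace"
        )
    i = above[0]
    x0, x1 = grid[i - 1], grid[i]
    y0, y1 = scaled[i - 1], scaled[i]
    ct = x0 + (threshold_fraction - y0) / (y1 - y0) * (x1 - x0)
    return CtEstimate("threshold", float(ct))


def ct_derivative(
    trace: FluorescenceTrace,
    order: Literal[1, 2] = 1,
    fit: SigmoidFit | None = None,
    grid_step: float = 1e-3,
) -> CtEstimate:
    """Cycle of the maximum first or second derivative of the fitted curve."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if trace.n_cycles < 5:
        raise ValueError("trace too short for derivative analysis")
    if fit is None:
        fit = fit_logistic(trace)
    grid = np.arange(trace.cycles[0], trace.cycles[-1] + grid_step, grid_step)
    d1 = fit.derivative_at(grid)
    if order == 1:
        values = d1
    else:
        values = np.gradient(d1, grid)
    return CtEstimate("d1max" if order == 1 else "d2max", float(grid[int(np.argmax(values))]))


def cy0(trace: FluorescenceTrace, fit: SigmoidFit | None = None) -> CtEstimate:
    """Tangent construction: where the inflection-point tangent of the
    baseline-subtracted fitted curve meets the cycle axis.

    For the logistic this is ``c_half - 2k`` in closed form; the value is
    invariant to rescaling the fluorescence axis.
    """
    if fit is None:
        fit = fit_logistic(trace)
    slope = fit.derivative_at(fit.c_half)
    if slope <= 0 or not np.isfinite(slope):
        raise ValueError("zero or invalid derivative at the inflection point")
    value = fit.c_half - float(fit.amplitude_at(fit.c_half)) / float(slope)
    return CtEstimate("cy0", float(value))


def f0_backproject(
    trace: FluorescenceTrace,
    cutoff_cycle: int,
    include_baseline: bool = False,
    min_points: int = 5,
) -> CtEstimate:
    """Fit the logistic on cycles <= ``cutoff_cycle`` and evaluate at cycle 0.

    By default the baseline is subtracted so the value tracks the initial
    template amount; ``include_baseline=True`` reports the full fitted curve
    at cycle 0 instead.
    """
    mask = trace.cycles <= cutoff_cycle
    if int(mask.sum()) < min_points:
        raise ValueError(
            f"need >= {min_points} cycles before cutoff {cutoff_cycle}, "
            f"got {int(mask.sum())}"
        )
    truncated = FluorescenceTrace(
        trace.well_id, trace.cycles[mask], trace.fluorescence[mask]
    )
    full_range = float(trace.fluorescence.max() - trace.fluorescence.min())
    trunc_range = float(truncated.fluorescence.max() - truncated.fluorescence.min())
    if full_range > 0 and trunc_range < 0.05 * full_range:
        raise ValueError(
            f"cutoff {cutoff_cycle} precedes detectable amplification "
            f"(truncated range {trunc_range:.3g} vs full {full_range:.3g})"
        )
    fit = fit_logistic(truncated)
    value = float(fit.amplitude_at(0.0))
    if include_baseline:
        value += fit.F_b
    return CtEstimate("f0", value)
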