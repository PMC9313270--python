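"""Early-stopping peak quantification of control-subtracted qPCR traces.

Processing chain for one plate:

1. replicate wells are averaged on raw fluorescence;
2. a per-well background (default: mean of cycles 1-10) is subtracted;
3. the background-subtracted negative-control trace — the shared process
   component — is subtracted from every sample and standard;
4. the cleaned signal of each well is streamed cycle-by-cycle from the first
   processed cycle, tracking the running minimum; once a configurable number
   of consecutive cycles rise above the running minimum the well stops early
   and reports the absolute value of the minimum (the "peak");
5. the assay is rejected if any sample rose materially above the control
   before reaching its own minimum (earlier amplification than the control
   means free sequences interfered with the reaction);
6. peaks of standards with known concentration are regressed on
   log10(concentration); the fitted line is inverted to quantify unknowns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import FlatCurveError, InvalidDesignError, PeakFluoError, TraceMismatchError
from .trace import FluorescenceTrace, PlateLayout

logger = logging.getLogger(__name__)

BackgroundMode = Literal["mean", "max"]

DEFAULT_BACKGROUND_WINDOW: tuple[int, int] = (1, 10)
DEFAULT_START_CYCLE = 11
DEFAULT_PERSISTENCE = 3
DEFAULT_VALIDITY_TOLERANCE = 25.0


@dataclass(frozen=True)
class CleanedTrace:
    """Background- and control-subtracted signal from the first processed cycle."""

    well_id: str
    cycles: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cycles", np.asarray(self.cycles, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class PeakResult:
    """Outcome of the streaming minimum search for one well."""

    peak_magnitude: float
    peak_cycle: int
    stop_cycle: int
    found: bool


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line: mean peak vs log10(concentration in ng/mL)."""

    slope: float
    intercept: float
    r_squared: float | None
    fit_points: tuple[tuple[float, float], ...]  # (log10 conc, mean peak)


@dataclass(frozen=True)
class QuantResult:
    """Quantification of one sample group."""

    group: str
    estimated_concentration: float | None
    valid_assay: bool
    replicate_peaks: tuple[float, ...] = ()
    peak: PeakResult | None = None


@dataclass(frozen=True)
class PeakFluoParams:
    """Algorithm knobs.  Defaults follow the reference procedure: background
    from cycles 1-10, processing from cycle 11, three-cycle persistence."""

    background_window: tuple[int, int] = DEFAULT_BACKGROUND_WINDOW
    background_mode: BackgroundMode = "mean"
    start_cycle: int = DEFAULT_START_CYCLE
    persistence: int = DEFAULT_PERSISTENCE
    validity_tolerance: float = DEFAULT_VALIDITY_TOLERANCE
    quant_mode: Literal["log10", "two_point_raw"] = "log10"

    def __post_init__(self) -> None:
        lo, hi = self.background_window
        if lo < 1 or hi < lo:
            raise ValueError(f"bad background window {self.background_window}")
        if self.start_cycle <= hi:
            raise ValueError(
                f"start_cycle {self.start_cycle} must lie past the background "
                f"window end {hi}"
            )
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")


def estimate_background(
    trace: FluorescenceTrace,
    window: tuple[int, int] = DEFAULT_BACKGROUND_WINDOW,
    mode: BackgroundMode = "mean",
) -> float:
    """Per-well background over the early-cycle window (mean or max)."""
    lo, hi = window
    if lo < trace.cycles[0] or hi > trace.cycles[-1] or hi < lo:
        raise ValueError(
            f"window {window} outside trace cycles "
            f"[{trace.cycles[0]}, {trace.cycles[-1]}]"
        )
    mask = (trace.cycles >= lo) & (trace.cycles <= hi)
    vals = trace.fluorescence[mask]
    if mode == "mean":
        return float(np.mean(vals))
    if mode == "max":
        return float(np.max(vals))
    raise ValueError(f"unknown background mode {mode!r}")


def clean_trace(
    trace: FluorescenceTrace,
    control_trace: FluorescenceTrace,
    window: tuple[int, int] = DEFAULT_BACKGROUND_WINDOW,
    mode: BackgroundMode = "mean",
    start_cycle: int = DEFAULT_START_CYCLE,
) -> CleanedTrace:
    """``(f_n - bg_n) - (f_0 - bg_0)`` from ``start_cycle`` onward.

    The control cleaned against itself is identically zero.
    """
    trace.require_same_grid(control_trace)
    bg_n = estimate_background(trace, window, mode)
    bg_0 = estimate_background(control_trace, window, mode)
    mask = trace.cycles >= start_cycle
    if not mask.any():
        raise ValueError(f"start_cycle {start_cycle} is past the end of the trace")
    cleaned = (trace.fluorescence[mask] - bg_n) - (
        control_trace.fluorescence[mask] - bg_0
    )
    return CleanedTrace(trace.well_id, trace.cycles[mask], cleaned)


def find_peak(
    cleaned: CleanedTrace,
    persistence: int = DEFAULT_PERSISTENCE,
    start_cycle: int | None = None,
) -> PeakResult:
    """Streaming global-minimum search with early stopping.

    Cycles are consumed in order while maintaining the running minimum of the
    signed cleaned signal.  After ``persistence`` consecutive cycles strictly
    above the running minimum the search stops; ties neither improve the
    minimum nor count toward persistence.  If the trace ends first, the
    global minimum is still reported with ``found=False``.  The first
    occurrence wins on tied minima.
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    cycles, values = cleaned.cycles, cleaned.values
    if start_cycle is not None:
        mask = cycles >= start_cycle
        if not mask.any():
            raise ValueError(
                f"trace (last cycle {cycles[-1]}) shorter than start_cycle {start_cycle}"
            )
        cycles, values = cycles[mask], values[mask]
    best = values[0]
    best_cycle = int(cycles[0])
    streak = 0
    for c, v in zip(cycles[1:], values[1:]):
        if v < best:
            best = v
            best_cycle = int(c)
            streak = 0
        elif v > best:
            streak += 1
            if streak >= persistence:
                return PeakResult(abs(float(best)), best_cycle, int(c), True)
        else:  # exact tie with the running minimum: no progress either way
            streak = 0
    return PeakResult(abs(float(best)), best_cycle, int(cycles[-1]), False)


def brute_force_peak(cleaned: CleanedTrace) -> PeakResult:
    """Reference (non-streaming) result: argmin over the full cleaned trace."""
    idx = int(np.argmin(cleaned.values))
    return PeakResult(
        abs(float(cleaned.values[idx])),
        int(cleaned.cycles[idx]),
        int(cleaned.cycles[-1]),
        True,
    )


def average_replicates(traces: Sequence[FluorescenceTrace]) -> FluorescenceTrace:
    """Cycle-wise arithmetic mean of raw fluorescence across replicate wells."""
    if len(traces) == 0:
        raise ValueError("cannot average an empty replicate list")
    first = traces[0]
    for t in traces[1:]:
        first.require_same_grid(t)
    mean = np.mean([t.fluorescence for t in traces], axis=0)
    well_id = "+".join(t.well_id for t in traces)
    return FluorescenceTrace(well_id, first.cycles, mean)


def validate_assay(
    sample_cleaned: Iterable[CleanedTrace],
    tolerance: float = DEFAULT_VALIDITY_TOLERANCE,
) -> bool:
    """False (invalid) if any sample rose above the control by more than
    ``tolerance`` before reaching its own global minimum — the signature of a
    sample amplifying earlier than the negative control."""
    for ct in sample_cleaned:
        min_idx = int(np.argmin(ct.values))
        if min_idx > 0 and np.any(ct.values[:min_idx] > tolerance):
            logger.info(
                "well %s exceeded +%g before its minimum: assay invalid",
                ct.well_id,
                tolerance,
            )
            return False
    return True


def fit_standard_curve(
    standard_peaks: Sequence[tuple[float, float]],
) -> StandardCurve:
    """Least-squares fit of mean peak magnitude on log10(concentration).

    ``standard_peaks`` holds (concentration ng/mL, peak) pairs; replicate
    peaks for the same concentration are averaged before fitting.  With
    exactly two concentrations this reduces to the two-point slope.
    R-squared is reported only for three or more concentrations.
    """
    if len(standard_peaks) == 0:
        raise ValueError("no standard peaks to fit")
    by_conc: dict[float, list[float]] = {}
    for conc, peak in standard_peaks:
        if conc <= 0:
            raise ValueError(f"standard concentration must be positive, got {conc}")
        by_conc.setdefault(float(conc), []).append(float(peak))
    if len(by_conc) < 2:
        raise ValueError(
            f"need >= 2 distinct standard concentrations, got {len(by_conc)}"
        )
    concs = np.array(sorted(by_conc))
    peaks = np.array([np.mean(by_conc[c]) for c in concs])
    x = np.log10(concs)
    slope, intercept = np.polyfit(x, peaks, 1)
    if len(concs) >= 3:
        resid = peaks - (slope * x + intercept)
        ss_tot = float(np.sum((peaks - peaks.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    else:
        r2 = None
    return StandardCurve(
        float(slope),
        float(intercept),
        r2,
        tuple(zip(x.tolist(), peaks.tolist())),
    )


def quantify(
    sample_peak: float,
    curve: StandardCurve,
    min_abs_slope: float = 1e-9,
) -> float:
    """Invert the standard curve: ``10 ** ((peak - intercept) / slope)``.

    A sample whose peak equals a fitted point's mean peak returns that
    standard's concentration exactly (for a two-point curve).
    """
    if abs(curve.slope) < min_abs_slope:
        raise FlatCurveError(
            f"standard-curve slope {curve.slope:g} too flat for quantification"
        )
    with np.errstate(over="ignore"):
        return float(np.power(10.0, (sample_peak - curve.intercept) / curve.slope))


def quantify_two_point_raw(
    sample_peak: float,
    c1: tuple[float, float],
    c2: tuple[float, float],
    min_abs_slope: float = 1e-9,
) -> float:
    """Two-point inversion on the raw (unlogged) concentration axis, kept for
    strict emulation of the published pseudocode; ``c1``/``c2`` are
    (concentration, peak) pairs."""
    (conc1, peak1), (conc2, peak2) = c1, c2
    m = (peak1 - peak2) / (conc1 - conc2)
    if abs(m) < min_abs_slope:
        raise FlatCurveError("two-point slope too flat for quantification")
    return (sample_peak - peak2) / m + conc2


@dataclass(frozen=True)
class PlateResult:
    """Full-pipeline output for one plate."""

    curve: StandardCurve
    samples: dict[str, QuantResult]
    standards: dict[str, QuantResult]
    control_peak: PeakResult
    valid_assay: bool
    stop_cycles: dict[str, int] = field(default_factory=dict)


def run_peakfluo(
    traces: Sequence[FluorescenceTrace],
    layout: PlateLayout,
    params: PeakFluoParams = PeakFluoParams(),
) -> PlateResult:
    """Average replicates, clean, stream peaks, gate validity, fit the
    standard curve and quantify every unknown group.

    When the validity gate fails, concentrations are withheld
    (``estimated_concentration=None``) but peaks are still reported.
    """
    by_id = {t.well_id: t for t in traces}
    missing = [w.well_id for w in layout.wells if w.well_id not in by_id]
    if missing:
        raise InvalidDesignError(f"layout wells missing from plate: {missing}")
    if not layout.has_control:
        raise InvalidDesignError("layout has no control group")

    def group_mean(group: str) -> FluorescenceTrace:
        return average_replicates([by_id[w.well_id] for w in layout.wells_in(group)])

    control_mean = group_mean(layout.control_group)

    clean_kw = dict(
        window=params.background_window,
        mode=params.background_mode,
        start_cycle=params.start_cycle,
    )
    control_cleaned = clean_trace(control_mean, control_mean, **clean_kw)
    control_peak = find_peak(control_cleaned, params.persistence)

    cleaned: dict[str, CleanedTrace] = {}
    peaks: dict[str, PeakResult] = {}
    rep_peaks: dict[str, tuple[float, ...]] = {}
    stop_cycles: dict[str, int] = {}
    noncontrol = [
        g for g in layout.groups() if g != layout.control_group
    ]
    for group in noncontrol:
        ct = clean_trace(group_mean(group), control_mean, **clean_kw)
        pk = find_peak(ct, params.persistence)
        cleaned[group] = ct
        peaks[group] = pk
        stop_cycles[group] = pk.stop_cycle
        logger.info("group %s stopped at cycle %d", group, pk.stop_cycle)
        reps = []
        for w in layout.wells_in(group):
            rct = clean_trace(by_id[w.well_id], control_mean, **clean_kw)
            reps.append(find_peak(rct, params.persistence).peak_magnitude)
        rep_peaks[group] = tuple(reps)

    valid = validate_assay(cleaned.values(), params.validity_tolerance)

    standard_pairs = []
    for group in noncontrol:
        spec_wells = layout.wells_in(group)
        if spec_wells[0].role == "standard":
            standard_pairs.append(
                (layout.group_concentration(group), peaks[group].peak_magnitude)
            )
    curve = fit_standard_curve(standard_pairs)

    standards: dict[str, QuantResult] = {}
    samples: dict[str, QuantResult] = {}
    for group in noncontrol:
        role = layout.wells_in(group)[0].role
        pk = peaks[group]
        if valid:
            if params.quant_mode == "two_point_raw":
                pts = sorted(standard_pairs)
                est = quantify_two_point_raw(pk.peak_magnitude, pts[0], pts[-1])
            else:
                est = quantify(pk.peak_magnitude, curve)
        else:
            est = None
        result = QuantResult(group, est, valid, rep_peaks[group], pk)
        (standards if role == "standard" else samples)[group] = result
    return PlateResult(curve, samples, standards, control_peak, valid, stop_cycles)
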