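"""End-to-end runs: optional simulation, quantification by any method,
method comparison, structured result reports."""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, ampsim, baselines, core, io
from .errors import PeakFluoError
from .trace import FluorescenceTrace, PlateLayout

logger = logging.getLogger(__name__)

Method = Literal["peakfluo", "ct", "d1", "d2", "cy0", "f0"]

BASELINE_METHODS: tuple[str, ...] = ("ct", "d1", "d2", "cy0", "f0")


class AlgorithmConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    background_window: tuple[int, int] = core.DEFAULT_BACKGROUND_WINDOW
    background_mode: Literal["mean", "max"] = "mean"
    start_cycle: int = core.DEFAULT_START_CYCLE
    persistence: int = Field(default=core.DEFAULT_PERSISTENCE, ge=1)
    validity_tolerance: float = core.DEFAULT_VALIDITY_TOLERANCE
    quant_mode: Literal["log10", "two_point_raw"] = "log10"
    threshold_fraction: float = Field(
        default=baselines.DEFAULT_THRESHOLD_FRACTION, gt=0.0, lt=1.0
    )
    cutoff_cycle: Optional[int] = None

    def to_params(self) -> core.PeakFluoParams:
        return core.PeakFluoParams(
            background_window=tuple(self.background_window),
            background_mode=self.background_mode,
            start_cycle=self.start_cycle,
            persistence=self.persistence,
            validity_tolerance=self.validity_tolerance,
            quant_mode=self.quant_mode,
        )


class RunConfig(BaseModel):
    """Everything needed for one reproducible run.  Unknown keys rejected;
    round-trips losslessly through JSON."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    method: Method = "peakfluo"
    plate: Optional[str] = None  # path to an existing plate CSV
    layout: str
    simulate: Optional[ampsim.SimConfig] = None
    algorithm: AlgorithmConfig = AlgorithmConfig()
    out: Optional[str] = None


def _curve_dict(curve: core.StandardCurve) -> dict:
    return {
        "slope": curve.slope,
        "intercept": curve.intercept,
        "r_squared": curve.r_squared,
        "fit_points": [list(p) for p in curve.fit_points],
    }


def run_peakfluo_report(
    traces: Sequence[FluorescenceTrace],
    layout: PlateLayout,
    params: core.PeakFluoParams,
) -> dict:
    result = core.run_peakfluo(traces, layout, params)
    groups = {}
    for coll in (result.standards, result.samples):
        for name, q in coll.items():
            groups[name] = {
                "role": "standard" if name in result.standards else "unknown",
                "peak_magnitude": q.peak.peak_magnitude,
                "peak_cycle": q.peak.peak_cycle,
                "stop_cycle": q.peak.stop_cycle,
                "found": q.peak.found,
                "replicate_peaks": list(q.replicate_peaks),
                "estimated_concentration": q.estimated_concentration,
            }
    return {
        "method": "peakfluo",
        "valid_assay": result.valid_assay,
        "standard_curve": _curve_dict(result.curve),
        "control_peak_magnitude": result.control_peak.peak_magnitude,
        "stop_cycles": dict(result.stop_cycles),
        "groups": groups,
    }


def _group_value(
    trace: FluorescenceTrace, method: str, algo: AlgorithmConfig
) -> float:
    if method == "ct":
        return baselines.ct_threshold(trace, algo.threshold_fraction).value
    if method == "d1":
        return baselines.ct_derivative(trace, 1).value
    if method == "d2":
        return baselines.ct_derivative(trace, 2).value
    if method == "cy0":
        return baselines.cy0(trace).value
    if method == "f0":
        cutoff = algo.cutoff_cycle or trace.n_cycles
        return baselines.f0_backproject(trace, cutoff).value
    raise ValueError(f"unknown method {method!r}")


def run_baseline_report(
    traces: Sequence[FluorescenceTrace],
    layout: PlateLayout,
    method: str,
    algo: AlgorithmConfig,
) -> dict:
    """Quantify a plate with one of the classical estimators: the per-group
    value is regressed on log10(concentration) for the standards and the
    fitted line inverted for unknowns."""
    by_id = {t.well_id: t for t in traces}
    values: dict[str, float] = {}
    roles: dict[str, str] = {}
    for group, wells in layout.groups().items():
        if wells[0].role == "control":
            continue
        mean = core.average_replicates([by_id[w.well_id] for w in wells])
        values[group] = _group_value(mean, method, algo)
        roles[group] = wells[0].role
    pairs = [
        (layout.group_concentration(g), values[g])
        for g in values
        if roles[g] == "standard"
    ]
    curve = core.fit_standard_curve(pairs)
    groups = {}
    for g, val in values.items():
        est = core.quantify(val, curve)
        groups[g] = {
            "role": roles[g],
            "value": val,
            "estimated_concentration": est,
        }
    return {
        "method": method,
        "valid_assay": True,
        "standard_curve": _curve_dict(curve),
        "groups": groups,
    }


def compare_methods(
    traces: Sequence[FluorescenceTrace],
    layout: PlateLayout,
    methods: Sequence[str] = ("peakfluo", "ct"),
    algo: AlgorithmConfig = AlgorithmConfig(),
) -> dict:
    """Standard-curve linearity (R^2) of several methods on the same plate."""
    out: dict[str, dict] = {}
    for method in methods:
        if method == "peakfluo":
            report = run_peakfluo_report(traces, layout, algo.to_params())
        else:
            report = run_baseline_report(traces, layout, method, algo)
        out[method] = {
            "r_squared": report["standard_curve"]["r_squared"],
            "standard_curve": report["standard_curve"],
        }
    return out


def format_r2_table(per_plate: dict[str, dict[str, dict]]) -> str:
    """Render {plate: {method: {'r_squared': ...}}} as a fixed-width table
    with one row per method and one column per plate."""
    plates = list(per_plate)
    methods: list[str] = []
    for results in per_plate.values():
        for m in results:
            if m not in methods:
                methods.append(m)
    width = max(12, *(len(p) + 2 for p in plates))
    head = "Method".ljust(12) + "".join(p.rjust(width) for p in plates)
    lines = [head]
    for m in methods:
        cells = []
        for p in plates:
            r2 = per_plate[p].get(m, {}).get("r_squared")
            cells.append(("-" if r2 is None else f"{r2:.3f}").rjust(width))
        lines.append(m.ljust(12) + "".join(cells))
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate (optional) -> quantify -> report.  Deterministic per seed."""
    t0 = time.perf_counter()
    layout = io.read_layout(config.layout)
    if config.simulate is not None:
        traces = ampsim.simulate_plate(layout, config.simulate, seed=config.seed)
        if config.plate:
            io.write_plate(traces, config.plate)
    elif config.plate:
        traces = io.read_plate(config.plate)
    else:
        raise PeakFluoError("config needs either a plate path or a simulate section")
    logger.info("loaded %d traces in %.3fs", len(traces), time.perf_counter() - t0)

    t1 = time.perf_counter()
    try:
        if config.method == "peakfluo":
            report = run_peakfluo_report(traces, layout, config.algorithm.to_params())
        else:
            report = run_baseline_report(
                traces, layout, config.method, config.algorithm
            )
    except PeakFluoError as exc:
        raise PeakFluoError(f"quantification stage failed: {exc}") from exc
    logger.info("quantified in %.3fs", time.perf_counter() - t1)

    report["version"] = __version__
    report["seed"] = config.seed
    # hash the semantic parameters only, not the file locations
    report["config_hash"] = io.config_hash(
        config.model_dump(mode="json", exclude={"plate", "layout", "out"})
    )
    if config.out:
        io.write_results(report, config.out)
    return report
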