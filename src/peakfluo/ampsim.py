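"""Synthetic qPCR plate generator.

Produces amplification curves with the canonical four-phase shape —
background, exponential growth, linear slowdown, plateau — modelled as a
4-parameter logistic in cycle number.  The logistic slope is tied by default
to the reaction efficiency ``E`` so that the early (exponential) tail of the
curve grows by a factor of ``1 + E`` per cycle, matching the growth law
``y_n = y_0 * (1 + E)**n`` for template copies.

Concentration enters through a hyperbolic displacement map: higher analyte
concentration displaces more aptamer-adaptor complexes, leaving fewer
template copies and hence a *later* amplification onset.  The 0 ng/mL
control therefore amplifies earliest.

Noise has two components: a per-plate random-walk "process" term shared by
every well (removed downstream by negative-control subtraction) and i.i.d.
per-well Gaussian read noise.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import InvalidDesignError
from .trace import FluorescenceTrace, PlateLayout

__all__ = [
    "SimConfig",
    "concentration_to_y0",
    "onset_cycle",
    "simulate_trace",
    "simulate_plate",
    "quantification_tuned_config",
]


class SimConfig(BaseModel):
    """All simulator parameters.  Serializes losslessly to/from JSON."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_cycles: int = Field(default=40, ge=5)
    baseline_level: float = 100.0
    baseline_drift: float = 0.05
    plateau_level: float = 1000.0
    efficiency_E: float = Field(default=0.9, gt=0.0, le=1.0)
    detection_threshold_copies: float = Field(default=1e7, gt=0.0)
    y0_control: float = Field(default=1e4, ge=1.0)
    displacement_Kd: float = Field(default=0.2, gt=0.0)
    noise_sd_well: float = Field(default=5.0, ge=0.0)
    noise_sd_process: float = Field(default=2.0, ge=0.0)
    #: logistic slope in cycles; None ties it to 1/ln(1+E) so the curve's
    #: exponential tail multiplies by (1+E) each cycle
    slope_cycles: Optional[float] = Field(default=None, gt=0.0)
    #: half-rise cycle = onset + onset_to_half_slopes * slope; controls how
    #: far past detectability the curve reaches half amplitude
    onset_to_half_slopes: float = Field(default=5.0, gt=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_levels(self) -> "SimConfig":
        if not self.plateau_level > self.baseline_level:
            raise ValueError("plateau_level must exceed baseline_level")
        return self

    @property
    def slope_k(self) -> float:
        """Effective logistic slope (cycles per e-fold of the early tail)."""
        if self.slope_cycles is not None:
            return self.slope_cycles
        return 1.0 / math.log1p(self.efficiency_E)

    @property
    def amplitude(self) -> float:
        return self.plateau_level - self.baseline_level


def quantification_tuned_config(**overrides) -> SimConfig:
    """A configuration tuned for calibration studies.

    With the slope tied to the efficiency, the depth of the control-subtracted
    dip saturates (it is a bounded difference of two logistics), which bends
    the peak-vs-log10(concentration) relationship.  A gentler slope and a
    smaller half-displacement constant keep the dip depth in its linear
    regime across the 0.1-10 ng/mL panel, at the cost of a longer run.
    """
    params = dict(
        n_cycles=80,
        displacement_Kd=0.02,
        slope_cycles=3.5 / math.log1p(0.9),
        efficiency_E=0.9,
    )
    params.update(overrides)
    return SimConfig(**params)


def concentration_to_y0(conc: float, cfg: SimConfig) -> float:
    """Initial template copies left after displacement by ``conc`` ng/mL.

    Hyperbolic (Langmuir-like) map: ``y0_control / (1 + conc/Kd)``, floored
    at one copy.  Zero concentration (the negative control) displaces
    nothing and returns ``y0_control``.
    """
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    return max(1.0, cfg.y0_control / (1.0 + conc / cfg.displacement_Kd))


def onset_cycle(y0: float, cfg: SimConfig) -> float:
    """Real-valued cycle at which ``y0`` copies growing by (1+E) per cycle
    reach the detection threshold."""
    if y0 < 1:
        raise ValueError(f"y0 must be >= 1, got {y0}")
    if cfg.detection_threshold_copies <= y0:
        warnings.warn(
            f"template already detectable (y0={y0:g} >= threshold "
            f"{cfg.detection_threshold_copies:g}); onset set to 0",
            stacklevel=2,
        )
        return 0.0
    return math.log(cfg.detection_threshold_copies / y0) / math.log1p(cfg.efficiency_E)


def _noiseless_curve(conc: float, cfg: SimConfig) -> np.ndarray:
    k = cfg.slope_k
    y0 = concentration_to_y0(conc, cfg)
    half_rise = onset_cycle(y0, cfg) + cfg.onset_to_half_slopes * k
    c = np.arange(1, cfg.n_cycles + 1, dtype=float)
    sigmoid = 1.0 / (1.0 + np.exp(-(c - half_rise) / k))
    return cfg.baseline_level + cfg.baseline_drift * c + cfg.amplitude * sigmoid


def simulate_trace(
    conc: float,
    cfg: SimConfig,
    process_noise: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    well_id: str = "well",
) -> FluorescenceTrace:
    """Simulate one well at ``conc`` ng/mL.

    ``process_noise`` is the plate-wide shared component (length
    ``n_cycles``); per-well Gaussian read noise is drawn from ``rng``.
    Both default to zero / a config-seeded generator.
    """
    f = _noiseless_curve(conc, cfg)
    if process_noise is not None:
        process_noise = np.asarray(process_noise, dtype=float)
        if len(process_noise) != cfg.n_cycles:
            raise ValueError("process_noise length must equal n_cycles")
        f = f + process_noise
    if cfg.noise_sd_well > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        f = f + rng.normal(0.0, cfg.noise_sd_well, size=cfg.n_cycles)
    return FluorescenceTrace(well_id, np.arange(1, cfg.n_cycles + 1), f)


def process_noise_walk(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Shared-across-wells process component: a Gaussian random walk."""
    if cfg.noise_sd_process == 0:
        return np.zeros(cfg.n_cycles)
    return np.cumsum(rng.normal(0.0, cfg.noise_sd_process, size=cfg.n_cycles))


def simulate_plate(
    design: PlateLayout,
    cfg: SimConfig,
    seed: int | None = None,
) -> list[FluorescenceTrace]:
    """Simulate every well of ``design`` under one shared process-noise
    realization.  Deterministic for a fixed (design, cfg, seed).

    Every well needs a true concentration; the design must include a
    control group (the quantification algorithm requires its trace).
    """
    if not design.has_control:
        raise InvalidDesignError("plate design must include a control group")
    for w in design.wells:
        if w.concentration is None:
            raise InvalidDesignError(
                f"well {w.well_id!r} has no concentration to simulate"
            )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    shared = process_noise_walk(cfg, rng)
    traces = []
    for w in design.wells:
        traces.append(
            simulate_trace(w.concentration, cfg, shared, rng, well_id=w.well_id)
        )
    return traces
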