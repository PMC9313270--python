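"""Labeled curve-image datasets for the high/low classifier."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .. import ampsim
from ..trace import FluorescenceTrace, PlateLayout
from .images import AxesSpec, render_curve_image

logger = logging.getLogger(__name__)

#: clinically motivated decision boundary, ng/mL
DEFAULT_THRESHOLD = 5.0


@dataclass(frozen=True)
class CurveDataset:
    images: np.ndarray  # (n, height, width) float32 in [0, 1]
    labels: np.ndarray  # (n,) int8; 1 = high, 0 = low
    concentrations: np.ndarray  # (n,) float
    well_ids: tuple[str, ...]
    axes: AxesSpec

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_high(self) -> int:
        return int(self.labels.sum())

    @property
    def n_low(self) -> int:
        return int(len(self.labels) - self.labels.sum())


def label_concentration(conc: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """'high' iff strictly above the threshold; exact ties go to 'low'."""
    if conc == threshold:
        logger.info("concentration exactly at threshold %g labeled 'low'", threshold)
    return "high" if conc > threshold else "low"


def build_dataset(
    curves: Sequence[tuple[FluorescenceTrace, float]],
    axes: AxesSpec,
    threshold: float = DEFAULT_THRESHOLD,
) -> CurveDataset:
    """Render (trace, true concentration) pairs into a labeled image dataset."""
    images, labels, concs, ids = [], [], [], []
    for trace, conc in curves:
        lbl = label_concentration(conc, threshold)
        img = render_curve_image(trace, axes, label=lbl, concentration=conc)
        images.append(img.pixels)
        labels.append(1 if lbl == "high" else 0)
        concs.append(conc)
        ids.append(trace.well_id)
    n = len(images)
    shape = (n, axes.height, axes.width) if n else (0, axes.height, axes.width)
    return CurveDataset(
        np.asarray(images, dtype=np.float32).reshape(shape),
        np.asarray(labels, dtype=np.int8),
        np.asarray(concs, dtype=float),
        tuple(ids),
        axes,
    )


def dataset_from_plates(
    plates: Sequence[tuple[Sequence[FluorescenceTrace], PlateLayout]],
    axes: AxesSpec,
    threshold: float = DEFAULT_THRESHOLD,
    include_controls: bool = False,
) -> CurveDataset:
    """Collect labeled curves from (traces, layout) pairs; every included
    well must carry a true concentration in the layout."""
    curves: list[tuple[FluorescenceTrace, float]] = []
    for traces, layout in plates:
        by_id = {t.well_id: t for t in traces}
        for w in layout.wells:
            if w.role == "control" and not include_controls:
                continue
            if w.concentration is None:
                raise ValueError(
                    f"well {w.well_id!r} has unknown concentration; cannot label"
                )
            curves.append((by_id[w.well_id], w.concentration))
    return build_dataset(curves, axes, threshold)


def default_axes(cfg: ampsim.SimConfig, size: int = 32) -> AxesSpec:
    """Axes window covering simulated traces with noise headroom."""
    margin = 6.0 * (cfg.noise_sd_well + cfg.noise_sd_process * np.sqrt(cfg.n_cycles))
    return AxesSpec(
        cycle_range=(1.0, float(cfg.n_cycles)),
        fluorescence_range=(
            cfg.baseline_level - margin,
            cfg.plateau_level + abs(cfg.baseline_drift) * cfg.n_cycles + margin,
        ),
        width=size,
        height=size,
    )


def generate_reference_dataset(
    n_high: int = 201,
    n_low: int = 77,
    cfg: ampsim.SimConfig | None = None,
    seed: int = 0,
    axes: AxesSpec | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    high_concs: Sequence[float] = (10.0,),
    low_concs: Sequence[float] = (0.1, 1.0),
) -> CurveDataset:
    """Simulate a dataset with a chosen class composition.

    Default composition is 201 high-concentration curves (10 ng/mL) and 77
    low-concentration curves (0.1 and 1 ng/mL, split evenly), matching the
    0.1 / 1 / 10 ng/mL standards panel around a 5 ng/mL boundary.  Curves are
    generated in mini-batches that share a process-noise realization, like
    wells of a physical plate.
    """
    cfg = cfg if cfg is not None else ampsim.SimConfig()
    axes = axes if axes is not None else default_axes(cfg)
    rng = np.random.default_rng(seed)
    concs = [high_concs[i % len(high_concs)] for i in range(n_high)]
    concs += [low_concs[i % len(low_concs)] for i in range(n_low)]
    curves: list[tuple[FluorescenceTrace, float]] = []
    batch = 12  # wells per simulated plate
    shared = ampsim.process_noise_walk(cfg, rng)
    for i, conc in enumerate(concs):
        if i and i % batch == 0:
            shared = ampsim.process_noise_walk(cfg, rng)
        trace = ampsim.simulate_trace(conc, cfg, shared, rng, well_id=f"w{i:04d}")
        curves.append((trace, conc))
    return build_dataset(curves, axes, threshold)
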