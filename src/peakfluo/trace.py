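"""Core data containers: fluorescence traces and plate layouts."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .errors import InvalidDesignError, TraceMismatchError

Role = Literal["control", "standard", "unknown"]

ROLES: tuple[Role, ...] = ("control", "standard", "unknown")


@dataclass(frozen=True)
class FluorescenceTrace:
    """One well's cycle-indexed fluorescence series.

    Cycles are 1-based, strictly increasing and contiguous; fluorescence is
    finite and the same length as ``cycles``.
    """

    well_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        cycles = np.asarray(self.cycles, dtype=int)
        fluo = np.asarray(self.fluorescence, dtype=float)
        if cycles.ndim != 1 or fluo.ndim != 1 or len(cycles) != len(fluo):
            raise ValueError("cycles and fluorescence must be 1-D and equal length")
        if len(cycles) == 0:
            raise ValueError("empty trace")
        if not np.all(np.diff(cycles) == 1):
            raise ValueError("cycles must be contiguous and strictly increasing")
        if not np.all(np.isfinite(fluo)):
            raise ValueError(f"non-finite fluorescence in well {self.well_id!r}")
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "fluorescence", fluo)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def same_grid(self, other: "FluorescenceTrace") -> bool:
        return self.n_cycles == other.n_cycles and bool(
            np.all(self.cycles == other.cycles)
        )

    def require_same_grid(self, other: "FluorescenceTrace") -> None:
        if not self.same_grid(other):
            raise TraceMismatchError(
                f"wells {self.well_id!r} and {other.well_id!r} have different cycle grids"
            )


@dataclass(frozen=True)
class WellSpec:
    """Role assignment for one well.

    ``concentration`` is the true concentration in ng/mL.  It is required to
    simulate a well (controls use 0.0) but may be ``None`` for unknowns when a
    layout is read back from disk for quantification.
    """

    well_id: str
    role: Role
    concentration: float | None
    replicate_group: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InvalidDesignError(f"unknown role {self.role!r}")
        if self.role == "control" and self.concentration not in (None, 0.0):
            raise InvalidDesignError("control wells must have concentration 0")
        if self.role == "standard":
            if self.concentration is None or self.concentration <= 0:
                raise InvalidDesignError(
                    f"standard well {self.well_id!r} needs a positive concentration"
                )


@dataclass(frozen=True)
class PlateLayout:
    """Maps wells to roles and replicate groups.

    Doubles as the simulation design when all wells (including unknowns)
    carry a true concentration.
    """

    wells: tuple[WellSpec, ...]

    def __post_init__(self) -> None:
        wells = tuple(self.wells)
        ids = [w.well_id for w in wells]
        if len(set(ids)) != len(ids):
            raise InvalidDesignError("duplicate well ids in layout")
        control_groups = {w.replicate_group for w in wells if w.role == "control"}
        if len(control_groups) > 1:
            raise InvalidDesignError("more than one control replicate group")
        std_concs = [
            w.concentration for w in wells if w.role == "standard"
        ]
        by_group: dict[str, set[float]] = {}
        for w in wells:
            if w.role == "standard":
                by_group.setdefault(w.replicate_group, set()).add(w.concentration)
        for group, concs in by_group.items():
            if len(concs) > 1:
                raise InvalidDesignError(
                    f"standard group {group!r} mixes concentrations {sorted(concs)}"
                )
        seen: dict[float, str] = {}
        for group, concs in by_group.items():
            (conc,) = concs
            if conc in seen and seen[conc] != group:
                raise InvalidDesignError(
                    f"standard concentration {conc} assigned to two groups"
                )
            seen[conc] = group
        del std_concs
        object.__setattr__(self, "wells", wells)

    @property
    def control_group(self) -> str:
        for w in self.wells:
            if w.role == "control":
                return w.replicate_group
        raise InvalidDesignError("layout has no control group")

    @property
    def has_control(self) -> bool:
        return any(w.role == "control" for w in self.wells)

    def groups(self, role: Role | None = None) -> dict[str, list[WellSpec]]:
        out: dict[str, list[WellSpec]] = {}
        for w in self.wells:
            if role is None or w.role == role:
                out.setdefault(w.replicate_group, []).append(w)
        return out

    def group_concentration(self, group: str) -> float | None:
        concs = {w.concentration for w in self.wells if w.replicate_group == group}
        if len(concs) != 1:
            raise InvalidDesignError(f"group {group!r} has mixed concentrations")
        return concs.pop()

    def wells_in(self, group: str) -> list[WellSpec]:
        return [w for w in self.wells if w.replicate_group == group]


def triplicate_panel(
    concentrations: Iterable[float] = (0.1, 1.0, 10.0),
    unknowns: Iterable[float] = (),
    replicates: int = 3,
) -> PlateLayout:
    """Build the standard calibration panel: a 0 ng/mL control plus standards,
    each in ``replicates`` wells, optionally followed by unknown samples whose
    true concentration is retained for simulation."""
    wells: list[WellSpec] = []
    for r in range(replicates):
        wells.append(WellSpec(f"NC{r + 1}", "control", 0.0, "control"))
    for i, conc in enumerate(concentrations, start=1):
        for r in range(replicates):
            wells.append(WellSpec(f"S{i}_{r + 1}", "standard", float(conc), f"std{i}"))
    for i, conc in enumerate(unknowns, start=1):
        for r in range(replicates):
            wells.append(WellSpec(f"U{i}_{r + 1}", "unknown", float(conc), f"unk{i}"))
    return PlateLayout(tuple(wells))
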