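"""Ground-truth domain types for the synthetic field and plate generator."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

NUCLEUS_CLASSES = ("healthy", "pyknosed", "fragmented")
PYKNOSED_SUBCLASSES = ("mitotic", "apoptotic", "n/a")
VIABILITY_CLASSES = ("healthy", "early_apoptotic", "late_apoptotic", "necrotic", "lysed")
FUCCI_STATES = ("red", "green", "yellow", "unlabeled", "n/a")
MODES = ("viability", "multiplex", "fucci")
KINETIC_CLASSES = ("rapid", "intermediate", "slow")
CELL_CYCLE_ACTIONS = ("none", "g1_arrest", "s_arrest", "g2m_arrest")
ROLES = ("treatment", "dmso_control", "untreated", "reference_compound")


class TruthError(ValueError):
    """Invalid ground-truth construction."""


@dataclass
class CellTruth:
    """Ground truth for one simulated cell.

    Phenotype booleans (``tubulin_effect``, ``mito_mass_increased``,
    ``membrane_permeable``) are defined only for cells with a healthy
    nucleus — downstream phenotype gates only ever see healthy-nucleus
    cells — and are ``None`` otherwise. ``fucci_state`` is ``"n/a"``
    outside FUCCI-mode simulations.
    """

    cell_id: int
    center: tuple[float, float]  # (x, y) pixels
    nucleus_class: str = "healthy"
    pyknosed_subclass: str = "n/a"
    viability_class: str = "healthy"
    fucci_state: str = "n/a"
    tubulin_effect: bool | None = None
    mito_mass_increased: bool | None = None
    membrane_permeable: bool | None = None

    def __post_init__(self) -> None:
        if self.nucleus_class not in NUCLEUS_CLASSES:
            raise TruthError(f"bad nucleus_class {self.nucleus_class!r}")
        if self.pyknosed_subclass not in PYKNOSED_SUBCLASSES:
            raise TruthError(f"bad pyknosed_subclass {self.pyknosed_subclass!r}")
        if self.viability_class not in VIABILITY_CLASSES:
            raise TruthError(f"bad viability_class {self.viability_class!r}")
        if self.fucci_state not in FUCCI_STATES:
            raise TruthError(f"bad fucci_state {self.fucci_state!r}")
        if (self.pyknosed_subclass != "n/a") != (self.nucleus_class == "pyknosed"):
            raise TruthError(
                "pyknosed_subclass must be set exactly when nucleus_class='pyknosed'"
            )
        booleans = (self.tubulin_effect, self.mito_mass_increased, self.membrane_permeable)
        if self.nucleus_class != "healthy" and any(b is not None for b in booleans):
            raise TruthError(
                "phenotype booleans are defined only for healthy-nucleus cells"
            )


@dataclass
class ArtifactTruth:
    """A non-cellular bright object: compound precipitate or auto-fluorescence.

    ``footprint`` is a boolean mask over the field; ``intensity_scale``
    multiplies the median nuclear intensity (> 1 by construction).
    """

    kind: str  # "precipitate" | "autofluorescence"
    footprint: np.ndarray
    intensity_scale: float

    def __post_init__(self) -> None:
        if self.kind not in ("precipitate", "autofluorescence"):
            raise TruthError(f"bad artifact kind {self.kind!r}")
        if self.intensity_scale <= 1:
            raise TruthError("artifact intensity_scale must be > 1")
        self.footprint = np.asarray(self.footprint, dtype=bool)


# default per-class hazard scale and potency halving time (hours); the
# ordering rapid < intermediate < slow in halving time is an invariant
KINETIC_DEFAULTS = {
    "rapid": {"halving_time": 10.0, "max_exit_rate": 0.35},
    "intermediate": {"halving_time": 24.0, "max_exit_rate": 0.15},
    "slow": {"halving_time": 48.0, "max_exit_rate": 0.05},
}


@dataclass
class CompoundKineticsSpec:
    """Dose- and time-dependent death kinetics of one compound."""

    ic50_at_reference_time: float  # µM
    hill_slope: float = 1.5
    kinetic_class: str = "intermediate"
    potency_halving_time: float | None = None  # hours; default from class
    terminal_state_bias: Mapping[str, float] = field(
        default_factory=lambda: {"apoptotic": 0.6, "necrotic": 0.25, "lysed": 0.15}
    )
    cell_cycle_action: str = "none"
    max_exit_rate: float | None = None  # per-hour hazard at saturating dose

    def __post_init__(self) -> None:
        if self.ic50_at_reference_time <= 0:
            raise TruthError("ic50 must be > 0")
        if self.hill_slope <= 0:
            raise TruthError("hill_slope must be > 0")
        if self.kinetic_class not in KINETIC_CLASSES:
            raise TruthError(f"bad kinetic_class {self.kinetic_class!r}")
        if self.cell_cycle_action not in CELL_CYCLE_ACTIONS:
            raise TruthError(f"bad cell_cycle_action {self.cell_cycle_action!r}")
        defaults = KINETIC_DEFAULTS[self.kinetic_class]
        if self.potency_halving_time is None:
            self.potency_halving_time = defaults["halving_time"]
        if self.max_exit_rate is None:
            self.max_exit_rate = defaults["max_exit_rate"]
        if self.potency_halving_time <= 0:
            raise TruthError("potency_halving_time must be > 0")
        total = sum(self.terminal_state_bias.values())
        if not np.isclose(total, 1.0):
            raise TruthError("terminal_state_bias must sum to 1")
        bad = set(self.terminal_state_bias) - {"apoptotic", "necrotic", "lysed"}
        if bad:
            raise TruthError(f"unknown terminal routes {bad}")

    def ic50_at(self, t_hours: float, reference_time: float = 0.0) -> float:
        """Effective IC50 at time ``t``: potency doubles (midpoint halves)
        every ``potency_halving_time`` hours after the reference time."""
        return self.ic50_at_reference_time * 2.0 ** (
            -(t_hours - reference_time) / self.potency_halving_time
        )

    def exit_hazard(self, concentration: float, t_hours: float) -> float:
        """Per-hour hazard of leaving the healthy compartment."""
        if concentration <= 0:
            return 0.0
        ic50 = self.ic50_at(t_hours)
        cn = concentration**self.hill_slope
        return self.max_exit_rate * cn / (cn + ic50**self.hill_slope)


@dataclass
class WellAssignment:
    compound: str | None  # None for controls
    concentration: float  # µM; 0 for controls
    role: str = "treatment"
    cell_line: str = "line_A"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise TruthError(f"bad role {self.role!r}")
        if self.role == "treatment" and self.compound is None:
            raise TruthError("treatment wells need a compound id")
        if self.concentration < 0:
            raise TruthError("concentration must be >= 0")


def outer_wells_384() -> set[str]:
    """Outer ring of a 384-well plate (rows A/P, columns 1/24) — filled
    with buffer in the assay layout and never assigned."""
    rows = "ABCDEFGHIJKLMNOP"
    outer = set()
    for r in rows:
        for c in range(1, 25):
            if r in ("A", "P") or c in (1, 24):
                outer.add(f"{r}{c:02d}")
    return outer


@dataclass
class PlateDesign:
    """Plate layout: well -> assignment, time points, channel mode."""

    wells: dict[str, WellAssignment]
    timepoints: list[float]
    mode: str = "viability"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise TruthError(f"bad mode {self.mode!r}")
        outer = outer_wells_384()
        assigned_outer = sorted(set(self.wells) & outer)
        if assigned_outer:
            raise TruthError(
                f"outer wells may not be assigned (buffer only): {assigned_outer}"
            )
        n_dmso = sum(1 for w in self.wells.values() if w.role == "dmso_control")
        if n_dmso < 2:
            raise TruthError(
                f"plate needs >= 2 dmso_control wells for normalization, got {n_dmso}"
            )
        if not self.timepoints:
            raise TruthError("at least one timepoint required")
        if any(t < 0 for t in self.timepoints):
            raise TruthError("timepoints must be >= 0 hours")

    @property
    def dmso_wells(self) -> list[str]:
        return [w for w, a in self.wells.items() if a.role == "dmso_control"]

    @property
    def treatment_compounds(self) -> set[str]:
        return {
            a.compound
            for a in self.wells.values()
            if a.role in ("treatment", "reference_compound") and a.compound
        }
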