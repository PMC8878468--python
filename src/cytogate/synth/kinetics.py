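"""Discrete-time compartment model of per-well population kinetics.

Each well evolves at 1 h steps: healthy cells divide at a basal rate;
compound exposure drives exit from the healthy compartment with a Hill
hazard whose midpoint halves every ``potency_halving_time`` hours;
exited cells are routed (per the compound's terminal-state bias) through
early apoptotic -> late apoptotic -> necrotic -> lysed, or enter the
necrotic/lysed compartments directly. Lysed cells may detach and clear;
the cleared count is tracked so total bookkeeping is exact.

FUCCI-mode wells additionally carry a red/green/yellow occupancy over
the healthy compartment that drifts towards an arrest target under
cell-cycle-active compounds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .render import VIABILITY_TO_NUCLEUS, cell_for_viability, random_layout, RenderParams
from .truth import (
    CellTruth,
    CompoundKineticsSpec,
    PlateDesign,
    TruthError,
    VIABILITY_CLASSES,
)

STATE_COLUMNS = list(VIABILITY_CLASSES)  # healthy..lysed

#: baseline FUCCI occupancy (red = G1, green = S/G2/M, yellow = G1/S)
FUCCI_BASE = np.array([0.45, 0.40, 0.15])
#: arrest targets per cell-cycle action, order (red, green, yellow)
FUCCI_TARGETS = {
    "none": FUCCI_BASE,
    "g1_arrest": np.array([0.85, 0.10, 0.05]),
    "s_arrest": np.array([0.10, 0.25, 0.65]),
    "g2m_arrest": np.array([0.08, 0.84, 0.08]),
}
FUCCI_DRIFT_RATE = 0.10  # per hour at full Hill occupancy


@dataclass
class SimulationParams:
    initial_cells: int = 200
    basal_division_rate: float = 0.030  # per hour (doubling ~ 23 h)
    p_early_to_late: float = 0.25
    p_late_to_necrotic: float = 0.20
    p_necrotic_to_lysed: float = 0.15
    p_lysed_cleared: float = 0.02
    fucci_unlabeled_fraction: float = 0.05
    step_hours: float = 1.0


@dataclass
class WellTrajectory:
    """Exact truth for one well: per-timepoint compartment counts."""

    well: str
    compound: str | None
    concentration: float
    role: str
    cell_line: str
    records: pd.DataFrame  # one row per requested timepoint

    def counts_at(self, timepoint: float) -> dict[str, int]:
        row = self.records[self.records["timepoint"] == timepoint]
        if row.empty:
            raise KeyError(f"no record at t={timepoint} for well {self.well}")
        return {s: int(row.iloc[0][s]) for s in STATE_COLUMNS}


@dataclass
class PlateResult:
    design: PlateDesign
    params: SimulationParams
    seed: int
    wells: dict[str, WellTrajectory]

    @property
    def truth_table(self) -> pd.DataFrame:
        return pd.concat([w.records for w in self.wells.values()], ignore_index=True)


def _simulate_well(
    assignment,
    well: str,
    kinetics: CompoundKineticsSpec | None,
    design: PlateDesign,
    params: SimulationParams,
    rng: np.random.Generator,
) -> WellTrajectory:
    conc = assignment.concentration if assignment.role in ("treatment", "reference_compound") else 0.0
    counts = dict.fromkeys(STATE_COLUMNS, 0)
    counts["healthy"] = params.initial_cells
    cleared = 0
    total_created = params.initial_cells
    fucci = FUCCI_BASE.copy()

    horizon = max(design.timepoints)
    requested = sorted(set(design.timepoints))
    rows = []
    t = 0.0

    def record(t_now: float) -> None:
        if design.mode == "fucci":
            labeled = 1.0 - params.fucci_unlabeled_fraction
            n_healthy = counts["healthy"]
            occ = np.append(fucci * labeled, params.fucci_unlabeled_fraction)
            draw = rng.multinomial(n_healthy, occ) if n_healthy > 0 else np.zeros(4, int)
            fucci_counts = dict(zip(("red", "green", "yellow", "unlabeled"), draw.tolist()))
        else:
            fucci_counts = {k: 0 for k in ("red", "green", "yellow", "unlabeled")}
        rows.append(
            {
                "well": well,
                "timepoint": t_now,
                "compound": assignment.compound,
                "concentration": conc,
                "role": assignment.role,
                "cell_line": assignment.cell_line,
                **{s: counts[s] for s in STATE_COLUMNS},
                **{f"fucci_{k}": v for k, v in fucci_counts.items()},
                "cleared": cleared,
                "total_created": total_created,
            }
        )

    next_record = 0
    while True:
        while next_record < len(requested) and requested[next_record] <= t + 1e-9:
            record(requested[next_record])
            next_record += 1
        if t >= horizon - 1e-9:
            break

        # --- one step of the chain ---
        h = counts["healthy"]
        births = rng.binomial(h, min(1.0, params.basal_division_rate * params.step_hours))
        if kinetics is not None and conc > 0:
            hazard = kinetics.exit_hazard(conc, t)
            p_exit = 1.0 - np.exp(-hazard * params.step_hours)
        else:
            p_exit = 0.0
        exits = rng.binomial(h, p_exit) if p_exit > 0 else 0

        if exits > 0 and kinetics is not None:
            bias = kinetics.terminal_state_bias
            probs = [bias.get("apoptotic", 0.0), bias.get("necrotic", 0.0), bias.get("lysed", 0.0)]
            routed = rng.multinomial(exits, probs)
        else:
            routed = np.zeros(3, dtype=int)

        e2l = rng.binomial(counts["early_apoptotic"], params.p_early_to_late)
        l2n = rng.binomial(counts["late_apoptotic"], params.p_late_to_necrotic)
        n2l = rng.binomial(counts["necrotic"], params.p_necrotic_to_lysed)
        ly2c = rng.binomial(counts["lysed"], params.p_lysed_cleared)

        counts["healthy"] = h + births - exits
        counts["early_apoptotic"] += int(routed[0]) - e2l
        counts["late_apoptotic"] += e2l - l2n
        counts["necrotic"] += l2n + int(routed[1]) - n2l
        counts["lysed"] += n2l + int(routed[2]) - ly2c
        cleared += ly2c
        total_created += births

        # FUCCI occupancy drift under arrest-inducing compounds
        if design.mode == "fucci" and kinetics is not None and conc > 0:
            target = FUCCI_TARGETS[kinetics.cell_cycle_action]
            ic50 = kinetics.ic50_at(t)
            occ = conc**kinetics.hill_slope / (
                conc**kinetics.hill_slope + ic50**kinetics.hill_slope
            )
            rate = FUCCI_DRIFT_RATE * occ * params.step_hours
            fucci = fucci + rate * (target - fucci)
            fucci = np.clip(fucci, 0, None)
            fucci = fucci / fucci.sum()

        t += params.step_hours

    df = pd.DataFrame(rows)
    # conservation check — exact by construction
    totals = df[STATE_COLUMNS].sum(axis=1) + df["cleared"]
    assert (totals == df["total_created"]).all()
    return WellTrajectory(well, assignment.compound, conc, assignment.role,
                          assignment.cell_line, df)


def simulate_plate(
    design: PlateDesign,
    kinetics: dict[str, CompoundKineticsSpec],
    seed: int = 0,
    params: SimulationParams | None = None,
) -> PlateResult:
    """Simulate every well of ``design`` over its timepoints.

    Every treatment compound must have a kinetics spec; the design
    itself guarantees the presence of DMSO control wells. Identical
    (design, kinetics, seed) give identical truth tables.
    """
    params = params or SimulationParams()
    missing = design.treatment_compounds - set(kinetics)
    if missing:
        raise TruthError(f"no kinetics spec for compounds: {sorted(missing)}")
    if not design.dmso_wells:
        raise TruthError("design has no DMSO control wells; normalization impossible")

    wells: dict[str, WellTrajectory] = {}
    for well in sorted(design.wells):  # sorted: seed-stable iteration order
        assignment = design.wells[well]
        rng = np.random.default_rng([seed, zlib.crc32(well.encode())])
        spec = kinetics.get(assignment.compound) if assignment.compound else None
        wells[well] = _simulate_well(assignment, well, spec, design, params, rng)
    return PlateResult(design=design, params=params, seed=seed, wells=wells)


def sample_cells_for_well(
    trajectory: WellTrajectory,
    timepoint: float,
    rng: np.random.Generator,
    render_params: RenderParams | None = None,
    max_cells: int = 120,
    mode: str = "viability",
) -> list[CellTruth]:
    """Draw a renderable field population matching a well's compartment
    mix at one timepoint (capped at ``max_cells``; proportions kept)."""
    render_params = render_params or RenderParams()
    counts = trajectory.counts_at(timepoint)
    total = sum(counts.values())
    if total == 0:
        return []
    scale = min(1.0, max_cells / total)
    n_per_state = {s: int(round(c * scale)) for s, c in counts.items()}
    n_total = sum(n_per_state.values())
    if n_total == 0:
        return []
    centers = random_layout(
        n_total,
        render_params.shape,
        max(render_params.min_center_distance, 2.5 * render_params.nucleus_radius),
        rng,
        margin=render_params.margin,
    )
    row = trajectory.records[trajectory.records["timepoint"] == timepoint].iloc[0]
    cells: list[CellTruth] = []
    i = 0
    for state in STATE_COLUMNS:
        for _ in range(n_per_state[state]):
            fucci = "n/a"
            if mode == "fucci" and state == "healthy":
                weights = np.array(
                    [row[f"fucci_{k}"] for k in ("red", "green", "yellow", "unlabeled")],
                    dtype=float,
                )
                if weights.sum() > 0:
                    fucci = ("red", "green", "yellow", "unlabeled")[
                        rng.choice(4, p=weights / weights.sum())
                    ]
                else:
                    fucci = "unlabeled"
            cells.append(
                cell_for_viability(i, (float(centers[i][0]), float(centers[i][1])), state, fucci)
            )
            i += 1
    return cells
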