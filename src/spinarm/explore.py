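"""Goal exploration of the behavior domain (seeding + rGEP loop).

The behavior space is two-dimensional: movement amplitude (deg) against
maximal speed (deg/s).  An archive keeps every valid movement's command
vector, behavior and metrics.  Exploration runs in two stages:

1. *Seeding.*  A bounded CMA-ES minimizes the movement cost toward a
   target minimum-jerk template (small initial step size, 0.005, on the
   normalized [0, 1] parameter cube); every valid movement met during the
   optimization is harvested as a seed.
2. *rGEP.*  Repeatedly sample a goal on the periphery of (extend) or in a
   hole inside (fill) the occupied region of a behavior grid, retrieve the
   archived movement nearest the goal, replay its parameters with small
   Gaussian noise, and archive the outcome if it is a valid movement.

The occupied-cell count of the grid is the behavior-domain *area*; valid
movements per occupied cell is the *density*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._cmaes import CMAES
from .circuits import CircuitTopology
from .commands import CommandRanges, CommandVector
from .evaluate import (GO_TIME, MovementMetrics, cocontraction_penalty,
                       evaluate_movement, minjerk_template)
from .simulate import SimConfig, SimTrace, _CompiledModel, default_model, run_trial


@dataclass
class ArchiveEntry:
    entry_id: int
    vector: CommandVector
    behavior: tuple  # (amplitude deg, max_speed deg/s)
    metrics: MovementMetrics
    parent_id: int | None = None
    provenance: str = "seed"  # seed | extend | fill


@dataclass(frozen=True)
class BehaviorGrid:
    amplitude_cell: float = 5.0  # deg
    speed_cell: float = 10.0  # deg/s

    def cell_of(self, behavior) -> tuple:
        amp, speed = behavior
        return (int(np.floor(amp / self.amplitude_cell)),
                int(np.floor(speed / self.speed_cell)))

    def cell_bounds(self, cell) -> tuple:
        i, j = cell
        return (i * self.amplitude_cell, (i + 1) * self.amplitude_cell,
                j * self.speed_cell, (j + 1) * self.speed_cell)

    def occupancy(self, archive) -> dict:
        counts: dict[tuple, int] = {}
        for e in archive:
            c = self.cell_of(e.behavior)
            counts[c] = counts.get(c, 0) + 1
        return counts


def grid_metrics(archive, grid: BehaviorGrid | None = None) -> tuple:
    """(area in occupied cells, mean valid movements per occupied cell)."""
    grid = grid or BehaviorGrid()
    counts = grid.occupancy(archive)
    area = len(counts)
    density = (sum(counts.values()) / area) if area else 0.0
    return area, density


def domain_perimeter(archive, grid: BehaviorGrid | None = None) -> list:
    """Occupied boundary cells (for plotting the domain outline)."""
    grid = grid or BehaviorGrid()
    occ = set(grid.occupancy(archive))
    out = []
    for (i, j) in occ:
        nbrs = sum((i + di, j + dj) in occ
                   for di in (-1, 0, 1) for dj in (-1, 0, 1)
                   if (di, dj) != (0, 0))
        if nbrs < 8:
            out.append((i, j))
    return sorted(out)


# ---------------------------------------------------------------------------
# goal sampling


_NEIGHBORS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
              if (di, dj) != (0, 0)]


def _dilation_ring(occ: set) -> list:
    ring = set()
    for (i, j) in occ:
        for di, dj in _NEIGHBORS:
            c = (i + di, j + dj)
            if c not in occ and c[0] >= 0 and c[1] >= 0:
                ring.add(c)
    return sorted(ring)


def _holes(occ: set) -> list:
    holes = []
    for c in _dilation_ring(occ):
        n_occ = sum((c[0] + di, c[1] + dj) in occ for di, dj in _NEIGHBORS)
        if n_occ >= 2:
            holes.append(c)
    return sorted(holes)


def sample_goal(archive, grid: BehaviorGrid, strategy: str,
                rng: np.random.Generator) -> tuple:
    """Draw one behavior-space goal on the periphery (extend) or in a hole (fill)."""
    if not archive:
        raise ValueError("archive is empty; seed it first")
    occ = set(grid.occupancy(archive))
    if strategy == "fill":
        cells = _holes(occ)
        if not cells:
            strategy, cells = "extend", _dilation_ring(occ)
    elif strategy == "extend":
        cells = _dilation_ring(occ)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    cell = cells[rng.integers(len(cells))]
    a_lo, a_hi, s_lo, s_hi = grid.cell_bounds(cell)
    return (float(rng.uniform(a_lo, a_hi)), float(rng.uniform(s_lo, s_hi)))


DEFAULT_SPEED_SCALE = 300.0  # deg/s


def nearest_valid(archive, goal, speed_scale: float = DEFAULT_SPEED_SCALE) -> ArchiveEntry:
    """Archive entry whose behavior is closest to the goal (scaled Euclidean).

    Amplitude is scaled by 110 deg and speed by ``speed_scale``; exact ties
    break to the lowest entry id.
    """
    if not archive:
        raise ValueError("archive is empty")
    ga, gs = goal
    best = None
    best_key = None
    for e in archive:
        d = ((e.behavior[0] - ga) / 110.0) ** 2 + ((e.behavior[1] - gs) / speed_scale) ** 2
        key = (d, e.entry_id)
        if best_key is None or key < best_key:
            best, best_key = e, key
    return best


def perturb(vector: CommandVector, sigma_explore: float,
            rng: np.random.Generator) -> CommandVector:
    """Add iid zero-mean Gaussian noise per coordinate, clipped to [0, 1]."""
    if sigma_explore <= 0:
        raise ValueError("sigma_explore must be > 0")
    x = vector.as_array() + rng.normal(0.0, sigma_explore, size=len(vector))
    return CommandVector(tuple(np.clip(x, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# seeding


@dataclass(frozen=True)
class SeederConfig:
    target_amplitude: float = 30.0  # deg
    target_duration: float = 1.0  # s
    sigma0: float = 0.005
    bounds: tuple = (0.0, 1.0)
    budget: int = 2000  # simulation runs
    popsize: int | None = None
    n_restarts: int = 4
    prescan: int = 150  # random draws per restart to pick the ES start point
    rng_seed: int = 0


def _target_cost(trace: SimTrace, target_amplitude: float,
                 target_duration: float) -> float:
    """Cost of a trace against a FIXED target template (for the seeder)."""
    if trace.failed:
        return 1e6
    t = trace.time
    sel = (t >= 2.0) & (t <= 10.0)
    desired = trace.angle[0] + minjerk_template(
        target_amplitude, target_duration, GO_TIME, t[sel])
    tracking = float(np.mean((trace.angle[sel] - desired) ** 2))
    p1 = cocontraction_penalty(trace.potentials["FlxAlpha"],
                               trace.potentials["ExtAlpha"], t, (2.0, 5.0))
    p2 = cocontraction_penalty(trace.potentials["FlxAlpha"],
                               trace.potentials["ExtAlpha"], t, (7.0, 10.0))
    return tracking + p1 + p2


def seed_search(topology: CircuitTopology, seeder: SeederConfig | None = None,
                model: _CompiledModel | None = None,
                sim: SimConfig | None = None,
                ranges: CommandRanges | None = None) -> list:
    """Run the evolution-strategy seeder; harvest every valid movement met.

    Each restart draws a fresh random start point on the parameter cube and
    runs CMA-ES (step size 0.005, bounds [0, 1]) toward the target template
    until its share of the run budget is spent.  May legitimately return an
    empty list if no valid movement is encountered within the budget.
    """
    seeder = seeder or SeederConfig()
    if seeder.budget <= 0:
        raise ValueError("budget must be > 0")
    model = model or default_model(topology)
    sim = sim or SimConfig()
    rng = np.random.default_rng(seeder.rng_seed)
    n = topology.parameter_count
    seeds: list[ArchiveEntry] = []
    evals = 0

    def run_one(x) -> float:
        nonlocal evals
        vec = CommandVector(tuple(x))
        trace = run_trial(vec, topology, model=model, sim=sim, ranges=ranges)
        evals += 1
        metrics = evaluate_movement(trace)
        if metrics.valid:
            seeds.append(ArchiveEntry(
                entry_id=len(seeds), vector=vec,
                behavior=(metrics.amplitude, metrics.max_speed),
                metrics=metrics, provenance="seed"))
        return _target_cost(trace, seeder.target_amplitude,
                            seeder.target_duration)

    per_restart = max(1, seeder.budget // max(1, seeder.n_restarts))
    for _ in range(seeder.n_restarts):
        if evals >= seeder.budget:
            break
        spent = 0
        # pick the restart's start point as the best of a random prescan:
        # the cost plateau around fully quiescent configurations is flat,
        # so the ES needs a graded (movement-producing) basin to start in
        n_scan = min(seeder.prescan, per_restart // 2)
        best_x, best_c = None, np.inf
        for _ in range(max(1, n_scan)):
            x = rng.uniform(0.0, 1.0, size=n)
            c = run_one(x)
            spent += 1
            if c < best_c:
                best_x, best_c = x, c
        es = CMAES(best_x, seeder.sigma0, bounds=seeder.bounds,
                   popsize=seeder.popsize, rng=rng)
        while spent < per_restart and evals < seeder.budget:
            xs = es.ask()
            fit = []
            for x in xs:
                fit.append(run_one(x))
                spent += 1
            es.tell(xs, fit)
    return seeds


# ---------------------------------------------------------------------------
# the rGEP loop


@dataclass(frozen=True)
class GEPConfig:
    n_extend_rounds: int = 300
    n_fill_rounds: int = 50
    goals_per_round_cap: int = 10
    sigma_explore: float = 0.02
    speed_scale: float = DEFAULT_SPEED_SCALE
    rng_seed: int = 0
    grid: BehaviorGrid = field(default_factory=BehaviorGrid)


def run_gep(seeds, topology: CircuitTopology, gep: GEPConfig | None = None,
            model: _CompiledModel | None = None,
            sim: SimConfig | None = None,
            ranges: CommandRanges | None = None) -> tuple:
    """Iterate goal -> nearest -> perturb -> simulate -> evaluate -> store.

    Returns (archive, history); the history logs per-round run counts and
    the area/density trajectory of the behavior domain.  Only valid
    movements enter the archive; the number of goals per extend round
    scales with the current boundary length up to the configured cap.
    """
    if not seeds:
        raise ValueError("rGEP needs at least one seed")
    gep = gep or GEPConfig()
    model = model or default_model(topology)
    sim = sim or SimConfig()
    rng = np.random.default_rng(gep.rng_seed)
    archive: list[ArchiveEntry] = []
    for s in seeds:
        archive.append(ArchiveEntry(
            entry_id=len(archive), vector=s.vector, behavior=s.behavior,
            metrics=s.metrics, parent_id=None, provenance="seed"))
    history = []
    runs = 0
    rounds = [("extend", gep.n_extend_rounds), ("fill", gep.n_fill_rounds)]
    for strategy, n_rounds in rounds:
        for _ in range(n_rounds):
            occ = set(gep.grid.occupancy(archive))
            boundary = len(_dilation_ring(occ))
            n_goals = max(1, min(gep.goals_per_round_cap, boundary))
            for _ in range(n_goals):
                goal = sample_goal(archive, gep.grid, strategy, rng)
                parent = nearest_valid(archive, goal, gep.speed_scale)
                vec = perturb(parent.vector, gep.sigma_explore, rng)
                trace = run_trial(vec, topology, model=model, sim=sim,
                                  ranges=ranges)
                metrics = evaluate_movement(trace)
                runs += 1
                if metrics.valid:
                    archive.append(ArchiveEntry(
                        entry_id=len(archive), vector=vec,
                        behavior=(metrics.amplitude, metrics.max_speed),
                        metrics=metrics, parent_id=parent.entry_id,
                        provenance=strategy))
            area, density = grid_metrics(archive, gep.grid)
            history.append({"strategy": strategy, "runs": runs,
                            "n_valid": len(archive), "area": area,
                            "density": density})
    return archive, history


# ---------------------------------------------------------------------------
# persistence


def archive_to_frame(archive):
    import pandas as pd

    rows = []
    for e in archive:
        tri = e.metrics.triphasic
        rows.append({
            "entry_id": e.entry_id,
            "parent_id": e.parent_id if e.parent_id is not None else -1,
            "provenance": e.provenance,
            "amplitude": e.behavior[0],
            "max_speed": e.behavior[1],
            "duration": e.metrics.duration,
            "cost": e.metrics.cost,
            "valid": e.metrics.valid,
            "triphasic": bool(tri.is_triphasic) if tri else False,
            "vector": json.dumps(list(e.vector.values)),
        })
    return pd.DataFrame(rows)


def save_archive(archive, csv_path, manifest: dict | None = None) -> None:
    csv_path = Path(csv_path)
    archive_to_frame(archive).to_csv(csv_path, index=False)
    if manifest is not None:
        csv_path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
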