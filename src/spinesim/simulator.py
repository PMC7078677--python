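"""Time-stepped coupling of actin foci and membrane mechanics.

One tick of length dt:

1. evaluate the membrane force field;
2. advance every focus's filament bookkeeping, using the magnitude of the
   membrane force at the focus's center vertex in the branching rate;
3. remove foci that reached B = 0, logging their lifetimes;
4. with probability ``dt * gamma_f`` attempt to nucleate a new focus;
5. evaluate the actin force field;
6. move the membrane: classical RK4 on dx/dt = zeta (F_mem + F_fil), with
   F_mem re-evaluated at every RK4 stage, F_fil held constant over the
   tick, and recursive halving of the interval whenever a free vertex
   would move farther than d_tol;
7. remesh and re-map focus centers onto the nearest surviving vertex;
8. record time, area, focus count and mean barbed-end count.

A full run first relaxes the mesh to the resting shape (area A_s), inserts
``n_f0`` foci by the normal nucleation procedure, then loops the tick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._kernels import advance_interval
from .errors import StabilityError
from .foci import Focus, actin_force_field, nucleate_focus
from .actin import step_focus_state
from .mechanics import ForceField, membrane_force, relax_to_rest
from .mesh import (
    MembraneMesh, compute_geometry, excise_self_intersections,
    init_spine_mesh, remesh,
)
from .params import ModelParams

__all__ = [
    "SimulationState",
    "SimulationTrace",
    "move_membrane",
    "simulation_step",
    "run_simulation",
    "run_sweep",
    "get_resting_mesh",
]

logger = logging.getLogger("spinesim")

MAX_HALVINGS = 20
JAM_FUSE_AFTER = 8  # contact-jammed ticks before fusing at the contact


@dataclass
class SimulationState:
    """Complete dynamic state of a running simulation."""

    mesh: MembraneMesh
    foci: List[Focus]
    t: float
    rng: np.random.Generator
    params: ModelParams
    next_focus_id: int = 0
    lifetime_log: List[dict] = field(default_factory=list)
    jammed_ticks: int = 0  # consecutive ticks reverted by wall contact


@dataclass
class SimulationTrace:
    """Per-step observables plus focus-lifetime log and mesh snapshots."""

    t: np.ndarray
    area: np.ndarray
    n_f: np.ndarray
    mean_b: np.ndarray
    focus_log: pd.DataFrame
    snapshots: List[Tuple[float, MembraneMesh]]
    a_s: float
    params: ModelParams
    seed: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "area": self.area,
            "n_f": self.n_f, "mean_B": self.mean_b,
        })


def move_membrane(
    mesh: MembraneMesh,
    total_actin_force: ForceField,
    params: ModelParams,
    dt: float,
) -> MembraneMesh:
    """Integrate membrane motion over *dt* with adaptive sub-stepping.

    Fixed vertices never move.  The actin force field is frozen for the
    whole interval; the membrane force is re-evaluated at every RK4 stage
    and at every sub-interval boundary.
    """
    if total_actin_force.vectors.shape != mesh.positions.shape:
        raise ValueError("force field does not match mesh size")
    pos = np.ascontiguousarray(mesh.positions, dtype=np.float64)
    free = np.ascontiguousarray(~mesh.fixed)
    ffil = np.ascontiguousarray(total_actin_force.vectors, dtype=np.float64)
    new, status = advance_interval(pos, free, ffil, float(dt), params.d_tol,
                                   params.zeta, params.P, params.tau,
                                   params.kappa, MAX_HALVINGS)
    if status != 0:
        raise StabilityError(
            f"free-vertex displacement still above d_tol={params.d_tol} μm "
            f"after {MAX_HALVINGS} interval halvings"
        )
    out = mesh.copy()
    out.positions = new
    _clamp_to_plateaus(out)
    return out


def _clamp_to_plateaus(mesh: MembraneMesh) -> None:
    """Keep free vertices from crossing the fixed plateau chords.

    The regions beyond the plateaus are excluded volume — the neck is
    filled by its stable actin core and the PSD chord abuts the synaptic
    contact — so a free vertex that would cross a chord within its
    x-extent is projected back onto it.  Without this, a vertex slipping
    past a plateau corner seeds an inverted lobe that the pressure term
    then inflates.
    """
    pos = mesh.positions
    free = ~mesh.fixed
    for level, sign in ((mesh.h_PSD, 1.0), (mesh.h_neck, -1.0)):
        if level is None or not np.isfinite(level):
            continue
        on = mesh.fixed & np.isclose(pos[:, 1], level)
        if not on.any():
            continue
        x_lo, x_hi = pos[on, 0].min(), pos[on, 0].max()
        crossing = (free & (sign * pos[:, 1] > sign * level)
                    & (pos[:, 0] >= x_lo) & (pos[:, 0] <= x_hi))
        # a hair inside the chord, not onto it: coincident vertices would
        # make the ring degenerate (self-touching)
        pos[crossing, 1] = level - sign * 1e-9


def _self_intersects(mesh: MembraneMesh) -> bool:
    import shapely

    return not shapely.Polygon(mesh.positions).is_valid


def _resolve_wall_contacts(old_pos: np.ndarray,
                           mesh: MembraneMesh) -> MembraneMesh:
    """Steric contact: keep membrane walls from crossing during a tick.

    The model has no self-contact force, so a tick's motion can push two
    membrane walls through each other (a retracting protrusion's flanks,
    or the two sides of a crevice being zipped shut by tension); the
    inverted lens between crossed edges would then be inflated without
    bound by the pressure term.  When the moved polygon self-intersects,
    the whole tick's movement is reverted: the membrane jams in contact
    for that tick while the actin dynamics continue, and it moves again
    once the force balance releases it.  (Reverting only the vertices
    near the crossing was tried and creates unphysical mixed states —
    frozen walls entangled by a still-moving surround.)
    """
    import shapely

    if (len(old_pos) != len(mesh.positions)
            or shapely.Polygon(mesh.positions).is_valid):
        return mesh
    out = mesh.copy()
    out.positions = old_pos.copy()
    return out


def simulation_step(state: SimulationState) -> SimulationState:
    """Advance the coupled system by one tick of length dt (in place)."""
    params = state.params
    mesh = state.mesh

    f_mem = membrane_force(mesh, params)
    f_mem_norm = np.linalg.norm(f_mem.vectors, axis=1)

    # actin update with the membrane force magnitude at each focus center
    for focus in state.foci:
        focus.state = step_focus_state(
            focus.state, float(f_mem_norm[focus.center_vertex]), params, state.rng)

    survivors = []
    for focus in state.foci:
        if focus.alive:
            survivors.append(focus)
        else:
            death = state.t + params.dt
            state.lifetime_log.append({
                "id": focus.id,
                "birth": focus.birth_time,
                "death": death,
                "lifetime": death - focus.birth_time,
                "x_n": focus.x_n[0],
                "y_n": focus.x_n[1],
            })
    state.foci = survivors

    if state.rng.random() < params.dt * params.gamma_f:
        new = nucleate_focus(mesh, params, state.rng,
                             birth_time=state.t + params.dt,
                             focus_id=state.next_focus_id)
        if new is not None:
            state.foci.append(new)
            state.next_focus_id += 1

    f_fil = actin_force_field(mesh, state.foci, params)
    moved = move_membrane(mesh, f_fil, params, params.dt)
    resolved = _resolve_wall_contacts(mesh.positions, moved)
    if resolved is not moved:
        state.jammed_ticks += 1
        if state.jammed_ticks >= JAM_FUSE_AFTER:
            # persistent contact: the crevice is being pressed shut, not
            # brushed in passing — fuse the membrane at the contact and
            # let the dynamics continue
            moved = excise_self_intersections(moved)
            state.jammed_ticks = 0
        else:
            moved = resolved
    else:
        state.jammed_ticks = 0
    old_centers = [moved.positions[f.center_vertex].copy()
                   for f in state.foci]
    new_mesh = remesh(moved, params)
    if new_mesh is not moved and _self_intersects(new_mesh):
        # remeshing across a tight fold can create a crossing; defer it
        new_mesh = moved

    if new_mesh is not moved:
        # re-map focus centers to the nearest surviving vertex
        for focus, old_center in zip(state.foci, old_centers):
            focus.center_vertex = int(np.argmin(
                np.linalg.norm(new_mesh.positions - old_center, axis=1)))

    state.mesh = new_mesh
    state.t += params.dt
    return state


_REST_CACHE: Dict[tuple, Tuple[MembraneMesh, float]] = {}


def get_resting_mesh(params: ModelParams):
    """Relaxed resting mesh and area A_s, cached on the mechanics-relevant
    parameters (the resting shape does not depend on the actin kinetics)."""
    key = (params.dt, params.delta_s, params.r_s, params.r_neck, params.r_PSD,
           params.P, params.tau, params.kappa, params.zeta, params.d_tol,
           params.d_min, params.d_max)
    if key not in _REST_CACHE:
        mesh, a_s = relax_to_rest(init_spine_mesh(params), params)
        _REST_CACHE[key] = (mesh, a_s)
    mesh, a_s = _REST_CACHE[key]
    return mesh.copy(), a_s


def run_simulation(
    params: ModelParams,
    duration: float,
    seed: int,
    snapshot_interval: float = 15.0,
    rest: Optional[Tuple[MembraneMesh, float]] = None,
) -> SimulationTrace:
    """Relax, seed ``n_f0`` foci, and simulate for *duration* seconds.

    Observables are recorded after every step; a run of zero duration
    records the initial state once.  *rest* may supply a precomputed
    ``(resting_mesh, A_s)`` to skip the relaxation phase.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    rng = np.random.default_rng(seed)
    if rest is None:
        rest = get_resting_mesh(params)
    mesh, a_s = rest[0].copy(), rest[1]

    state = SimulationState(mesh=mesh, foci=[], t=0.0, rng=rng, params=params)
    for _ in range(params.n_f0):
        focus = nucleate_focus(mesh, params, rng, birth_time=0.0,
                               focus_id=state.next_focus_id)
        if focus is not None:
            state.foci.append(focus)
            state.next_focus_id += 1

    n_steps = int(round(duration / params.dt))
    records = max(n_steps, 1)
    t_arr = np.empty(records)
    area_arr = np.empty(records)
    nf_arr = np.empty(records, dtype=np.int64)
    mb_arr = np.empty(records)
    snapshots: List[Tuple[float, MembraneMesh]] = []

    def record(i: int) -> None:
        t_arr[i] = state.t
        area_arr[i] = compute_geometry(state.mesh).area_enclosed
        nf_arr[i] = len(state.foci)
        mb_arr[i] = (np.mean([f.state.B for f in state.foci])
                     if state.foci else np.nan)

    snap_every = max(1, int(round(snapshot_interval / params.dt)))
    if n_steps == 0:
        record(0)
    for i in range(n_steps):
        simulation_step(state)
        record(i)
        if (i + 1) % snap_every == 0:
            snapshots.append((state.t, state.mesh.copy()))
        if (i + 1) % 1000 == 0:
            logger.info("step %d/%d  t=%.1f s  area=%.4f  n_f=%d",
                        i + 1, n_steps, state.t, area_arr[i], nf_arr[i])

    log = pd.DataFrame(
        state.lifetime_log,
        columns=["id", "birth", "death", "lifetime", "x_n", "y_n"],
    )
    return SimulationTrace(t_arr, area_arr, nf_arr, mb_arr, log,
                           snapshots, a_s, params, seed)


def run_sweep(
    base: ModelParams,
    param_name: str,
    values,
    n_replicates: int = 15,
    replicate_duration: float = 900.0,
    seeds=None,
    long_duration: Optional[float] = 5400.0,
) -> pd.DataFrame:
    """Per-run summaries over a one-parameter sweep.

    For each value: one long run (omitted when *long_duration* is None) and
    *n_replicates* replicate runs with distinct seeds.  Each row reports the
    run's mean area, area SD, mean focus lifetime (completed foci), mean
    focus count and the resting area.
    """
    if param_name not in base.asdict():
        raise ValueError(f"unknown parameter {param_name!r}")
    if seeds is None:
        seeds = np.arange(1, n_replicates + 1)
    rows = []
    for value in values:
        params = base.replace(**{param_name: value})
        rest = get_resting_mesh(params)
        runs = []
        if long_duration:
            runs.append(("long", int(10_000 + round(1000 * float(value))), long_duration))
        for rep, seed in enumerate(seeds):
            runs.append((f"rep{rep}", int(seed), replicate_duration))
        for kind, seed, dur in runs:
            trace = run_simulation(params, dur, seed, rest=rest)
            lifetimes = trace.focus_log["lifetime"].to_numpy()
            rows.append({
                param_name: value,
                "kind": kind,
                "seed": seed,
                "duration": dur,
                "mean_area": float(trace.area.mean()),
                "sd_area": float(trace.area.std(ddof=0)),
                "mean_lifetime": float(lifetimes.mean()) if len(lifetimes) else np.nan,
                "mean_n_f": float(trace.n_f.mean()),
                "a_s": trace.a_s,
            })
            logger.info("sweep %s=%s %s done (mean area %.4f)",
                        param_name, value, kind, rows[-1]["mean_area"])
    return pd.DataFrame(rows)
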