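"""Helfrich-type membrane energy, its gradient force, and relaxation.

The membrane resists deformation through three terms,

    E_mem = P * Omega + tau * S + 2 kappa * int_Gamma H^2 ds,

with pressure difference P, line tension tau and bending modulus kappa;
Omega is the enclosed area, S the boundary length and H the curvature.  On
the polygon mesh the integral becomes a sum over vertices of H_k^2 ds_k
using the discrete operators of :mod:`spinesim.mesh`.  The force on vertex
k is the negative gradient of this *discretized* energy,
F_mem(x^k) = -dE_mem/dx^k, evaluated analytically (and verified against
finite differences in the test-suite).

With the PSD and neck held fixed, the membrane force alone drives the mesh
to a characteristic resting shape whose enclosed area A_s is the baseline
of all area fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import membrane_force_kernel
from .errors import ConvergenceError
from .mesh import MembraneMesh, compute_geometry, remesh
from .params import ModelParams

__all__ = [
    "ForceField",
    "membrane_energy",
    "membrane_force",
    "relax_to_rest",
]


@dataclass
class ForceField:
    """Per-vertex 2D force vectors (pN) with a source label."""

    vectors: np.ndarray
    source: str = "total"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("force field contains non-finite entries")

    def __add__(self, other: "ForceField") -> "ForceField":
        return ForceField(self.vectors + other.vectors, "total")


def membrane_energy(mesh: MembraneMesh, params: ModelParams) -> float:
    """Discretized membrane energy P*Omega + tau*S + 2*kappa*sum H^2 ds."""
    geo = compute_geometry(mesh)
    bending = float(np.sum(geo.curvature ** 2 * geo.ds))
    return (params.P * geo.area_enclosed
            + params.tau * geo.boundary_length
            + 2.0 * params.kappa * bending)


def membrane_force(mesh: MembraneMesh, params: ModelParams) -> ForceField:
    """Negative analytic gradient of :func:`membrane_energy` per vertex."""
    compute_geometry(mesh)  # surface degenerate-geometry errors consistently
    vec = membrane_force_kernel(
        np.ascontiguousarray(mesh.positions, dtype=np.float64),
        params.P, params.tau, params.kappa,
    )
    return ForceField(vec, "membrane")


def relax_to_rest(
    mesh: MembraneMesh,
    params: ModelParams,
    max_disp_tol: float = 1e-4,
    max_iters: int = 100_000,
    window: int = 500,
    area_tol: float = 5e-4,
):
    """Relax the mesh under membrane forces alone to its resting shape.

    Iterates the simulation's movement step (zero actin force) followed by
    remeshing.  The discrete energy has no isolated static minimum — free
    vertices could collapse onto each other without the remeshing bounds —
    so the resting shape is the quasi-stationary state of this gradient
    flow.  Convergence is declared when either the largest free-vertex
    displacement of a step falls below *max_disp_tol* (μm) or the mean
    enclosed area over consecutive *window*-step windows drifts by less
    than *area_tol* (μm²).  Returns ``(resting_mesh, A_s)`` with ``A_s``
    the enclosed area of the converged mesh.
    """
    from .simulator import move_membrane  # local import to avoid a cycle

    current = mesh.copy()
    zero = ForceField(np.zeros_like(current.positions), "actin")
    prev_window_mean = None
    area_sum = 0.0
    last_disp = np.inf
    for it in range(1, max_iters + 1):
        moved = move_membrane(current, zero, params, params.dt)
        free = ~current.fixed
        if free.any():
            disp = np.linalg.norm(moved.positions - current.positions, axis=1)
            last_disp = float(disp[free].max())
        else:
            last_disp = 0.0
        current = remesh(moved, params)
        if current.n_vertices != moved.n_vertices:
            zero = ForceField(np.zeros_like(current.positions), "actin")
        if last_disp < max_disp_tol:
            return current, compute_geometry(current).area_enclosed
        area_sum += compute_geometry(current).area_enclosed
        if it % window == 0:
            window_mean = area_sum / window
            area_sum = 0.0
            if (prev_window_mean is not None
                    and abs(window_mean - prev_window_mean) < area_tol):
                return current, compute_geometry(current).area_enclosed
            prev_window_mean = window_mean
    raise ConvergenceError(
        f"resting shape did not stabilize within {max_iters} iterations "
        f"(last max displacement {last_disp:.3e} μm)"
    )
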