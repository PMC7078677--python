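"""Nucleation of polymerization foci and their force field on the mesh.

New foci nucleate near the membrane but away from the PSD, reflecting the
localization of the branching machinery (Arp2/3 within ~100 nm of the
membrane) and the need for short filaments.  Nucleation samples 1,000
uniform candidate points inside the spine polygon, keeps those within
``nucleation_shell`` (0.1 μm) of the membrane and farther than that from
the PSD chord, and selects one with probability proportional to
``exp(-d_j / lambda)`` where ``d_j`` is the candidate's distance to the
PSD.  Small ``lambda`` concentrates nucleation near the PSD; large
``lambda`` makes the choice uniform within the shell.

The force a focus exerts on the membrane acts at its center vertex
``X_c`` (a mesh vertex near the nucleation point ``X_n``) and extends
laterally with a Gaussian kernel

    W(x) = alpha / (sigma sqrt(2 pi)) * exp(-x^2 / (2 sigma^2)),

so vertex k feels ``sum_i W(||x^k - X_c^i||) B^i V_{i,k}`` with
``V_{i,k} = (x^k - X_n^i) / ||x^k - X_n^i||`` pointing away from the
nucleation point and B^i the focus's barbed-end count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import shapely

from .actin import FocusState
from .mechanics import ForceField
from .mesh import MembraneMesh
from .params import ModelParams

__all__ = ["Focus", "nucleate_focus", "actin_force_field"]

N_CANDIDATES = 1000


@dataclass
class Focus:
    """A polymerization focus.

    ``x_n`` is the (fixed) nucleation point, ``center_vertex`` indexes the
    mesh vertex serving as force center X_c (re-mapped after remeshing),
    ``state`` carries the filament bookkeeping and ``birth_time`` the
    nucleation time in seconds.
    """

    id: int
    x_n: np.ndarray
    center_vertex: int
    state: FocusState
    birth_time: float = 0.0

    @property
    def alive(self) -> bool:
        return self.state.alive


def _sample_interior_points(mesh: MembraneMesh, rng: np.random.Generator,
                            n_points: int) -> Optional[np.ndarray]:
    """Rejection-sample uniform points inside the polygon."""
    polygon = shapely.Polygon(mesh.positions)
    if not polygon.is_valid or polygon.area <= 0.0:
        return None
    minx, miny, maxx, maxy = polygon.bounds
    points = np.empty((n_points, 2))
    have = 0
    for _ in range(200):  # acceptance rate is ~Omega/bbox, far above 1/200
        need = n_points - have
        batch = rng.uniform((minx, miny), (maxx, maxy), size=(max(4 * need, 64), 2))
        inside = shapely.contains_xy(polygon, batch[:, 0], batch[:, 1])
        accepted = batch[inside][:need]
        points[have:have + len(accepted)] = accepted
        have += len(accepted)
        if have == n_points:
            return points
    return points[:have] if have else None


def nucleate_focus(
    mesh: MembraneMesh,
    params: ModelParams,
    rng: np.random.Generator,
    birth_time: float = 0.0,
    focus_id: int = 0,
    initial_filaments: int = 1,
) -> Optional[Focus]:
    """Attempt to nucleate one focus; returns None if no candidate survives.

    The fresh focus starts with *initial_filaments* filaments, all
    minus-end capped (the nascent Arp2/3-bound state).
    """
    shell = params.nucleation_shell
    candidates = _sample_interior_points(mesh, rng, N_CANDIDATES)
    if candidates is None:
        return None

    boundary = shapely.LinearRing(mesh.positions)
    seg = mesh.psd_segment()
    psd = (shapely.LineString(seg) if not np.allclose(seg[0], seg[1])
           else shapely.Point(seg[0]))
    pts = shapely.points(candidates)
    d_membrane = shapely.distance(pts, boundary)
    d_psd = shapely.distance(pts, psd)

    keep = (d_membrane <= shell) & (d_psd > shell)
    if not keep.any():
        return None
    candidates = candidates[keep]
    d_psd = d_psd[keep]

    # PSD-distance weighting; shift by the minimum for numerical stability
    w = np.exp(-(d_psd - d_psd.min()) / params.lam)
    x_n = candidates[rng.choice(len(candidates), p=w / w.sum())]

    near = np.flatnonzero(
        np.linalg.norm(mesh.positions - x_n, axis=1) <= shell)
    if len(near) == 0:
        return None
    center = int(near[rng.integers(len(near))])
    return Focus(
        id=focus_id,
        x_n=np.asarray(x_n, dtype=float),
        center_vertex=center,
        state=FocusState(m_c=int(initial_filaments), m_u=0),
        birth_time=birth_time,
    )


def actin_force_field(
    mesh: MembraneMesh,
    foci: List[Focus],
    params: ModelParams,
) -> ForceField:
    """Sum the Gaussian force kernels of all foci over the mesh vertices."""
    pos = mesh.positions
    total = np.zeros_like(pos)
    w0 = params.alpha / (params.sigma * math.sqrt(2.0 * math.pi))
    for focus in foci:
        center = pos[focus.center_vertex]
        d_center = np.linalg.norm(pos - center, axis=1)
        w = w0 * np.exp(-(d_center ** 2) / (2.0 * params.sigma ** 2))
        v = pos - focus.x_n
        norms = np.linalg.norm(v, axis=1)
        ok = norms > 0.0  # a vertex coincident with X_n gets no contribution
        contrib = np.zeros_like(pos)
        contrib[ok] = (w[ok] * focus.state.B / norms[ok])[:, None] * v[ok]
        total += contrib
    return ForceField(total, "actin")
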