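"""Closed polygonal membrane mesh: construction, measurement, remeshing.

The spine membrane is a simple, counterclockwise-ordered 2D polygon.  Two
morphological constraints of a mature spine are built in at initialization:
vertices at the post-synaptic density (PSD) are projected onto a flat
plateau at ``y = h_PSD`` and vertices at the neck onto ``y = h_neck``; both
sets are flagged *fixed* and never move afterwards.

Discrete geometric operators:

* enclosed area via the shoelace formula;
* boundary length as the sum of edge lengths;
* per-vertex curvature ``H_k = 1/R_k`` from the circumradius of the vertex
  and its two neighbours, signed by the turn direction (positive on a
  counterclockwise-convex arc);
* per-vertex arc-length weight ``ds_k`` as half the sum of the two adjacent
  edge lengths.

Remeshing keeps edge lengths within ``[d_min, d_max]``: edges longer than
``d_max`` are split at their midpoint, edges shorter than ``d_min`` lose one
(free) endpoint.  Fixed vertices are never removed, and a midpoint inserted
between two fixed vertices is itself fixed (it lies on the same plateau).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GeometryError
from .params import ModelParams

__all__ = [
    "MembraneMesh",
    "GeometryReport",
    "init_spine_mesh",
    "compute_geometry",
    "remesh",
    "excise_self_intersections",
]


@dataclass
class MembraneMesh:
    """Cyclically ordered polygon with per-vertex fixed flags.

    Attributes
    ----------
    positions : (n, 2) float array
        Vertex coordinates in μm, counterclockwise order.
    fixed : (n,) bool array
        True for PSD/neck plateau vertices that never move.
    h_PSD, h_neck : float
        y-levels of the PSD and neck plateaus (μm).
    delta_s : float
        Target edge length (μm).
    """

    positions: np.ndarray
    fixed: np.ndarray
    h_PSD: float
    h_neck: float
    delta_s: float

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    def copy(self) -> "MembraneMesh":
        return MembraneMesh(
            self.positions.copy(), self.fixed.copy(),
            self.h_PSD, self.h_neck, self.delta_s,
        )

    def psd_vertex_mask(self) -> np.ndarray:
        """Fixed vertices lying on the PSD plateau."""
        return self.fixed & np.isclose(self.positions[:, 1], self.h_PSD)

    def psd_segment(self) -> np.ndarray:
        """Endpoints ((x0, h_PSD), (x1, h_PSD)) of the PSD chord.

        Falls back to the degenerate point (0, h_PSD) when no vertex is on
        the plateau (e.g. ``r_PSD = 0``).
        """
        mask = self.psd_vertex_mask()
        if not mask.any():
            return np.array([[0.0, self.h_PSD], [0.0, self.h_PSD]])
        xs = self.positions[mask, 0]
        return np.array([[xs.min(), self.h_PSD], [xs.max(), self.h_PSD]])

    def write_csv(self, path: Union[str, Path]) -> None:
        """Write the snapshot as CSV with columns x, y, fixed (0/1)."""
        df = pd.DataFrame({
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
            "fixed": self.fixed.astype(int),
        })
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: Union[str, Path], h_PSD: float = np.nan,
                 h_neck: float = np.nan, delta_s: float = 0.03) -> "MembraneMesh":
        df = pd.read_csv(path)
        return cls(
            df[["x", "y"]].to_numpy(float),
            df["fixed"].to_numpy(bool),
            h_PSD, h_neck, delta_s,
        )


@dataclass
class GeometryReport:
    """Discrete geometric measurements of a mesh.

    ``area_enclosed`` is the shoelace area Ω (μm²), ``boundary_length`` the
    perimeter S (μm), ``curvature`` the per-vertex signed curvature H
    (μm⁻¹), ``ds`` the per-vertex arc-length weight (μm) and
    ``edge_lengths`` the per-edge lengths (edge k joins vertices k, k+1).
    """

    area_enclosed: float
    boundary_length: float
    curvature: np.ndarray
    ds: np.ndarray
    edge_lengths: np.ndarray


def init_spine_mesh(params: ModelParams) -> MembraneMesh:
    """Build the initial spine mesh: a circle with PSD and neck plateaus.

    A circle of radius ``r_s`` centred at the origin is sampled at
    ``round(2π r_s / delta_s)`` equidistant vertices.  Vertices with
    ``y >= h_PSD`` are projected to ``y = h_PSD`` and fixed, those with
    ``y <= h_neck`` to ``y = h_neck``, where ``h_PSD = +sqrt(r_s² - r_PSD²)``
    and ``h_neck = -sqrt(r_s² - r_neck²)``.
    """
    if params.r_PSD >= params.r_s or params.r_neck >= params.r_s:
        raise ConfigurationError("r_PSD and r_neck must be smaller than r_s")
    r = params.r_s
    h_psd = math.sqrt(r * r - params.r_PSD ** 2)
    h_neck = -math.sqrt(r * r - params.r_neck ** 2)

    n = int(round(2.0 * math.pi * r / params.delta_s))
    theta = 2.0 * math.pi * np.arange(n) / n
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    fixed = np.zeros(n, dtype=bool)
    top = pos[:, 1] >= h_psd
    pos[top, 1] = h_psd
    fixed |= top
    bottom = pos[:, 1] <= h_neck
    pos[bottom, 1] = h_neck
    fixed |= bottom
    return MembraneMesh(pos, fixed, h_psd, h_neck, params.delta_s)


def compute_geometry(mesh: MembraneMesh) -> GeometryReport:
    """Measure area, boundary length, curvature and arc-length weights."""
    pos = mesh.positions
    if len(pos) < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    nxt = np.roll(pos, -1, axis=0)
    prv = np.roll(pos, 1, axis=0)

    e2 = nxt - pos                      # edge k -> k+1
    e1 = pos - prv                      # edge k-1 -> k
    e3 = nxt - prv
    L2 = np.hypot(e2[:, 0], e2[:, 1])   # length of edge (k, k+1)
    L1 = np.hypot(e1[:, 0], e1[:, 1])
    L3 = np.hypot(e3[:, 0], e3[:, 1])
    if np.any(L2 == 0.0):
        raise GeometryError("duplicate consecutive vertices")

    area = 0.5 * float(np.sum(pos[:, 0] * nxt[:, 1] - nxt[:, 0] * pos[:, 1]))
    boundary = float(L2.sum())

    # circumradius curvature of (k-1, k, k+1): H = 4 * signed triangle area
    # / (product of side lengths); collinear triples give H = 0.
    cross = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    den = L1 * L2 * L3
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(den > 0.0, 2.0 * cross / den, 0.0)

    ds = 0.5 * (L1 + L2)
    return GeometryReport(area, boundary, H, ds, L2)


def remesh(mesh: MembraneMesh, params: ModelParams) -> MembraneMesh:
    """Restore edge lengths to ``[d_min, d_max]`` by splits and collapses.

    Splits run first and are repeated, then collapses, until no rule fires.
    A too-short edge loses its free endpoint (the second one in cyclic order
    if both are free); edges between two fixed vertices are exempt from
    collapsing.  Returns a new mesh; the input is left untouched.
    """
    d_min, d_max = params.d_min, params.d_max

    # fast path: nothing to do (the common case during simulation)
    edges = np.linalg.norm(np.roll(mesh.positions, -1, axis=0) - mesh.positions,
                           axis=1)
    both_fixed = mesh.fixed & np.roll(mesh.fixed, -1)
    if not (np.any(edges > d_max)
            or np.any((edges < d_min) & ~both_fixed)):
        return mesh

    pos = mesh.positions.astype(float, copy=True)
    fix = mesh.fixed.astype(bool, copy=True)

    max_rounds = 100 * len(pos) + 1000
    rounds = 0
    while True:
        rounds += 1
        if rounds > max_rounds:
            raise GeometryError("remeshing did not terminate")

        nxt = np.roll(pos, -1, axis=0)
        lengths = np.hypot(*(nxt - pos).T)

        # split pass: insert midpoints on all over-long edges
        long_edges = np.flatnonzero(lengths > d_max)
        if len(long_edges):
            fix_next = np.roll(fix, -1)
            mids = 0.5 * (pos[long_edges] + nxt[long_edges])
            mid_fix = fix[long_edges] & fix_next[long_edges]
            # insert after vertex k of each long edge (k, k+1)
            pos = np.insert(pos, long_edges + 1, mids, axis=0)
            fix = np.insert(fix, long_edges + 1, mid_fix)
            continue

        # collapse pass: remove one endpoint of the first under-short edge
        # whose endpoints are not both fixed (those are exempt)
        fix_next = np.roll(fix, -1)
        short = np.flatnonzero((lengths < d_min) & ~(fix & fix_next))
        if len(short) == 0:
            break
        k = int(short[0])
        nk = (k + 1) % len(pos)
        drop = nk if not fix[nk] else k
        if len(pos) - 1 < 3:
            raise GeometryError("remeshing would reduce polygon below 3 vertices")
        pos = np.delete(pos, drop, axis=0)
        fix = np.delete(fix, drop)

    return MembraneMesh(pos, fix, mesh.h_PSD, mesh.h_neck, mesh.delta_s)



def excise_self_intersections(mesh: MembraneMesh) -> MembraneMesh:
    """Untangle a self-intersecting polygon by 2-opt uncrossing.

    The membrane model carries no self-contact force, so colliding
    membrane walls — the flanks of a retracting protrusion, or the two
    sides of a narrowing crevice being zipped shut by line tension — can
    cross; the inverted lens between the crossing edges would then grow
    without bound because negative signed area is rewarded by the
    pressure term.  Called every tick, this guard resolves each crossing
    while the lens is still microscopic by reversing the vertex subchain
    between the two crossing edges (the classic 2-opt move).  That
    reconnects the membrane through the contact point — a local fusion —
    while preserving every vertex position and fixed flag bitwise; each
    reversal strictly increases the enclosed signed area, so the
    iteration terminates.  Returns the input mesh unchanged when the
    polygon is already simple.
    """
    import shapely

    if shapely.Polygon(mesh.positions).is_valid:
        return mesh
    pos = mesh.positions.copy()
    fix = mesh.fixed.copy()
    untangled = False
    for _ in range(200):
        crossings = _all_crossings(pos)
        if not crossings:
            untangled = True
            break
        # most local pair first: the smallest lens is the actual contact
        n = len(pos)
        crossings.sort(key=lambda c: min(c[1] - c[0], n - (c[1] - c[0])))
        i, j, _ = crossings[0]
        pos[i + 1:j + 1] = pos[i + 1:j + 1][::-1]
        fix[i + 1:j + 1] = fix[i + 1:j + 1][::-1]
        # reversing either subchain uncrosses the pair but they yield
        # opposite global orientations; keep the counterclockwise one
        nxt = np.roll(pos, -1, axis=0)
        if np.sum(pos[:, 0] * nxt[:, 1] - nxt[:, 0] * pos[:, 1]) < 0.0:
            pos = pos[::-1].copy()
            fix = fix[::-1].copy()
    if not untangled:
        raise GeometryError("self-intersection repair did not converge")
    # a degenerate touch (vertex exactly on an edge) has no proper
    # crossing; it is measure-zero and harmless, so it is left alone
    return MembraneMesh(pos, fix, mesh.h_PSD, mesh.h_neck, mesh.delta_s)


def _all_crossings(pos: np.ndarray):
    """All properly crossing non-adjacent edge pairs, with their points."""
    n = len(pos)
    p1 = pos
    p2 = np.roll(pos, -1, axis=0)
    d = p2 - p1
    out = []
    for i in range(n - 2):
        # vectorized proper-intersection test of edge i against edges j > i+1
        js = np.arange(i + 2, n if i > 0 else n - 1)
        if len(js) == 0:
            continue
        q1, q2 = p1[js], p2[js]
        r = d[i]
        s = q2 - q1
        denom = r[0] * s[:, 1] - r[1] * s[:, 0]
        diff = q1 - p1[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (diff[:, 0] * s[:, 1] - diff[:, 1] * s[:, 0]) / denom
            u = (diff[:, 0] * r[1] - diff[:, 1] * r[0]) / denom
        hit = (denom != 0) & (t > 0) & (t < 1) & (u > 0) & (u < 1)
        for k in np.flatnonzero(hit):
            out.append((i, int(js[k]), p1[i] + t[k] * r))
    return out


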