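"""Spherocylinder cell shapes and their 1D finite-volume discretization.

The cell is a cylinder of radius 0.5 um with hemispherical end caps.  The
axial radius profile r(x) fully describes the (axisymmetric) shape; a septal
constriction replaces the midcell wall with two concave circular arcs joined
by a small convex arc, with the midcell radius as the controlled quantity.

The discretization slices the cell into axial finite volumes.  Per cell we
keep the cytoplasmic volume, the lateral membrane area and the arc-length
metric; membrane diffusion acts along the arc length s(x) of the profile,
cytosolic diffusion along x weighted by the local cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "Constriction",
    "CellGeometry",
    "ConstrictionSchedule",
    "AxialGrid",
    "radius_profile",
    "constriction_metrics",
    "discretize",
    "grow",
    "with_constriction_radius",
]

#: Sub-samples per finite-volume cell used for the quadrature of volumes,
#: areas and arc lengths.
_QUAD_SUBDIV = 16


@dataclass(frozen=True)
class Constriction:
    """Septum descriptor: current minimum radius and the arc shape constants.

    The pinch profile is built from two circular arcs, concave with respect
    to the cytoplasm (radius ``concave_radius``), tangent to the cylinder
    wall and to a central convex arc (radius ``convex_radius``) whose lowest
    point is the septum radius ``r_min``.
    """

    r_min: float
    concave_radius: float = 0.5
    convex_radius: float = 0.1

    def half_width(self, radius: float) -> float:
        """Axial half-extent of the pinch region for a cell of given radius."""
        rc, rv = self.concave_radius, self.convex_radius
        h2 = (rc + rv) ** 2 - (self.r_min + rv - radius + rc) ** 2
        return float(np.sqrt(max(h2, 0.0)))


@dataclass(frozen=True)
class CellGeometry:
    """Rod-shaped cell: total pole-to-pole length, radius, optional septum."""

    length: float
    radius: float = 0.5
    constriction: Optional[Constriction] = None

    def __post_init__(self) -> None:
        if self.length < 2.0 * self.radius:
            raise ValueError(
                f"length {self.length} shorter than two cap radii ({2 * self.radius})"
            )
        c = self.constriction
        if c is not None:
            if not (0 < c.r_min <= self.radius):
                raise ValueError(f"constriction radius {c.r_min} outside (0, {self.radius}]")
            if self.length / 2.0 < self.radius + c.half_width(self.radius):
                raise ValueError("constriction overlaps the polar caps")

    @property
    def cylinder_length(self) -> float:
        return self.length - 2.0 * self.radius

    def analytic_volume(self) -> float:
        """Closed-form volume of the *unconstricted* spherocylinder (um^3)."""
        r = self.radius
        return float(np.pi * r * r * self.cylinder_length + 4.0 / 3.0 * np.pi * r**3)

    def analytic_area(self) -> float:
        """Closed-form surface area of the unconstricted spherocylinder (um^2)."""
        r = self.radius
        return float(2.0 * np.pi * r * self.cylinder_length + 4.0 * np.pi * r * r)


@dataclass(frozen=True)
class ConstrictionSchedule:
    """Linear septum closure: radius ramps from the cell radius down to
    ``r_min_final`` over ``ramp_duration`` starting at ``t_start``, then the
    shape is held for the rest of the run."""

    t_start: float = 300.0
    ramp_duration: float = 432.0
    hold: bool = True
    r_min_final: float = 0.077
    concave_radius: float = 0.5
    convex_radius: float = 0.1

    @property
    def t_end(self) -> float:
        return self.t_start + self.ramp_duration

    def radius_at(self, t: float, cell_radius: float = 0.5) -> float:
        """Septum radius at time ``t`` (um)."""
        if t <= self.t_start:
            return cell_radius
        if t >= self.t_end:
            return self.r_min_final if self.hold else self.r_min_final
        frac = (t - self.t_start) / self.ramp_duration
        return cell_radius + frac * (self.r_min_final - cell_radius)

    def constriction_at(self, t: float, cell_radius: float = 0.5) -> Optional[Constriction]:
        r = self.radius_at(t, cell_radius)
        if r >= cell_radius:
            return None
        return Constriction(r_min=r, concave_radius=self.concave_radius,
                            convex_radius=self.convex_radius)


def radius_profile(g: CellGeometry, x: float | np.ndarray) -> float | np.ndarray:
    """Local cell radius at axial position(s) ``x`` in [0, length]."""
    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr)
    if np.any((x_arr < -1e-12) | (x_arr > g.length + 1e-12)):
        raise ValueError("axial position outside the cell")
    x_arr = np.clip(x_arr, 0.0, g.length)
    R, L = g.radius, g.length

    # unconstricted base: hemispherical caps joined by a cylinder
    r = np.full_like(x_arr, R)
    left = x_arr < R
    r[left] = np.sqrt(np.maximum(R * R - (R - x_arr[left]) ** 2, 0.0))
    right = x_arr > L - R
    r[right] = np.sqrt(np.maximum(R * R - (x_arr[right] - (L - R)) ** 2, 0.0))

    c = g.constriction
    if c is not None and c.r_min < R:
        rc, rv = c.concave_radius, c.convex_radius
        half_w = c.half_width(R)
        u = np.abs(x_arr - L / 2.0)
        # tangency point between the concave and convex arcs, measured from midcell
        u_t = half_w * rv / (rc + rv)
        in_convex = u <= u_t
        in_concave = (u > u_t) & (u <= half_w)
        r[in_convex] = (c.r_min + rv) - np.sqrt(
            np.maximum(rv * rv - u[in_convex] ** 2, 0.0)
        )
        r[in_concave] = (R - rc) + np.sqrt(
            np.maximum(rc * rc - (half_w - u[in_concave]) ** 2, 0.0)
        )
    return float(r[0]) if scalar else r


def constriction_metrics(g: CellGeometry) -> tuple[float, float]:
    """Septum-to-cylinder radius ratio and cross-sectional area ratio, in %."""
    if g.constriction is None:
        raise ValueError("geometry has no constriction")
    ratio = g.constriction.r_min / g.radius
    return 100.0 * ratio, 100.0 * ratio * ratio


@dataclass(frozen=True)
class AxialGrid:
    """Finite-volume discretization of a cell along its major axis.

    ``cell_volume`` integrates pi r^2 dx per cell; ``membrane_area`` is the
    lateral surface of revolution per cell; ``arc_metric`` is the mean
    ds/dx over each cell; ``perimeter_to_area`` (um^-1) converts areal
    fluxes (um^-2 s^-1) into volumetric rates (um^-3 s^-1).

    ``face_conductance_cyt``/``face_conductance_mem`` are the geometric
    parts of the diffusive conductance at the n-1 interior faces (multiply
    by a diffusion coefficient to get amount flow per concentration
    difference).  They are series resistances integrated between adjacent
    cell centres -- 1 / int dx/(pi r^2) through the bulk and
    1 / int ds/(2 pi r) along the membrane -- which is exact for steady
    flux through a varying cross-section and in particular captures the
    funnel resistance of a septal constriction.  ``s_centers`` are
    arc-length coordinates of the cell centres; ``r_edges`` the profile
    radius at the interior faces.
    """

    geometry: CellGeometry
    x_edges: np.ndarray
    x_centers: np.ndarray
    cell_volume: np.ndarray
    membrane_area: np.ndarray
    arc_metric: np.ndarray
    perimeter_to_area: np.ndarray
    r_edges: np.ndarray
    s_centers: np.ndarray
    face_conductance_cyt: np.ndarray
    face_conductance_mem: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.x_centers)

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.x_edges)

    @property
    def total_volume(self) -> float:
        return float(self.cell_volume.sum())

    @property
    def total_area(self) -> float:
        return float(self.membrane_area.sum())

    def cylinder_mask(self) -> np.ndarray:
        """Cells whose centre lies in the cylindrical section (pinch included)."""
        g = self.geometry
        return (self.x_centers >= g.radius) & (self.x_centers <= g.length - g.radius)

    def to_frame(self):
        """Geometry snapshot as a pandas DataFrame (x, r, volume, area)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "x": self.x_centers,
                "r": radius_profile(self.geometry, self.x_centers),
                "volume": self.cell_volume,
                "area": self.membrane_area,
            }
        )


def _metrics_from_edges(g: CellGeometry, x_edges: np.ndarray) -> AxialGrid:
    """Build the finite-volume metrics for the given cell-face positions."""
    n = len(x_edges) - 1
    m = _QUAD_SUBDIV
    # dense sampling: m sub-intervals per cell
    frac = np.linspace(0.0, 1.0, m + 1)
    xs = x_edges[:-1, None] + np.diff(x_edges)[:, None] * frac[None, :]  # (n, m+1)
    rs = radius_profile(g, xs.ravel()).reshape(n, m + 1)

    # volume: Simpson on pi r^2 (m is even)
    w = np.ones(m + 1)
    w[1:-1:2], w[2:-1:2] = 4.0, 2.0
    h = np.diff(x_edges) / m
    vol = np.pi * (rs**2 * w).sum(axis=1) * h / 3.0

    # membrane area and arc length: polyline quadrature
    dr = np.diff(rs, axis=1)
    dl = np.sqrt(h[:, None] ** 2 + dr**2)
    area = 2.0 * np.pi * ((rs[:, :-1] + rs[:, 1:]) / 2.0 * dl).sum(axis=1)
    arclen = dl.sum(axis=1)

    if np.any(vol <= 0) or np.any(area <= 0):
        raise ValueError("degenerate (zero-volume) cell in discretization")

    x_centers = 0.5 * (x_edges[:-1] + x_edges[1:])
    s_edges = np.concatenate([[0.0], np.cumsum(arclen)])
    s_centers = 0.5 * (s_edges[:-1] + s_edges[1:])

    # face conductances: series resistance between adjacent cell centres.
    # trapezoid on the half-cells either side of each interior face; the
    # apex singularity of 1/r^2 is never touched because the integrals stop
    # at the outermost cell centres.
    half = m // 2
    with np.errstate(divide="ignore"):
        # r = 0 exactly at the pole apices; the resulting infinities sit in
        # the outermost half-cell integrals, which are discarded below.
        inv_a = 1.0 / (np.pi * rs**2)                    # bulk resistivity per dx
    r_bulk_right = np.trapezoid(inv_a[:, half:], dx=h[:, None], axis=1)
    r_bulk_left = np.trapezoid(inv_a[:, : half + 1], dx=h[:, None], axis=1)
    res_cyt = r_bulk_right[:-1] + r_bulk_left[1:]
    # membrane: resistance element ds / (2 pi r) on each sub-interval
    seg_res = dl / (np.pi * (rs[:, :-1] + rs[:, 1:]))
    res_mem = seg_res[:, half:].sum(axis=1)[:-1] + seg_res[:, :half].sum(axis=1)[1:]
    return AxialGrid(
        geometry=g,
        x_edges=np.asarray(x_edges, dtype=float),
        x_centers=x_centers,
        cell_volume=vol,
        membrane_area=area,
        arc_metric=arclen / np.diff(x_edges),
        perimeter_to_area=area / vol,
        r_edges=np.asarray(radius_profile(g, x_edges[1:-1]), dtype=float),
        s_centers=s_centers,
        face_conductance_cyt=1.0 / res_cyt,
        face_conductance_mem=1.0 / res_mem,
    )


def discretize(g: CellGeometry, n_cells: int) -> AxialGrid:
    """Slice the cell into ``n_cells`` uniform axial finite volumes."""
    if n_cells < 20:
        raise ValueError("need at least 20 axial cells")
    x_edges = np.linspace(0.0, g.length, n_cells + 1)
    return _metrics_from_edges(g, x_edges)


def with_constriction_radius(grid: AxialGrid, r_min: float,
                             concave_radius: float = 0.5,
                             convex_radius: float = 0.1) -> AxialGrid:
    """Same axial faces, new septum radius; metrics are recomputed."""
    g = grid.geometry
    c = None if r_min >= g.radius else Constriction(r_min, concave_radius, convex_radius)
    g2 = replace(g, constriction=c)
    return _metrics_from_edges(g2, grid.x_edges)


def grow(grid: AxialGrid, g: CellGeometry, dt: float, growth_rate: float) -> tuple[CellGeometry, AxialGrid]:
    """Stretch the cylindrical section by ``growth_rate * dt``.

    Cap cells keep their distance from the nearest pole; cylinder-section
    faces are stretched affinely.  Species concentrations are left untouched
    by the caller, so stretching alone inflates totals -- the solver's
    dilution term compensates.
    """
    if growth_rate < 0:
        raise ValueError("growth_rate must be >= 0")
    dL = growth_rate * dt
    if dL == 0:
        return g, grid
    L_old, R = g.length, g.radius
    g2 = replace(g, length=L_old + dL)
    x = grid.x_edges
    x_new = x.copy()
    cap_hi = x > L_old - R
    cyl = (x >= R) & (x <= L_old - R)
    x_new[cap_hi] = x[cap_hi] + dL
    stretch = (g2.cylinder_length) / max(g.cylinder_length, 1e-300)
    x_new[cyl] = R + (x[cyl] - R) * stretch
    return g2, _metrics_from_edges(g2, x_new)
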