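"""Time integration of the six-field Min system on the axial grid.

Method of lines: the reaction terms of :mod:`minosc.model_core` are evaluated
pointwise per finite-volume cell; diffusion is a conservative two-point flux
scheme (cytosolic species through the local cross-section, membrane species
along the arc length of the profile with per-species scaling 1, 1/2, 1/2,
1/4 of D_m); membrane-cytosol exchange is converted between areal and
volumetric rates by each cell's perimeter-to-area ratio.  No-flux boundaries
at both poles.

The resulting stiff ODE system is advanced with LSODA and a banded Jacobian
(species interleaved per cell, bandwidth 6).  Mass totals are linear
invariants of the semi-discrete system and are preserved by the integrator
to round-off when growth and production are switched off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from . import model_core as mc
from . import geometry as geo

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "IntegrationError",
    "initial_state",
    "step",
    "run_fixed_length",
    "run_growing",
    "run_division",
]

N_SPECIES = 6
_CYTOSOLIC = (0, 1)  # columns D, E2


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails or produces non-finite fields."""


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings for a simulation run.

    ``dx`` is the target axial cell size (um); ``n_cells`` overrides it when
    set.  ``burn_in`` seconds are integrated before recording starts (the
    initial near-homogeneous state needs that long to converge onto its
    attractor).  ``initial_tilt`` is the relative amplitude of the
    deterministic linear perturbation that breaks the pole symmetry.
    """

    dx: float = 0.05
    n_cells: Optional[int] = None
    burn_in: float = 1000.0
    duration: float = 1000.0
    growth_rate: float = 0.0
    production: bool = False
    initial_tilt: float = 1e-3
    record_interval: float = 2.0
    rtol: float = 1e-6
    atol: float = 1e-6
    geometry_update_interval: float = 2.0
    production_tau: float = 1.0

    def resolve_n_cells(self, length: float) -> int:
        if self.n_cells is not None:
            return self.n_cells
        return max(20, int(round(length / self.dx)))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Trajectory:
    """Recorded run: times, per-species fields and geometry at each record.

    ``fields`` has shape (n_times, n_cells, 6) in the species order
    ``("D", "E2", "d", "d2", "e2", "d2e2")``; cytosolic entries are per um^3,
    membrane entries per um^2.
    """

    times: np.ndarray
    x_edges: np.ndarray          # (nt, n+1)
    x_centers: np.ndarray        # (nt, n)
    cell_volume: np.ndarray      # (nt, n)
    membrane_area: np.ndarray    # (nt, n)
    fields: np.ndarray           # (nt, n, 6)
    length: np.ndarray           # (nt,)
    septum_radius: np.ndarray    # (nt,)
    params: mc.RateParameters
    totals: mc.ConcentrationTotals
    config: SimulationConfig
    clipped: float = 0.0         # total |amount| clipped to zero at records

    @property
    def n_times(self) -> int:
        return len(self.times)

    def minD_equivalents(self) -> np.ndarray:
        """MinD monomer-equivalent amount per cell, shape (nt, n)."""
        f, V, A = self.fields, self.cell_volume, self.membrane_area
        return V * f[..., 0] + A * (f[..., 2] + 2.0 * f[..., 3] + 2.0 * f[..., 5])

    def minE_equivalents(self) -> np.ndarray:
        """MinE dimer-equivalent amount per cell, shape (nt, n)."""
        f, V, A = self.fields, self.cell_volume, self.membrane_area
        return V * f[..., 1] + A * (f[..., 4] + f[..., 5])

    def total_minD(self) -> np.ndarray:
        return self.minD_equivalents().sum(axis=1)

    def total_minE(self) -> np.ndarray:
        return self.minE_equivalents().sum(axis=1)

    def save(self, path) -> None:
        """Persist as an HDF5 container plus JSON metadata attribute."""
        import h5py

        meta = {
            "params": self.params.to_dict(),
            "totals": asdict(self.totals),
            "config": self.config.to_dict(),
            "species": list(mc.SPECIES),
        }
        with h5py.File(path, "w") as f:
            for name in ("times", "x_edges", "x_centers", "cell_volume",
                         "membrane_area", "fields", "length", "septum_radius"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["metadata"] = json.dumps(meta)
            f.attrs["clipped"] = self.clipped

    @classmethod
    def load(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["metadata"])
            kw = {name: f[name][...] for name in
                  ("times", "x_edges", "x_centers", "cell_volume",
                   "membrane_area", "fields", "length", "septum_radius")}
            clipped = float(f.attrs.get("clipped", 0.0))
        return cls(params=mc.RateParameters(**meta["params"]),
                   totals=mc.ConcentrationTotals(**meta["totals"]),
                   config=SimulationConfig(**meta["config"]),
                   clipped=clipped, **kw)


# ---------------------------------------------------------------------------
# right-hand side


class _RHS:
    """Semi-discrete right-hand side on a fixed grid.

    Precomputes diffusive edge conductances and capacity vectors so a call
    is a handful of vector operations.
    """

    def __init__(self, grid: geo.AxialGrid, p: mc.RateParameters,
                 totals: Optional[mc.ConcentrationTotals] = None,
                 growth_rate: float = 0.0, production: bool = False,
                 production_tau: float = 1.0):
        self.grid = grid
        self.p = p
        n = grid.n_cells
        self.n = n
        V, A = grid.cell_volume, grid.membrane_area
        self.V, self.A = V, A
        self.p2a = grid.perimeter_to_area

        g_cyt = grid.face_conductance_cyt
        g_mem = grid.face_conductance_mem
        diff = (p.D_D, p.D_E, p.D_m, 0.5 * p.D_m, 0.5 * p.D_m, 0.25 * p.D_m)
        self.G = [diff[k] * (g_cyt if k in _CYTOSOLIC else g_mem)
                  for k in range(N_SPECIES)]
        self.inv_cap = [1.0 / (V if k in _CYTOSOLIC else A) for k in range(N_SPECIES)]

        self.growth_rate = growth_rate
        if growth_rate > 0:
            cyl_len = grid.geometry.cylinder_length
            if cyl_len <= 0:
                raise ValueError("cannot grow a cell with no cylindrical section")
            self.dilution_rate = growth_rate / cyl_len
            self.cyl_mask = grid.cylinder_mask()
        self.production = production
        if production:
            if totals is None:
                raise ValueError("production requires concentration totals")
            self.totals = totals
            self.Vtot = float(V.sum())
            self.tau = production_tau

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.p
        c = y.reshape(self.n, N_SPECIES)
        D, E2 = c[:, 0], c[:, 1]
        d, d2, e2, d2e2 = c[:, 2], c[:, 3], c[:, 4], c[:, 5]

        dim = p.omega_dim * d * d
        strip = p.omega_edf * e2 * d
        tet = p.omega_edf * e2 * d2
        hyd = p.omega_hydr * d2e2
        bindD = p.omega_db * D
        bindE = p.omega_eb * E2
        relE = p.omega_er * e2

        out = np.empty_like(c)
        out[:, 0] = self.p2a * (strip + 2.0 * hyd - bindD)
        out[:, 1] = self.p2a * (relE - bindE)
        out[:, 2] = bindD - 2.0 * dim - strip
        out[:, 3] = dim - tet
        out[:, 4] = bindE - relE - tet + hyd
        out[:, 5] = tet - hyd

        for k in range(N_SPECIES):
            ck = c[:, k]
            F = self.G[k] * (ck[1:] - ck[:-1])  # amount flow into the left cell
            ic = self.inv_cap[k]
            out[:-1, k] += F * ic[:-1]
            out[1:, k] -= F * ic[1:]

        if self.growth_rate > 0:
            out[self.cyl_mask, :] -= self.dilution_rate * c[self.cyl_mask, :]
        if self.production:
            nD = self.V @ D + self.A @ (d + 2.0 * d2 + 2.0 * d2e2)
            nE = self.V @ E2 + self.A @ (e2 + d2e2)
            out[:, 0] += (self.totals.minD_total * self.Vtot - nD) / (self.Vtot * self.tau)
            out[:, 1] += (self.totals.minE_dimer_total * self.Vtot - nE) / (self.Vtot * self.tau)
        return out.ravel()


def _integrate(rhs: _RHS, y0: np.ndarray, t0: float, t1: float,
               cfg: SimulationConfig, t_eval=None) -> np.ndarray:
    """Advance from t0 to t1; returns states at ``t_eval`` (or only at t1)."""
    if t_eval is None:
        t_eval = [t1]
    sol = solve_ivp(rhs, (t0, t1), y0, method="LSODA",
                    lband=N_SPECIES, uband=N_SPECIES,
                    rtol=cfg.rtol, atol=cfg.atol, t_eval=np.asarray(t_eval))
    if not sol.success:
        raise IntegrationError(f"LSODA failed on [{t0}, {t1}]: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"non-finite fields produced on [{t0}, {t1}]")
    return sol.y.T  # (n_eval, n*6)


def _clip_small_negatives(y: np.ndarray, scale: float, where: str) -> tuple[np.ndarray, float]:
    """Zero out integrator-noise negatives; fail on structural ones."""
    floor = -1e-4 * scale
    if y.min() < floor:
        raise IntegrationError(
            f"negative concentration overshoot beyond tolerance ({y.min():.3g}) {where}"
        )
    clipped = float(-y[y < 0].sum())
    return np.maximum(y, 0.0), clipped


# ---------------------------------------------------------------------------
# runs


def initial_state(grid: geo.AxialGrid, totals: mc.ConcentrationTotals,
                  tilt: float = 1e-3) -> np.ndarray:
    """Homogeneous cytosolic start: all MinD in ``D``, all MinE in ``E2``.

    A deterministic linear tilt of relative amplitude ``tilt`` is applied to
    ``D`` along the axis (zero volume-weighted mean shift on the symmetric
    grid) so that the mirror symmetry of the equations is broken
    reproducibly rather than by round-off noise.
    """
    n = grid.n_cells
    y = np.zeros((n, N_SPECIES))
    L = grid.geometry.length
    ramp = (grid.x_centers - L / 2.0) / (L / 2.0)
    y[:, 0] = totals.minD_total * (1.0 + tilt * ramp)
    y[:, 1] = totals.minE_dimer_total
    return y


def step(state: np.ndarray, grid: geo.AxialGrid, p: mc.RateParameters,
         dt: float, cfg: SimulationConfig = SimulationConfig()) -> np.ndarray:
    """Advance a state array (n, 6) by ``dt`` on a fixed grid."""
    rhs = _RHS(grid, p)
    y = _integrate(rhs, np.asarray(state, float).ravel(), 0.0, dt, cfg)[-1]
    return y.reshape(grid.n_cells, N_SPECIES)


class _Recorder:
    def __init__(self):
        self.t, self.fields, self.grids = [], [], []
        self.clipped = 0.0

    def add(self, t, y, grid, scale):
        arr = y.reshape(-1, N_SPECIES).copy()
        floor = -1e-4 * scale
        if arr.min() < floor:
            raise IntegrationError(
                f"negative concentration overshoot ({arr.min():.3g}) at t={t}"
            )
        self.clipped += float(-arr[arr < 0].sum())
        np.maximum(arr, 0.0, out=arr)
        self.t.append(float(t))
        self.fields.append(arr)
        self.grids.append(grid)

    def to_trajectory(self, p, totals, cfg) -> Trajectory:
        nt = len(self.t)
        n = self.fields[0].shape[0]
        traj = Trajectory(
            times=np.asarray(self.t),
            x_edges=np.stack([g.x_edges for g in self.grids]),
            x_centers=np.stack([g.x_centers for g in self.grids]),
            cell_volume=np.stack([g.cell_volume for g in self.grids]),
            membrane_area=np.stack([g.membrane_area for g in self.grids]),
            fields=np.stack(self.fields),
            length=np.asarray([g.geometry.length for g in self.grids]),
            septum_radius=np.asarray(
                [g.geometry.constriction.r_min if g.geometry.constriction else g.geometry.radius
                 for g in self.grids]),
            params=p, totals=totals, config=cfg, clipped=self.clipped,
        )
        assert traj.fields.shape == (nt, n, N_SPECIES)
        return traj


def run_fixed_length(L: float, p: mc.RateParameters, cfg: SimulationConfig,
                     totals: mc.ConcentrationTotals = mc.ConcentrationTotals(),
                     ) -> Trajectory:
    """Burn in, then record a run in a cell of fixed length ``L`` (um)."""
    if L < 1.0:
        raise ValueError("cell length must be at least 1 um")
    g = geo.CellGeometry(L)
    grid = geo.discretize(g, cfg.resolve_n_cells(L))
    y0 = initial_state(grid, totals, cfg.initial_tilt).ravel()
    rhs = _RHS(grid, p)
    t_rec = cfg.burn_in + np.arange(0.0, cfg.duration + 0.5 * cfg.record_interval,
                                    cfg.record_interval)
    ys = _integrate(rhs, y0, 0.0, float(t_rec[-1]), cfg, t_eval=t_rec)
    rec = _Recorder()
    scale = totals.minD_total
    for t, y in zip(t_rec, ys):
        rec.add(t, y, grid, scale)
    return rec.to_trajectory(p, totals, cfg)


def run_growing(L0: float, L1: float, growth_rate: float, p: mc.RateParameters,
                cfg: SimulationConfig,
                totals: mc.ConcentrationTotals = mc.ConcentrationTotals(),
                ) -> Trajectory:
    """Grow the cylindrical section linearly from ``L0`` to ``L1``.

    Each geometry-update interval the PDEs are advanced on a frozen grid with
    the growth dilution sink (rate * concentration / cylinder length, cylinder
    cells only) and homogeneous cytosolic production that relaxes the
    cell-average MinD and MinE concentrations back to their targets; the grid
    is then stretched with concentrations carried unchanged.
    """
    if growth_rate <= 0:
        raise ValueError("growth_rate must be positive for a growing run")
    if L1 <= L0:
        raise ValueError("L1 must exceed L0")
    g = geo.CellGeometry(L0)
    grid = geo.discretize(g, cfg.resolve_n_cells(L1))
    y = initial_state(grid, totals, cfg.initial_tilt).ravel()
    # burn-in without growth
    if cfg.burn_in > 0:
        y = _integrate(_RHS(grid, p), y, 0.0, cfg.burn_in, cfg)[-1]
    scale = totals.minD_total
    y, cl = _clip_small_negatives(y, scale, "after burn-in")

    rec = _Recorder()
    rec.clipped += cl
    rec.add(0.0, y, grid, scale)
    t = 0.0
    dt_g = cfg.geometry_update_interval
    next_record = cfg.record_interval
    while g.length < L1 - 1e-9:
        dt_here = min(dt_g, (L1 - g.length) / growth_rate)
        rhs = _RHS(grid, p, totals=totals, growth_rate=growth_rate,
                   production=True, production_tau=cfg.production_tau)
        y = _integrate(rhs, y, t, t + dt_here, cfg)[-1]
        y, cl = _clip_small_negatives(y, scale, f"at t={t + dt_here:.1f}")
        rec.clipped += cl
        t += dt_here
        g, grid = geo.grow(grid, g, dt_here, growth_rate)
        if t >= next_record - 1e-9:
            rec.add(t, y, grid, scale)
            next_record += cfg.record_interval
    if rec.t[-1] < t - 1e-9:
        rec.add(t, y, grid, scale)
    return rec.to_trajectory(p, totals, cfg)


def run_division(L: float, p: mc.RateParameters,
                 schedule: geo.ConstrictionSchedule, cfg: SimulationConfig,
                 totals: mc.ConcentrationTotals = mc.ConcentrationTotals(),
                 ) -> Trajectory:
    """Constrict a fixed-length cell per the schedule and record throughout.

    The cell is not grown during division.  The septum radius is updated on
    the geometry-update interval; at each update the species amounts per cell
    are conserved exactly (concentrations are rescaled by the old/new volume
    or area), so protein totals pass through the constriction unchanged up
    to integrator tolerance.
    """
    g = geo.CellGeometry(L)
    n = cfg.resolve_n_cells(L)
    grid = geo.discretize(g, n)
    y = initial_state(grid, totals, cfg.initial_tilt).ravel()
    if cfg.burn_in > 0:
        y = _integrate(_RHS(grid, p), y, 0.0, cfg.burn_in, cfg)[-1]
    scale = totals.minD_total
    y, cl = _clip_small_negatives(y, scale, "after burn-in")

    rec = _Recorder()
    rec.clipped += cl
    rec.add(0.0, y, grid, scale)

    def record_span(y, grid, t0, t1):
        t_rec = np.arange(np.ceil((t0 + 1e-9) / cfg.record_interval) * cfg.record_interval,
                          t1 + 1e-9, cfg.record_interval)
        if len(t_rec) == 0 or t_rec[-1] < t1 - 1e-9:
            t_rec = np.append(t_rec, t1)
        ys = _integrate(_RHS(grid, p), y, t0, t1, cfg, t_eval=t_rec)
        for tt, yy in zip(t_rec, ys):
            rec.add(tt, yy, grid, scale)
        return ys[-1]

    duration = cfg.duration
    t_ramp_end = min(schedule.t_end, duration)
    # before constriction
    if schedule.t_start > 0:
        y = record_span(y, grid, 0.0, min(schedule.t_start, duration))
    # ramp: piecewise-frozen septum radius, conservative remap at updates
    t = schedule.t_start
    while t < t_ramp_end - 1e-9:
        dt_here = min(cfg.geometry_update_interval, t_ramp_end - t)
        r_mid = schedule.radius_at(t + 0.5 * dt_here, g.radius)
        new_grid = geo.with_constriction_radius(
            grid, max(r_mid, schedule.r_min_final),
            schedule.concave_radius, schedule.convex_radius)
        c = y.reshape(n, N_SPECIES)
        for k in range(N_SPECIES):
            cap_old = grid.cell_volume if k in _CYTOSOLIC else grid.membrane_area
            cap_new = new_grid.cell_volume if k in _CYTOSOLIC else new_grid.membrane_area
            c[:, k] *= cap_old / cap_new
        grid = new_grid
        y = _integrate(_RHS(grid, p), y, t, t + dt_here, cfg)[-1]
        y, cl = _clip_small_negatives(y, scale, f"at t={t + dt_here:.1f}")
        rec.clipped += cl
        t += dt_here
        rec.add(t, y, grid, scale)
    # hold at maximal constriction
    if duration > t_ramp_end:
        final_grid = geo.with_constriction_radius(
            grid, schedule.r_min_final, schedule.concave_radius, schedule.convex_radius)
        if final_grid is not grid:
            c = y.reshape(n, N_SPECIES)
            for k in range(N_SPECIES):
                cap_old = grid.cell_volume if k in _CYTOSOLIC else grid.membrane_area
                cap_new = final_grid.cell_volume if k in _CYTOSOLIC else final_grid.membrane_area
                c[:, k] *= cap_old / cap_new
            grid = final_grid
        y = record_span(y, grid, t_ramp_end, duration)
    return rec.to_trajectory(p, totals, cfg)
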