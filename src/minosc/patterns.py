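"""Kymograph construction and pattern quantification.

A trajectory is collapsed onto the cell's major axis: the signal is the
total-MinD linear density (cytosolic plus membrane-bound, in monomer
equivalents per um), the quantity a fluorescence kymograph of fully-labelled
MinD measures.  Classification distinguishes stationary patterns from first-
and second-order breather modes, mixed travelling waves, and the
midcell-antinode regime; the period is read off the dominant Fourier
component of the pole-region signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
from scipy.signal import find_peaks

from . import model_core as mc
from . import solver as sv

__all__ = [
    "Kymograph",
    "PatternReport",
    "PartitionSeries",
    "ClassifierThresholds",
    "CLASS_GROUPS",
    "collapse",
    "estimate_period",
    "classify",
    "find_transition",
    "midcell_node_check",
    "partition_metrics",
    "kymograph_to_csv",
    "render_kymograph",
]


@dataclass
class Kymograph:
    """Space x time map of the collapsed total-MinD signal.

    ``signal[t, i]`` is the MinD monomer-equivalent density per um of cell
    axis; its axial integral recovers the total MinD amount at each time.
    ``channels`` optionally holds per-species linear densities.
    """

    times: np.ndarray            # (nt,)
    x: np.ndarray                # (nt, n) absolute axial positions, um
    signal: np.ndarray           # (nt, n)
    length: np.ndarray           # (nt,)
    dx: np.ndarray               # (nt, n) cell widths, um
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def x_norm(self) -> np.ndarray:
        return self.x / self.length[:, None]

    def total(self) -> np.ndarray:
        """Axial integral of the signal at each time (monomer equivalents)."""
        return (self.signal * self.dx).sum(axis=1)

    def pole_signal(self, which: str = "auto", fraction: float = 0.1) -> np.ndarray:
        """Mean signal over the outer ``fraction`` of the axis at one pole."""
        n = self.signal.shape[1]
        m = max(1, int(round(fraction * n)))
        lo = self.signal[:, :m].mean(axis=1)
        hi = self.signal[:, -m:].mean(axis=1)
        if which == "low":
            return lo
        if which == "high":
            return hi
        return lo if lo.std() >= hi.std() else hi


@dataclass
class PatternReport:
    """Classification of a kymograph window.

    ``pattern`` is one of ``stationary``, ``first_order_breather``,
    ``second_order_breather``, ``mixed_travelling``, ``midcell_antinode``.
    ``period`` is in seconds (None for stationary patterns); node and
    antinode positions are axial coordinates of minimal/maximal temporal
    variation of the signal.
    """

    pattern: str
    period: Optional[float]
    node_positions: np.ndarray
    antinode_positions: np.ndarray
    oscillation_amplitude: float
    mode_powers: tuple[float, float]

    @property
    def oscillatory(self) -> bool:
        return self.pattern != "stationary"

    def to_json(self) -> str:
        d = asdict(self)
        d["node_positions"] = list(map(float, self.node_positions))
        d["antinode_positions"] = list(map(float, self.antinode_positions))
        d["mode_powers"] = list(map(float, self.mode_powers))
        return json.dumps(d, indent=2)


@dataclass
class PartitionSeries:
    """Per-time division of each protein across the septum plane (percent)."""

    times: np.ndarray
    frac_minD_top: np.ndarray
    frac_minE_top: np.ndarray
    rms_from_parity_minD: float
    rms_from_parity_minE: float
    rms_D_vs_E: float
    window: tuple[float, float]


@dataclass(frozen=True)
class ClassifierThresholds:
    """Operational thresholds behind the qualitative pattern taxonomy.

    ``stationary_cv``: maximum temporal coefficient of variation for a
    pattern to count as stationary.  ``midcell_window``: central fraction of
    the cell used for the midcell-antinode call.  ``mixing_factor``: maximum
    power ratio between the first two spatial modes for a travelling-wave
    (mixed) call.  ``analysis_fraction``: trailing fraction of the record
    used for analysis.  ``peak_detach_fraction``: minimum fraction of time
    the instantaneous high-MinD peak must spend inside the central window
    for the pattern to count as a midcell antinode;
    ``midcell_mode1_factor``: the midcell-antinode call also requires the
    first spatial mode to retain at least this fraction of the second-mode
    power (a pure second-order breather puts its antinode at midcell too,
    but has no first-mode content).
    """

    stationary_cv: float = 0.05
    midcell_window: float = 0.4
    mixing_factor: float = 2.0
    analysis_fraction: float = 0.6
    node_variance_ratio: float = 0.1
    peak_detach_fraction: float = 0.2
    midcell_mode1_factor: float = 0.5


def collapse(traj: sv.Trajectory, channels: bool = False) -> Kymograph:
    """Collapse a trajectory to the total-MinD linear density kymograph."""
    dx = np.diff(traj.x_edges, axis=1)
    f = traj.fields
    vol_lin = traj.cell_volume / dx     # cross-section area per um
    area_lin = traj.membrane_area / dx  # perimeter per um
    signal = vol_lin * f[..., 0] + area_lin * (
        f[..., 2] + 2.0 * f[..., 3] + 2.0 * f[..., 5])
    chan: dict[str, np.ndarray] = {}
    if channels:
        for k, name in enumerate(mc.SPECIES):
            lin = vol_lin if k < 2 else area_lin
            chan[name] = lin * f[..., k]
    return Kymograph(times=traj.times, x=traj.x_centers, signal=signal,
                     length=traj.length, dx=dx, channels=chan)


def _analysis_window(k: Kymograph, fraction: float) -> slice:
    nt = len(k.times)
    start = int(np.floor((1.0 - fraction) * nt))
    return slice(min(start, nt - 2), nt)


def estimate_period(k: Kymograph, window: Optional[tuple[float, float]] = None,
                    min_rel_amplitude: float = 0.01) -> Optional[float]:
    """Dominant Fourier period (s) of the pole-region signal, or None.

    The pole signal of a pole-to-pole oscillation completes one full cycle
    per double switch, so its fundamental *is* the oscillation period.  The
    spectral peak is refined by parabolic interpolation; a signal whose
    relative temporal variation is below ``min_rel_amplitude`` is treated
    as stationary and yields None.
    """
    mask = np.ones(len(k.times), bool)
    if window is not None:
        mask = (k.times >= window[0]) & (k.times <= window[1])
    t = k.times[mask]
    if len(t) < 8:
        raise ValueError("period window too short")
    s = k.pole_signal()[mask]
    mean = s.mean()
    if mean <= 0 or s.std() < min_rel_amplitude * mean:
        return None
    dt = np.median(np.diff(t))
    a = (s - mean) * np.hanning(len(s))
    power = np.abs(np.fft.rfft(a)) ** 2
    if len(power) < 3:
        return None
    peak = int(np.argmax(power[1:])) + 1
    # parabolic refinement on log power
    if 1 <= peak < len(power) - 1 and power[peak - 1] > 0 and power[peak + 1] > 0:
        lp = np.log(power[peak - 1: peak + 2])
        denom = lp[0] - 2.0 * lp[1] + lp[2]
        shift = 0.5 * (lp[0] - lp[2]) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    freq = (peak + shift) / (len(s) * dt)
    if freq <= 0:
        return None
    return float(1.0 / freq)


def _mode_coefficients(k: Kymograph, win: slice) -> tuple[np.ndarray, np.ndarray]:
    """Time series of the first two spatial cosine-mode amplitudes."""
    s = k.signal[win]
    x = k.x[win][-1]
    dx = k.dx[win][-1]
    L = float(k.length[win][-1])
    a = s - s.mean(axis=0, keepdims=True)
    c1 = (a * np.cos(np.pi * x / L) * dx).sum(axis=1) / L
    c2 = (a * np.cos(2.0 * np.pi * x / L) * dx).sum(axis=1) / L
    return c1, c2


def classify(k: Kymograph, thresholds: ClassifierThresholds = ClassifierThresholds()
             ) -> PatternReport:
    """Assign a pattern class to a fixed-length kymograph window."""
    th = thresholds
    win = _analysis_window(k, th.analysis_fraction)
    if win.stop - win.start < 8:
        raise ValueError("classification window too short (need more records)")
    s = k.signal[win]
    x = k.x[win][-1]
    L = float(k.length[win][-1])
    mean_t = s.mean(axis=0)
    std_t = s.std(axis=0)
    amp = float(std_t.max() / max(mean_t.max(), 1e-300))

    # node/antinode positions from the temporal-variation profile
    peaks, _ = find_peaks(std_t, prominence=0.05 * std_t.max())
    anti = list(x[peaks])
    if std_t[0] > std_t[1]:
        anti.insert(0, x[0])
    if std_t[-1] > std_t[-2]:
        anti.append(x[-1])
    dips, _ = find_peaks(-std_t, prominence=0.05 * std_t.max())
    nodes = x[dips]

    significant = mean_t > 0.1 * mean_t.max()
    cv = std_t[significant] / mean_t[significant]
    if cv.max() < th.stationary_cv:
        return PatternReport("stationary", None, nodes, np.asarray(anti),
                             amp, (0.0, 0.0))

    c1, c2 = _mode_coefficients(k, win)
    p1, p2 = float(np.var(c1)), float(np.var(c2))
    period = estimate_period(Kymograph(k.times[win], k.x[win], s,
                                       k.length[win], k.dx[win]))

    powers = (p1, p2)
    if min(p1, p2) > 0 and max(p1, p2) / min(p1, p2) < th.mixing_factor:
        # standing modes are in phase or antiphase; travelling waves put the
        # two spatial modes in quadrature
        f1, f2 = np.fft.rfft(c1 - c1.mean()), np.fft.rfft(c2 - c2.mean())
        peak = int(np.argmax(np.abs(f1[1:]) ** 2 + np.abs(f2[1:]) ** 2)) + 1
        dphi = float(np.angle(f1[peak] * np.conj(f2[peak])))
        if abs(np.sin(dphi)) > 0.5:
            return PatternReport("mixed_travelling", period, nodes,
                                 np.asarray(anti), amp, powers)
    # midcell antinodes: the instantaneous high-MinD peak detaches from the
    # pole into the central region while substantial first-mode (pole-to-pole
    # alternating) content remains
    x_peak = x[np.argmax(s, axis=1)]
    frac_central = float(np.mean(np.abs(x_peak - L / 2.0)
                                 < 0.5 * th.midcell_window * L))
    if frac_central >= th.peak_detach_fraction and p1 >= th.midcell_mode1_factor * p2:
        return PatternReport("midcell_antinode", period, nodes,
                             np.asarray(anti), amp, powers)
    if p2 > p1:
        return PatternReport("second_order_breather", period, nodes,
                             np.asarray(anti), amp, powers)
    return PatternReport("first_order_breather", period, nodes,
                         np.asarray(anti), amp, powers)


#: Named groups usable as transition endpoints.
CLASS_GROUPS: dict[str, frozenset[str]] = {
    "stationary": frozenset({"stationary"}),
    "oscillating": frozenset({"first_order_breather", "second_order_breather",
                              "mixed_travelling", "midcell_antinode"}),
    "first_order": frozenset({"first_order_breather"}),
    "second_order": frozenset({"second_order_breather"}),
    "mixed_travelling": frozenset({"mixed_travelling"}),
    "midcell_antinode": frozenset({"midcell_antinode"}),
}


def _group(name: str) -> frozenset[str]:
    if name in CLASS_GROUPS:
        return CLASS_GROUPS[name]
    return frozenset({name})


def find_transition(p: mc.RateParameters, from_class: str, to_class: str,
                    L_lo: float, L_hi: float, tol: float = 0.1,
                    cfg: Optional[sv.SimulationConfig] = None,
                    totals: mc.ConcentrationTotals = mc.ConcentrationTotals(),
                    runner: Optional[Callable[[float], Kymograph]] = None,
                    thresholds: ClassifierThresholds = ClassifierThresholds(),
                    ) -> float:
    """Bisect on cell length for the boundary between two pattern regimes.

    Classification at ``L_lo`` must fall in ``from_class`` and at ``L_hi``
    in ``to_class`` (group names from :data:`CLASS_GROUPS` or literal class
    names).  Interior lengths are attributed to the ``to`` side only once
    they classify inside the ``to`` group; transitional states (e.g. mode
    mixing between two breather orders) count as not-yet-transitioned, so
    the returned length is where the ``to`` regime becomes established.
    """
    if runner is None:
        cfg = cfg or sv.SimulationConfig()

        def runner(L: float) -> Kymograph:
            return collapse(sv.run_fixed_length(L, p, cfg, totals))

    grp_from, grp_to = _group(from_class), _group(to_class)

    def side(L: float) -> bool:
        """True while not yet in the target regime."""
        return classify(runner(L), thresholds).pattern not in grp_to

    lo_report = classify(runner(L_lo), thresholds).pattern
    hi_report = classify(runner(L_hi), thresholds).pattern
    if lo_report not in grp_from or hi_report not in grp_to:
        raise ValueError(
            f"bracketing error: classes at ends are {lo_report!r} / {hi_report!r}, "
            f"expected {from_class!r} / {to_class!r}")
    lo, hi = L_lo, L_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if side(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def midcell_node_check(k: Kymograph,
                       thresholds: ClassifierThresholds = ClassifierThresholds()
                       ) -> bool:
    """True iff the kymograph shows a first-order breather with a definite
    midcell node (temporal variance at midcell far below its maximum)."""
    report = classify(k, thresholds)
    if report.pattern != "first_order_breather":
        return False
    win = _analysis_window(k, thresholds.analysis_fraction)
    s = k.signal[win]
    x = k.x[win][-1]
    L = float(k.length[win][-1])
    var_t = s.var(axis=0)
    mid_var = float(np.interp(L / 2.0, x, var_t))
    return mid_var < thresholds.node_variance_ratio * float(var_t.max())


def partition_metrics(traj: sv.Trajectory,
                      window: Optional[tuple[float, float]] = None,
                      schedule: Optional[object] = None,
                      fission_extrapolation: float = 80.0) -> PartitionSeries:
    """Fractions of MinD and MinE above the septum plane over a division run.

    The septum plane is midcell; the straddling finite-volume cell is split
    in proportion to the axial overlap.  RMS statistics are computed over
    ``window``; by default the window runs from maximal constriction to the
    projected fission time (``fission_extrapolation`` seconds later), the
    interval over which daughter-cell inheritance is decided.
    """
    nt, n = traj.fields.shape[:2]
    fracD = np.empty(nt)
    fracE = np.empty(nt)
    eqD = traj.minD_equivalents()
    eqE = traj.minE_equivalents()
    for it in range(nt):
        edges = traj.x_edges[it]
        mid = 0.5 * traj.length[it]
        # fraction of each cell lying above the plane
        upper = np.clip((edges[1:] - mid) / np.diff(edges), 0.0, 1.0)
        fracD[it] = 100.0 * (eqD[it] * upper).sum() / eqD[it].sum()
        fracE[it] = 100.0 * (eqE[it] * upper).sum() / eqE[it].sum()

    if window is None:
        if schedule is not None:
            t0 = float(schedule.t_end)
            t1 = t0 + fission_extrapolation
        else:
            t0 = float(traj.times[int(0.8 * nt)])
            t1 = float(traj.times[-1])
        window = (t0, min(t1, float(traj.times[-1])))
    m = (traj.times >= window[0]) & (traj.times <= window[1])
    if not m.any():
        raise ValueError("partition RMS window contains no records")
    rmsD = float(np.sqrt(np.mean((fracD[m] - 50.0) ** 2)))
    rmsE = float(np.sqrt(np.mean((fracE[m] - 50.0) ** 2)))
    rmsDE = float(np.sqrt(np.mean((fracD[m] - fracE[m]) ** 2)))
    return PartitionSeries(times=traj.times, frac_minD_top=fracD,
                           frac_minE_top=fracE, rms_from_parity_minD=rmsD,
                           rms_from_parity_minE=rmsE, rms_D_vs_E=rmsDE,
                           window=window)


def kymograph_to_csv(k: Kymograph, path) -> None:
    """Write the kymograph as CSV: one row per time, one column per x bin."""
    import pandas as pd

    cols = [f"x={xi:.4f}" for xi in k.x[-1]]
    df = pd.DataFrame(k.signal, index=pd.Index(k.times, name="t"), columns=cols)
    df.to_csv(path)


def render_kymograph(k: Kymograph, path, cmap: str = "viridis") -> None:
    """Heatmap of the kymograph (high MinD yellow, low dark blue)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.0, 6.0))
    extent = (float(k.x[-1][0]), float(k.x[-1][-1]),
              float(k.times[-1]), float(k.times[0]))
    ax.imshow(k.signal, aspect="auto", cmap=cmap, extent=extent)
    ax.set_xlabel("axial position (um)")
    ax.set_ylabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
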