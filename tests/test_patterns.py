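"""Kymograph analysis on constructed signals with known structure."""

import numpy as np
import pytest

from minosc import patterns as pt
from minosc import solver as sv
from minosc import model_core as mc
from minosc import ConcentrationTotals, RateParameters, SimulationConfig


def synthetic(profile, L=4.0, n=80, T=600.0, dt=2.0, period=80.0,
              base=100.0, amp=40.0):
    """Kymograph base + amp * profile(x, t) on a uniform grid."""
    t = np.arange(0.0, T, dt)
    x = (np.arange(n) + 0.5) * L / n
    sig = base + amp * profile(x[None, :], t[:, None], L, period)
    return pt.Kymograph(times=t, x=np.tile(x, (len(t), 1)), signal=sig,
                        length=np.full(len(t), L),
                        dx=np.full((len(t), n), L / n))


def first_order(x, t, L, T):
    return np.cos(np.pi * x / L) * np.cos(2 * np.pi * t / T)


def second_order(x, t, L, T):
    return np.cos(2 * np.pi * x / L) * np.cos(2 * np.pi * t / T)


def travelling(x, t, L, T):
    return (np.cos(np.pi * x / L) * np.cos(2 * np.pi * t / T)
            + np.cos(2 * np.pi * x / L) * np.sin(2 * np.pi * t / T))


class TestEstimatePeriod:
    def test_recovers_known_period(self):
        k = synthetic(lambda x, t, L, T: np.cos(2 * np.pi * t / T) + 0 * x,
                      period=83.0)
        assert pt.estimate_period(k) == pytest.approx(83.0, rel=0.03)

    def test_constant_signal_has_no_period(self):
        k = synthetic(lambda x, t, L, T: 0.0 * x * t)
        assert pt.estimate_period(k) is None

    def test_window_restriction(self):
        k = synthetic(first_order, period=60.0)
        assert pt.estimate_period(k, window=(200.0, 598.0)) == pytest.approx(
            60.0, rel=0.05)


class TestClassify:
    def test_first_order_breather_with_midcell_node(self):
        k = synthetic(first_order)
        rep = pt.classify(k)
        assert rep.pattern == "first_order_breather"
        assert rep.period == pytest.approx(80.0, rel=0.05)
        assert any(abs(nx - 2.0) < 0.1 for nx in rep.node_positions)

    def test_second_order_breather_has_two_nodes(self):
        k = synthetic(second_order)
        rep = pt.classify(k)
        assert rep.pattern == "second_order_breather"
        assert len(rep.node_positions) == 2

    def test_travelling_superposition_is_mixed(self):
        k = synthetic(travelling)
        assert pt.classify(k).pattern == "mixed_travelling"

    def test_constant_is_stationary_without_period(self):
        k = synthetic(lambda x, t, L, T: 0.0 * x * t)
        rep = pt.classify(k)
        assert rep.pattern == "stationary"
        assert rep.period is None

    def test_static_polar_profile_is_stationary(self):
        k = synthetic(lambda x, t, L, T: np.exp(-x / 0.5) + 0 * t, amp=300.0)
        assert pt.classify(k).pattern == "stationary"

    def test_invariant_under_rescaling_and_time_shift(self):
        k = synthetic(first_order)
        rep0 = pt.classify(k)
        k2 = pt.Kymograph(k.times + 137.0, k.x, 3.7 * k.signal, k.length, k.dx)
        rep2 = pt.classify(k2)
        assert rep2.pattern == rep0.pattern
        assert rep2.period == pytest.approx(rep0.period, rel=1e-6)

    def test_mirror_symmetry_preserves_class_and_reflects_nodes(self):
        k = synthetic(first_order)
        rep0 = pt.classify(k)
        km = pt.Kymograph(k.times, k.x, k.signal[:, ::-1], k.length, k.dx)
        repm = pt.classify(km)
        assert repm.pattern == rep0.pattern
        assert repm.period == pytest.approx(rep0.period, rel=1e-6)
        L = float(k.length[0])
        assert sorted(L - repm.node_positions) == pytest.approx(
            sorted(rep0.node_positions), abs=0.11)


class TestMidcellNodeCheck:
    def test_first_order_standing_wave_passes(self):
        assert pt.midcell_node_check(synthetic(first_order))

    def test_constant_kymograph_fails(self):
        k = synthetic(lambda x, t, L, T: 0.0 * x * t)
        assert not pt.midcell_node_check(k)

    def test_second_order_fails(self):
        assert not pt.midcell_node_check(synthetic(second_order))


@pytest.fixture(scope="module")
def run():
    cfg = SimulationConfig(burn_in=0.0, duration=100.0, record_interval=10.0)
    return sv.run_fixed_length(3.0, mc.preset("fully_labelled"), cfg)


class TestCollapse:
    def test_axial_integral_recovers_total_minD(self, run):
        k = pt.collapse(run)
        expected = 1389.0 * run.cell_volume[0].sum()
        assert k.total() == pytest.approx(expected, rel=1e-9)

    def test_uniform_cytosolic_state_follows_cross_section(self, run):
        k = pt.collapse(run)
        # at t=0 all MinD is cytosolic and uniform: signal tracks pi r(x)^2
        area = run.cell_volume[0] / np.diff(run.x_edges[0])
        ratio = k.signal[0] / area
        assert ratio == pytest.approx(np.full_like(ratio, ratio.mean()), rel=2e-3)

    def test_channels_sum_to_signal(self, run):
        k = pt.collapse(run, channels=True)
        total = (k.channels["D"] + k.channels["d"] + 2 * k.channels["d2"]
                 + 2 * k.channels["d2e2"])
        assert total == pytest.approx(k.signal, rel=1e-9)


class TestPartitionMetrics:
    def _toy_trajectory(self, asymmetry=0.0):
        nt, n, L = 11, 20, 4.0
        times = np.linspace(0, 100.0, nt)
        edges = np.tile(np.linspace(0, L, n + 1), (nt, 1))
        centers = 0.5 * (edges[:, :-1] + edges[:, 1:])
        vol = np.full((nt, n), 0.1)
        area = np.full((nt, n), 0.2)
        fields = np.zeros((nt, n, 6))
        fields[..., 0] = 1000.0
        fields[..., 1] = 300.0
        fields[:, :, 0] += asymmetry * (centers - L / 2)
        return sv.Trajectory(
            times=times, x_edges=edges, x_centers=centers, cell_volume=vol,
            membrane_area=area, fields=fields, length=np.full(nt, L),
            septum_radius=np.full(nt, 0.5), params=mc.preset("fully_labelled"),
            totals=ConcentrationTotals(), config=SimulationConfig())

    def test_symmetric_state_splits_evenly(self):
        ps = pt.partition_metrics(self._toy_trajectory())
        assert ps.frac_minD_top == pytest.approx(50.0)
        assert ps.frac_minE_top == pytest.approx(50.0)
        assert ps.rms_from_parity_minD == 0.0
        assert ps.rms_D_vs_E == 0.0

    def test_fractions_complement_to_100(self):
        traj = self._toy_trajectory(asymmetry=40.0)
        ps = pt.partition_metrics(traj)
        assert ps.frac_minD_top[0] > 50.0
        # bottom fraction is 100 - top by construction of the split
        eq = traj.minD_equivalents()[0]
        edges = traj.x_edges[0]
        upper = np.clip((edges[1:] - 2.0) / np.diff(edges), 0, 1)
        top = (eq * upper).sum() / eq.sum() * 100
        bottom = (eq * (1 - upper)).sum() / eq.sum() * 100
        assert top + bottom == pytest.approx(100.0)


def test_exports_write_files(tmp_path):
    k = synthetic(first_order, T=100.0)
    pt.kymograph_to_csv(k, tmp_path / "k.csv")
    pt.render_kymograph(k, tmp_path / "k.png")
    assert (tmp_path / "k.csv").stat().st_size > 0
    assert (tmp_path / "k.png").stat().st_size > 0
    import pandas as pd
    df = pd.read_csv(tmp_path / "k.csv", index_col=0)
    assert df.shape == k.signal.shape
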