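"""Signal-model unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ftilt import (
    AcquisitionGeometry,
    JointSchedule,
    NoiseModel,
    PeakModel,
    generate_schedule,
    protein_fixture,
    read_peak_table,
    simulate_full_grid,
    simulate_joint_fid,
    write_peak_table,
)


class TestPeakModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            PeakModel(freq_indirect=0, linewidth=1, amplitude=-1, rate=1)
        with pytest.raises(ValueError):
            PeakModel(freq_indirect=0, linewidth=-1, amplitude=1, rate=1)
        with pytest.raises(ValueError):
            PeakModel(freq_indirect=0, linewidth=1, amplitude=1, rate=0)


class TestGeometry:
    def test_t1_grid_is_dwell_multiples(self, small_geometry):
        np.testing.assert_allclose(
            small_geometry.t1_times, np.arange(16) / 100.0
        )

    def test_delay_universe_is_mesh_multiples(self, small_geometry):
        u = small_geometry.delay_universe
        assert u[0] == pytest.approx(0.01)
        assert u[-1] == pytest.approx(0.2)
        np.testing.assert_allclose(np.diff(u), 0.01)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionGeometry(r_min=2.0, r_max=1.0)
        with pytest.raises(ValueError):
            AcquisitionGeometry(n_t1=0)


class TestSimulateJointFid:
    def test_zero_peaks_gives_zero_vector(self, small_geometry, small_schedule):
        q = simulate_joint_fid([], small_geometry, small_schedule)
        assert np.all(q == 0)

    def test_single_point_closed_form(self, small_geometry):
        # one peak at 0 Hz, no linewidth, unit amplitude, R = 2/s sampled
        # at t1 = 0, t_relax = 0.5 s must give exp(-1)
        geom = AcquisitionGeometry(
            n_t1=4, sw_indirect=100.0, trelax_min=0.5, trelax_max=0.5,
            trelax_mesh=0.01, n_f1_recon=4, n_r_recon=4, r_min=0.5, r_max=5.0,
        )
        sched = JointSchedule(t1_indices=np.array([0]), delays=np.array([0.5]))
        pk = PeakModel(freq_indirect=0.0, linewidth=0.0, amplitude=1.0, rate=2.0)
        q = simulate_joint_fid([pk], geom, sched)
        assert q[0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_superposition(self, small_geometry, small_schedule):
        rng = np.random.default_rng(5)
        peaks = [
            PeakModel(
                freq_indirect=float(rng.uniform(-49, 50)),
                linewidth=float(rng.uniform(0, 5)),
                amplitude=float(rng.uniform(0.5, 2)),
                rate=float(rng.uniform(0.6, 4)),
            )
            for _ in range(3)
        ]
        total = simulate_joint_fid(peaks, small_geometry, small_schedule)
        parts = sum(
            simulate_joint_fid([p], small_geometry, small_schedule) for p in peaks
        )
        np.testing.assert_allclose(total, parts, rtol=1e-12, atol=1e-14)

    def test_zero_delay_reduces_to_pure_t1_fid(self):
        # with t_relax = 0 the relaxation factor is 1: the joint signal
        # equals the plain 2D evolution-time signal
        geom = AcquisitionGeometry(
            n_t1=8, sw_indirect=100.0, trelax_min=0.0, trelax_max=0.1,
            trelax_mesh=0.01, n_f1_recon=8, n_r_recon=4, r_min=0.5, r_max=5.0,
        )
        sched = JointSchedule(
            t1_indices=np.arange(8), delays=np.zeros(8)
        )
        pk = PeakModel(freq_indirect=12.5, linewidth=3.0, amplitude=2.0, rate=1.7)
        q = simulate_joint_fid([pk], geom, sched)
        t1 = np.arange(8) / 100.0
        expected = 2.0 * np.exp((2j * np.pi * 12.5 - np.pi * 3.0) * t1)
        np.testing.assert_allclose(q, expected, rtol=1e-12)

    def test_schedule_outside_geometry_rejected(self, small_geometry):
        bad = JointSchedule(t1_indices=np.array([99]), delays=np.array([0.01]))
        with pytest.raises(ValueError, match="row 0"):
            simulate_joint_fid([], small_geometry, bad)
        bad_delay = JointSchedule(t1_indices=np.array([0]), delays=np.array([0.015]))
        with pytest.raises(ValueError, match="delay"):
            simulate_joint_fid([], small_geometry, bad_delay)

    def test_noise_deterministic_and_calibrated(self, small_geometry):
        geom = AcquisitionGeometry(
            n_t1=200, sw_indirect=100.0, trelax_min=0.01, trelax_max=0.6,
            trelax_mesh=0.01, n_f1_recon=8, n_r_recon=8, r_min=0.5, r_max=5.0,
        )
        sched = generate_schedule(geom, 11000, seed=1)
        noise = NoiseModel(sigma=0.7, seed=42)
        q1 = simulate_joint_fid([], geom, sched, noise)
        q2 = simulate_joint_fid([], geom, sched, noise)
        np.testing.assert_array_equal(q1, q2)
        # per-component variance matches sigma^2 within 10% at n >= 1e4
        assert np.var(q1.real) == pytest.approx(0.49, rel=0.1)
        assert np.var(q1.imag) == pytest.approx(0.49, rel=0.1)
        q3 = simulate_joint_fid([], geom, sched, NoiseModel(sigma=0.7, seed=43))
        assert not np.array_equal(q1, q3)


class TestFullGridSimulation:
    def test_matches_joint_fid_row_by_row(self, small_geometry):
        pk = PeakModel(freq_indirect=10.0, linewidth=2.0, amplitude=1.5, rate=2.2)
        delays = np.array([0.01, 0.1, 0.2])
        grid = simulate_full_grid([pk], small_geometry, delays)
        sched = JointSchedule(
            t1_indices=np.tile(np.arange(16), 3),
            delays=np.repeat(delays, 16),
        )
        q = simulate_joint_fid([pk], small_geometry, sched)
        np.testing.assert_allclose(grid.ravel(), q, rtol=1e-12)


class TestProteinFixture:
    def test_single_peak_within_bounds(self, small_geometry):
        (pk,) = protein_fixture(1, small_geometry, seed=0)
        assert small_geometry.contains_frequency(pk.freq_indirect)
        assert small_geometry.r_min < pk.rate < small_geometry.r_max

    def test_rates_strictly_inside_band(self):
        geom = AcquisitionGeometry()  # 0.5-5 Hz band
        peaks = protein_fixture(20, geom, seed=3)
        rates = np.array([p.rate for p in peaks])
        assert np.all(rates > 0.5) and np.all(rates < 5.0)

    def test_frequency_separation_and_amplitude_range(self):
        geom = AcquisitionGeometry()
        peaks = protein_fixture(20, geom, seed=3)
        freqs = np.sort([p.freq_indirect for p in peaks])
        min_sep = 2 * geom.sw_indirect / geom.n_f1_recon
        assert np.min(np.diff(freqs)) >= min_sep
        amps = np.array([p.amplitude for p in peaks])
        assert amps.max() / amps.min() <= 10.0 + 1e-9

    def test_deterministic_by_seed(self, small_geometry):
        a = protein_fixture(3, small_geometry, seed=11)
        b = protein_fixture(3, small_geometry, seed=11)
        assert a == b

    def test_overcrowded_request_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            protein_fixture(1000, small_geometry, seed=0)


class TestPeakTableIO:
    def test_round_trip(self, tmp_path):
        geom = AcquisitionGeometry()
        peaks = protein_fixture(5, geom, seed=2)
        path = tmp_path / "peaks.tsv"
        write_peak_table(peaks, path)
        back = read_peak_table(path)
        for a, b in zip(peaks, back):
            assert a.freq_indirect == pytest.approx(b.freq_indirect, rel=1e-9)
            assert a.rate == pytest.approx(b.rate, rel=1e-9)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("freq_hz\tamplitude\n1.0\t2.0\n")
        with pytest.raises(ValueError, match="missing"):
            read_peak_table(path)
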