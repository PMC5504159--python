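"""Fourier row, Laplace kernel and joint-operator algebra tests."""

import numpy as np
import pytest

from ftilt import (
    AcquisitionGeometry,
    FrequencyGrid,
    JointOperator,
    JointSchedule,
    PeakModel,
    RateGrid,
    fourier_row,
    generate_schedule,
    laplace_entry,
    simulate_joint_fid,
)


class TestFrequencyGrid:
    def test_covers_half_open_interval(self, small_geometry):
        g = FrequencyGrid.from_geometry(small_geometry)
        sw = small_geometry.sw_indirect
        assert g.values[0] > -sw / 2
        assert g.values[-1] == pytest.approx(sw / 2)
        np.testing.assert_allclose(np.diff(g.values), sw / g.n)

    def test_contains_zero_bin(self, small_geometry):
        g = FrequencyGrid.from_geometry(small_geometry)
        assert np.min(np.abs(g.values)) == pytest.approx(0.0, abs=1e-12)


class TestRateGrid:
    def test_linear_endpoints(self, small_geometry):
        g = RateGrid.from_geometry(small_geometry)
        assert g.values[0] == small_geometry.r_min
        assert g.values[-1] == small_geometry.r_max
        assert np.all(np.diff(g.values) > 0)

    def test_log_option(self, small_geometry):
        g = RateGrid.from_geometry(small_geometry, spacing="log")
        ratios = g.values[1:] / g.values[:-1]
        np.testing.assert_allclose(ratios, ratios[0])

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            RateGrid(values=np.array([1.0, 0.5, 2.0]))


class TestFourierRow:
    def test_t1_zero_is_uniform(self, small_geometry):
        g = FrequencyGrid.from_geometry(small_geometry)
        row = fourier_row(0.0, g)
        np.testing.assert_allclose(row, np.full(g.n, 1.0 / g.n))

    def test_rows_form_scaled_unitary_matrix(self):
        # the n x n synthesis matrix at the canonical t1 values satisfies
        # F F^H = I / n with the 1/n scaling convention
        geom = AcquisitionGeometry(
            n_t1=4, sw_indirect=40.0, trelax_min=0.01, trelax_max=0.1,
            trelax_mesh=0.01, n_f1_recon=4, n_r_recon=4, r_min=0.5, r_max=5.0,
        )
        g = FrequencyGrid.from_geometry(geom)
        F = np.array([fourier_row(t, g) for t in geom.t1_times])
        np.testing.assert_allclose(F @ F.conj().T, np.eye(4) / 4, atol=1e-12)

    def test_on_grid_sinusoid_round_trip(self):
        # synthesizing a one-hot spectrum then analyzing with the DFT
        # returns a single nonzero bin
        geom = AcquisitionGeometry(
            n_t1=8, sw_indirect=80.0, trelax_min=0.01, trelax_max=0.1,
            trelax_mesh=0.01, n_f1_recon=8, n_r_recon=4, r_min=0.5, r_max=5.0,
        )
        g = FrequencyGrid.from_geometry(geom)
        S = np.zeros(8, dtype=complex)
        S[3] = 1.0
        fid = np.array([fourier_row(t, g) @ S for t in geom.t1_times])
        spec = np.array(
            [np.exp(-2j * np.pi * f * geom.t1_times) @ fid for f in g.values]
        )
        mags = np.abs(spec)
        assert mags.argmax() == 3
        mags[3] = 0.0
        assert np.all(mags < 1e-10)


class TestLaplaceEntry:
    def test_zero_delay_is_one(self):
        assert laplace_entry(0.0, 3.3) == pytest.approx(1.0)

    def test_closed_form(self):
        assert laplace_entry(0.5, 2.0) == pytest.approx(np.exp(-1.0), abs=1e-14)

    def test_monotone_decreasing_in_rate(self):
        rates = np.linspace(0.5, 5, 50)
        vals = laplace_entry(0.3, rates)
        assert np.all(np.diff(vals) < 0)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            laplace_entry(-0.1, 1.0)


class TestJointOperator:
    def test_zero_plane_maps_to_zero(self, small_geometry, small_schedule):
        op = JointOperator(small_geometry, small_schedule)
        assert np.all(op.forward(np.zeros(op.plane_shape)) == 0)
        assert np.all(op.adjoint(np.zeros(op.n_samples)) == 0)

    def test_one_hot_plane_closed_form(self, small_geometry, small_schedule):
        op = JointOperator(small_geometry, small_schedule)
        k0, j0 = 3, 2
        Q = np.zeros(op.plane_shape, dtype=complex)
        Q[k0, j0] = 1.0
        q = op.forward(Q)
        t1 = small_schedule.t1_indices / small_geometry.sw_indirect
        expected = (
            np.exp(2j * np.pi * op.fgrid.values[k0] * t1) / op.fgrid.n
            * np.exp(-op.rgrid.values[j0] * small_schedule.delays)
        )
        np.testing.assert_allclose(q, expected, rtol=1e-12)

    def test_matches_dense_kronecker(self, small_geometry, small_schedule):
        op = JointOperator(small_geometry, small_schedule)
        P = op.dense_matrix()
        rng = np.random.default_rng(3)
        for _ in range(5):
            Q = rng.standard_normal(op.plane_shape) + 1j * rng.standard_normal(op.plane_shape)
            ref = P @ Q.ravel()
            np.testing.assert_allclose(op.forward(Q), ref, rtol=1e-12)
            q = rng.standard_normal(op.n_samples) + 1j * rng.standard_normal(op.n_samples)
            np.testing.assert_allclose(
                op.adjoint(q).ravel(), P.conj().T @ q, rtol=1e-12
            )

    def test_adjoint_inner_product_identity(self, small_geometry, small_schedule):
        op = JointOperator(small_geometry, small_schedule)
        rng = np.random.default_rng(11)
        for _ in range(100):
            Q = rng.standard_normal(op.plane_shape) + 1j * rng.standard_normal(op.plane_shape)
            q = rng.standard_normal(op.n_samples) + 1j * rng.standard_normal(op.n_samples)
            lhs = np.vdot(q, op.forward(Q))
            rhs = np.vdot(op.adjoint(q), Q)
            assert abs(lhs - rhs) <= 1e-10 * max(
                np.linalg.norm(Q) * np.linalg.norm(q), 1.0
            )

    def test_rank_one_adjoint_of_unit_sample(self, small_geometry):
        sched = JointSchedule(t1_indices=np.array([5]), delays=np.array([0.05]))
        op = JointOperator(small_geometry, sched)
        plane = op.adjoint(np.array([1.0 + 0j]))
        t1 = 5 / small_geometry.sw_indirect
        f_row = np.exp(2j * np.pi * op.fgrid.values * t1) / op.fgrid.n
        l_row = np.exp(-op.rgrid.values * 0.05)
        np.testing.assert_allclose(plane, np.outer(f_row.conj(), l_row), rtol=1e-12)

    def test_shape_mismatch_rejected(self, small_geometry, small_schedule):
        op = JointOperator(small_geometry, small_schedule)
        with pytest.raises(ValueError):
            op.forward(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            op.adjoint(np.zeros(5))

    def test_full_sampling_single_rate_inverts_frequency(self):
        # every (t1, trelax) pair sampled, one decay rate: the Fourier
        # dimension must invert exactly by the adjoint of the unitary part
        geom = AcquisitionGeometry(
            n_t1=16, sw_indirect=160.0, trelax_min=0.1, trelax_max=0.1,
            trelax_mesh=0.01, n_f1_recon=16, n_r_recon=1, r_min=2.0, r_max=3.0,
        )
        rg = RateGrid(values=np.array([2.0]))
        sched = JointSchedule(
            t1_indices=np.arange(16), delays=np.full(16, 0.1)
        )
        fg = FrequencyGrid.from_geometry(geom)
        op = JointOperator(geom, sched, fg, rg)
        k0 = 6
        pk = PeakModel(
            freq_indirect=float(fg.values[k0]), linewidth=0.0, amplitude=1.0, rate=2.0
        )
        q = simulate_joint_fid([pk], geom, sched)
        # adjoint inverts the scaled-unitary Fourier part up to the
        # squared decay factor exp(-2 R trelax)
        plane = op.adjoint(q) / np.exp(-2 * 0.1 * 2)
        mags = np.abs(plane[:, 0])
        assert mags.argmax() == k0
        assert mags[k0] == pytest.approx(1.0, abs=1e-8)
        mags[k0] = 0
        assert np.all(mags < 1e-8)

    def test_normalized_columns_have_unit_norm(self, small_geometry, small_schedule):
        op = JointOperator(small_geometry, small_schedule, normalize_columns=True)
        P = op.dense_matrix()
        norms = np.linalg.norm(P, axis=0)
        np.testing.assert_allclose(norms, norms[0], rtol=1e-12)
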