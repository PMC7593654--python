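"""Classical reconstruction operators: geometry, linearity, accuracy."""

import numpy as np
import pytest

from patrecon import acoustics as ac, classical as cl
from .conftest import rel_l2, smooth_blob


def ncc(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))


class TestDelayAndSum:
    def test_zero_data_gives_zero_image(self, geom16):
        out = cl.delay_and_sum(
            np.zeros((geom16.n_det, geom16.n_t)), geom16)
        assert np.all(out == 0)

    def test_single_spike_paints_an_annulus(self, geom16):
        """One detector, one time sample: the backprojection is nonzero
        only on the annulus at that arrival distance."""
        gv = np.zeros((geom16.n_det, geom16.n_t))
        d, k = 5, 20
        gv[d, k] = 1.0
        out = cl.delay_and_sum(gv, geom16)
        r = np.arange(16)[:, None] * geom16.dx
        c = (np.arange(16)[None, :] - geom16.detector_cols[d]) * geom16.dx
        dist = np.sqrt(r * r + c * c)
        inside = np.abs(dist - k * geom16.c * geom16.dt) \
            < geom16.c * geom16.dt
        assert np.all(out[~inside] == 0)
        assert out[inside].max() > 0

    def test_peak_near_disc_center(self, geom64):
        """Simulation oracle: a small disc reconstructs with its peak
        within 2 pixels of the center."""
        m = 64
        y, x = np.mgrid[:m, :m]
        disc = (((y - 32) ** 2 + (x - 32) ** 2) <= 2.5 ** 2).astype(float)
        out = cl.delay_and_sum(ac.propagate(disc, geom64), geom64)
        peak = np.unravel_index(np.argmax(out), out.shape)
        assert max(abs(peak[0] - 32), abs(peak[1] - 32)) <= 2


class TestUniversalBackprojection:
    def test_zero_data_gives_zero_image(self, geom16):
        out = cl.universal_bp_2d(
            np.zeros((geom16.n_det, geom16.n_t)), geom16)
        assert np.all(out == 0)

    def test_linearity(self, geom16):
        rng = np.random.default_rng(6)
        g1 = rng.standard_normal((geom16.n_det, geom16.n_t))
        g2 = rng.standard_normal((geom16.n_det, geom16.n_t))
        lhs = cl.universal_bp_2d(2.0 * g1 - g2, geom16)
        rhs = 2.0 * cl.universal_bp_2d(g1, geom16) \
            - cl.universal_bp_2d(g2, geom16)
        assert np.abs(lhs - rhs).max() <= 1e-10 * np.abs(rhs).max()

    def test_beats_delay_and_sum_near_detector(self, geom64):
        """Head-to-head on a centered disc: the filtered formula has the
        smaller relative error in the half nearest the detector (the
        unfiltered sum is compared at its best least-squares scale)."""
        m = 64
        y, x = np.mgrid[:m, :m]
        disc = (((y - 32) ** 2 + (x - 32) ** 2) <= (m / 6) ** 2
                ).astype(float)
        g = ac.propagate(disc, geom64)
        ubp = cl.universal_bp_2d(g, geom64)
        das = cl.delay_and_sum(g, geom64)
        das = das * (np.sum(das * disc) / np.sum(das * das))
        near = slice(0, 32)
        assert rel_l2(ubp[near], disc[near]) < rel_l2(das[near], disc[near])


class TestFFTReconstruct:
    def test_zero_data_gives_zero_image(self, geom16):
        out = cl.fft_reconstruct(
            np.zeros((geom16.n_det, geom16.n_t)), geom16)
        assert np.all(out == 0)

    def test_round_trip_on_central_smooth_phantom(self, geom64, blob64):
        # frozen reference tolerance: measured 0.61 on this fixture; the
        # finite one-sided aperture leaves the oblique components
        # under-recovered (see the matrix-inversion comparison below)
        img, g = blob64
        rec = cl.fft_reconstruct(g, geom64)
        assert rel_l2(rec, img) <= 0.70

    def test_output_is_real_with_small_imaginary_residual(self, geom32,
                                                          blob32):
        # the conjugate-symmetry check raises if the imaginary residual
        # exceeds 1e-10 of the output scale
        img, g = blob32
        rec = cl.fft_reconstruct(g, geom32)
        assert np.isrealobj(rec) and np.all(np.isfinite(rec))

    def test_requires_uniform_full_line(self):
        geom = ac.AcousticGeometry(m=16, detector_stride=2)
        with pytest.raises(ValueError, match="stride"):
            cl.fft_reconstruct(np.zeros((geom.n_det, geom.n_t)), geom)


class TestTimeReversal:
    def test_zero_data_gives_zero_image(self, geom16):
        out = cl.time_reversal(
            np.zeros((geom16.n_det, geom16.n_t)), geom16)
        assert np.all(out == 0)

    def test_linearity(self, geom16):
        rng = np.random.default_rng(7)
        g1 = rng.standard_normal((geom16.n_det, geom16.n_t))
        g2 = rng.standard_normal((geom16.n_det, geom16.n_t))
        lhs = cl.time_reversal(g1 + 0.5 * g2, geom16)
        rhs = cl.time_reversal(g1, geom16) \
            + 0.5 * cl.time_reversal(g2, geom16)
        assert np.abs(lhs - rhs).max() <= 1e-8 * np.abs(rhs).max()

    def test_recovers_centered_disc(self, geom64):
        """Limited-view arcs are expected; correlation with the truth
        stays high (frozen reference threshold: measured 0.735)."""
        disc = smooth_blob(64, (32, 32), 5.0, 1.0)
        rec = cl.time_reversal(ac.propagate(disc, geom64), geom64)
        assert ncc(rec, disc) >= 0.65

    def test_cfl_guard(self):
        geom = ac.AcousticGeometry(m=16, dt=0.5)  # ok for propagation
        with pytest.raises(ValueError, match="stability"):
            cl.time_reversal(np.zeros((geom.n_det, geom.n_t)), geom)


class TestIterativeTimeReversal:
    def test_zero_iterations_equals_time_reversal(self, geom32, blob32):
        img, g = blob32
        f0, residuals = cl.iterative_time_reversal(g, geom32, 0)
        assert np.array_equal(f0, cl.time_reversal(g, geom32))
        assert len(residuals) == 1

    def test_residual_nonincreasing_first_iterates(self, geom32, blob32):
        # empirical on noiseless full-record data, not a guarantee
        img, g = blob32
        _, residuals = cl.iterative_time_reversal(g, geom32, 5)
        assert all(residuals[i + 1] <= residuals[i] + 1e-12
                   for i in range(5))

    def test_consistent_data_improves_at_first_step(self, geom32,
                                                    blob32):
        img, g = blob32  # g = A img exactly (noiseless)
        _, residuals = cl.iterative_time_reversal(g, geom32, 1)
        assert residuals[1] <= residuals[0]


class TestGradientDescent:
    def test_zero_data_returns_zero_image(self, A8, geom8):
        f, trace = cl.gradient_descent(
            A8, np.zeros((geom8.n_det, geom8.n_t)),
            cl.VariationalConfig(n_iter=5))
        assert np.all(f == 0)
        assert all(t == 0 for t in trace)

    def test_monotone_loss_under_default_step(self, A8, geom8):
        rng = np.random.default_rng(8)
        g = ac.propagate(rng.random((8, 8)), geom8)
        _, trace = cl.gradient_descent(A8, g,
                                       cl.VariationalConfig(n_iter=50))
        assert all(trace[i + 1] <= trace[i] + 1e-12
                   for i in range(len(trace) - 1))

    def test_converges_to_normal_equations_solution(self):
        """Well-conditioned printed system: after 500 iterations the
        iterate matches the least-squares solution from a direct
        normal-equations solve (independent oracle) to 1e-6."""
        A = np.array([[1.0, 0.0],
                      [0.0, 2.0],
                      [1.0, 1.0]])
        g = np.array([1.0, 2.0, 3.0])
        f, trace = cl.gradient_descent(
            A, g, cl.VariationalConfig(n_iter=500))
        f_star = np.linalg.solve(A.T @ A, A.T @ g)
        assert np.abs(f - f_star).max() <= 1e-6
        assert len(trace) == 501


class TestProximalGradient:
    def test_no_regularizer_matches_gradient_descent(self, A8, geom8):
        rng = np.random.default_rng(10)
        g = ac.propagate(rng.random((8, 8)), geom8)
        cfg = cl.VariationalConfig(n_iter=40)
        f_pg = cl.proximal_gradient(A8, g, cfg)
        f_gd, _ = cl.gradient_descent(A8, g, cfg)
        assert np.array_equal(f_pg, f_gd)

    def test_nonneg_prox_clips(self, A8, geom8):
        rng = np.random.default_rng(11)
        g = ac.TimeSeries(
            rng.standard_normal((geom8.n_det, geom8.n_t)),
            geom8.fingerprint)
        f = cl.proximal_gradient(
            A8, g, cl.VariationalConfig(n_iter=20, regularizer="nonneg"))
        assert f.min() >= 0.0

    def test_tv_prox_reduces_total_variation(self, A32, geom32):
        from patrecon import phantom as ph
        img = ph.generate_phantom(ph.PhantomSpec(image_size=32, seed=21))
        g = ac.add_noise(ac.propagate(img, geom32),
                         ac.NoiseModel(0.05, seed=1))
        cfg = cl.VariationalConfig(n_iter=40)
        f_gd, _ = cl.gradient_descent(A32, g, cfg)
        f_tv = cl.proximal_gradient(
            A32, g, cl.VariationalConfig(n_iter=40, regularizer="tv",
                                         reg_weight=2.0))
        assert ph.total_variation(f_tv) < ph.total_variation(f_gd)


class TestTikhonov:
    def test_large_alpha_shrinks_to_zero(self, A8, geom8):
        rng = np.random.default_rng(12)
        g = ac.propagate(rng.random((8, 8)), geom8)
        f = cl.tikhonov_solve(A8, g, 1e9)
        atg = ac.apply_adjoint(A8, g)
        assert np.linalg.norm(f) <= 1e-6 * np.linalg.norm(atg)

    def test_normal_equation_residual(self, A8, geom8):
        rng = np.random.default_rng(13)
        g = ac.propagate(rng.standard_normal((8, 8)), geom8)
        f = cl.tikhonov_solve(A8, g, 1e-3)
        H = A8.entries.T @ A8.entries + 1e-3 * np.eye(64)
        b = A8.entries.T @ g.values.ravel()
        assert np.linalg.norm(H @ f.ravel() - b) <= 1e-8 \
            * np.linalg.norm(b)

    def test_agrees_with_penalized_gradient_descent(self, A8, geom8):
        """Iterative-vs-closed-form equivalence: hand-rolled Landweber
        with the quadratic penalty gradient added."""
        rng = np.random.default_rng(14)
        g = ac.propagate(rng.random((8, 8)), geom8)
        alpha = 1e-2
        f_direct = cl.tikhonov_solve(A8, g, alpha)
        eta = 1.0 / (A8.sigma_max() ** 2 + alpha)
        f = np.zeros(64)
        gv = g.values.ravel()
        for _ in range(5000):
            grad = A8.entries.T @ (A8.entries @ f - gv) + alpha * f
            f = f - eta * grad
        assert rel_l2(f.reshape(8, 8), f_direct) <= 1e-4

    def test_rejects_nonpositive_alpha(self, A8):
        with pytest.raises(ValueError):
            cl.tikhonov_solve(A8, np.zeros(A8.shape[0]).reshape(
                A8.geometry.n_det, A8.geometry.n_t), 0.0)


class TestNullspaceProjector:
    def test_idempotent(self, A8):
        P = cl.nullspace_projector(A8)
        assert np.abs(P.matrix @ P.matrix - P.matrix).max() <= 1e-10

    def test_projection_preserves_data(self, A8, geom8):
        rng = np.random.default_rng(15)
        P = cl.nullspace_projector(A8)
        f0 = rng.random((8, 8))
        Af0 = ac.apply_forward(A8, f0).values
        for _ in range(10):
            v = rng.standard_normal((8, 8))
            out = cl.data_consistent_correct(f0, v, P)
            Aout = ac.apply_forward(A8, out).values
            assert rel_l2(Aout, Af0) <= 1e-8

    def test_zero_correction_is_identity(self, A8):
        P = cl.nullspace_projector(A8)
        f0 = np.ones((8, 8))
        assert np.allclose(cl.data_consistent_correct(f0, np.zeros((8, 8)),
                                                      P), f0)

    def test_large_systems_refused(self):
        geom = ac.AcousticGeometry(m=64)
        fake = ac.ForwardMatrix(np.zeros((4, 4)), geom)
        with pytest.raises(ValueError, match="m <= 32"):
            cl.nullspace_projector(fake)


class TestVisibleRegionRecovery:
    """On noiseless data from the central smooth phantom, each operator
    recovers the half of the domain nearest the detector to within its
    frozen reference error (measured 0.61 / 0.46 / 0.33)."""

    def test_fft(self, geom32, blob32):
        img, g = blob32
        rec = cl.fft_reconstruct(g, geom32)
        assert rel_l2(rec, img, slice(0, 16)) <= 0.70

    def test_iterative_time_reversal(self, geom32, blob32):
        img, g = blob32
        rec, _ = cl.iterative_time_reversal(g, geom32, 5)
        assert rel_l2(rec, img, slice(0, 16)) <= 0.55

    def test_gradient_descent(self, A32, geom32, blob32):
        img, g = blob32
        rec, _ = cl.gradient_descent(A32, g,
                                     cl.VariationalConfig(n_iter=200))
        assert rel_l2(rec, img, slice(0, 16)) <= 0.40
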