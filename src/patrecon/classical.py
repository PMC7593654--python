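"""Classical (non-learned) reconstruction operators for 2D PAT.

All operators map detector time series g back to an image estimate of the
initial pressure f.  The catalogue covers the standard families:

* backprojection: :func:`delay_and_sum` (unfiltered) and
  :func:`universal_bp_2d` (the 2D filtered-backprojection formula);
* Fourier-domain inversion for a planar/line geometry:
  :func:`fft_reconstruct`;
* :func:`time_reversal` and :func:`iterative_time_reversal`;
* variational schemes built on the dense forward matrix:
  :func:`gradient_descent`, :func:`proximal_gradient`,
  :func:`tikhonov_solve`;
* the null-space projector used to make learned post-processing
  data-consistent.

The one-sided line detector makes this a limited-view problem: wavefronts
travelling parallel to the detector are never recorded, so even exact
formulas leave arc artifacts away from the detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .acoustics import (AcousticGeometry, ForwardMatrix, TimeSeries,
                        apply_adjoint, apply_forward, propagate)

__all__ = [
    "VariationalConfig", "delay_and_sum", "universal_bp_2d",
    "fft_reconstruct", "time_reversal", "iterative_time_reversal",
    "gradient_descent", "proximal_gradient", "tikhonov_solve",
    "NullspaceProjector", "nullspace_projector", "data_consistent_correct",
]


@dataclass
class VariationalConfig:
    """Settings for the iterative least-squares solvers.

    ``step`` is the gradient step length eta (None = 1/sigma_max(A)^2,
    which guarantees monotone decrease of the data misfit);
    ``reg_weight`` is the regularization weight alpha.
    """

    step: float | None = None
    reg_weight: float = 0.0
    n_iter: int = 50
    regularizer: str = "none"  # none | nonneg | tv
    tv_inner_iters: int = 20
    tolerance: float = 0.0

    def __post_init__(self):
        if self.step is not None and self.step <= 0:
            raise ValueError("step must be positive")
        if self.reg_weight < 0:
            raise ValueError("reg_weight must be >= 0")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        if self.regularizer not in ("none", "nonneg", "tv"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")


def _values(g) -> np.ndarray:
    return g.values if isinstance(g, TimeSeries) else np.asarray(g, float)


def _pixel_distances(geom: AcousticGeometry, det_col: int) -> np.ndarray:
    """Distance from every pixel center to detector node (0, det_col)."""
    r = np.arange(geom.m)[:, None] * geom.dx
    c = (np.arange(geom.m)[None, :] - det_col) * geom.dx
    return np.sqrt(r * r + c * c)


def delay_and_sum(g, geom: AcousticGeometry) -> np.ndarray:
    """Unfiltered backprojection: sum each detector's sample at the
    arrival time t = |x - x_s| / c over all detectors (linear
    interpolation in time; arrivals beyond the record contribute zero).
    """
    gv = _values(g)
    if gv.shape != (geom.n_det, geom.n_t):
        raise ValueError(f"data shape {gv.shape} does not match geometry")
    out = np.zeros((geom.m, geom.m))
    for d, col in enumerate(geom.detector_cols):
        tk = _pixel_distances(geom, col) / (geom.c * geom.dt)
        k0 = np.floor(tk).astype(int)
        w = tk - k0
        valid = k0 + 1 < geom.n_t
        k0c = np.clip(k0, 0, geom.n_t - 2)
        out += np.where(
            valid, (1.0 - w) * gv[d, k0c] + w * gv[d, k0c + 1], 0.0)
    return out


# one calibration constant per geometry, computed lazily (see
# universal_bp_2d docstring)
_UBP_NORM_CACHE: dict[str, float] = {}


def _ubp_raw(gv: np.ndarray, geom: AcousticGeometry) -> np.ndarray:
    """2D universal backprojection up to a global constant."""
    t = geom.times
    dt = geom.dt
    # d/dt (g / t); skip the t=0 sample, central differences inside
    q = np.zeros_like(gv)
    q[:, 1:] = gv[:, 1:] / t[1:]
    h = np.zeros_like(gv)
    h[:, 1:-1] = (q[:, 2:] - q[:, :-2]) / (2.0 * dt)
    out = np.zeros((geom.m, geom.m))
    t2 = t * t
    for d, col in enumerate(geom.detector_cols):
        t0 = _pixel_distances(geom, col) / geom.c
        # trapezoid over t starting one sample above the 1/sqrt singularity
        mask = t[None, None, :] >= (t0 + dt)[:, :, None]
        denom = np.sqrt(np.maximum(t2[None, None, :]
                                   - (t0 * t0)[:, :, None], 1e-300))
        wts = dt * mask.astype(float)
        first = mask & (np.cumsum(mask, axis=2) == 1)
        wts[first] *= 0.5
        wts[:, :, -1] *= 0.5
        out += (wts * h[d][None, None, :] / denom).sum(axis=2)
    depth = np.arange(geom.m)[:, None] * geom.dx
    # kappa * cos(alpha) = |x - x_s| * depth / |x - x_s| = depth
    return out * depth * geom.dx * geom.detector_stride


def universal_bp_2d(g, geom: AcousticGeometry) -> np.ndarray:
    """2D universal backprojection for the one-sided line detector.

    Implements the exact 2D filtered-backprojection integral (time
    derivative of g/t, weighted by 1/sqrt(t^2 - t0^2), backprojected with
    weight kappa * cos(alpha) = depth).  The closed-form solid-angle
    normalization applies only to closed measurement curves, so for the
    open line the overall constant is calibrated once per geometry
    against a simulated disc phantom (least-squares amplitude fit) and
    cached.  The operator is linear in g.
    """
    gv = _values(g)
    if gv.shape != (geom.n_det, geom.n_t):
        raise ValueError(f"data shape {gv.shape} does not match geometry")
    key = geom.fingerprint
    if key not in _UBP_NORM_CACHE:
        disc = _calibration_disc(geom.m)
        raw = _ubp_raw(propagate(disc, geom).values, geom)
        _UBP_NORM_CACHE[key] = float(
            np.sum(raw * disc) / np.sum(raw * raw))
    return _UBP_NORM_CACHE[key] * _ubp_raw(gv, geom)


def _calibration_disc(m: int) -> np.ndarray:
    y, x = np.mgrid[:m, :m]
    return (((y - m / 2) ** 2 + (x - m / 2) ** 2) <= (m / 6) ** 2
            ).astype(float)


def fft_reconstruct(g, geom: AcousticGeometry, lateral_pad: int = 2
                    ) -> np.ndarray:
    """Fourier-domain reconstruction for the uniform full-width line.

    Cosine transform in time, FFT along the (zero-padded) detector line,
    then the algebraic map from temporal frequency to depth wavenumber
    via the dispersion relation omega = c |k|.  The Jacobian scaling
    B = k_depth / omega is applied *before* interpolating onto the
    uniform depth-wavenumber grid: the scaled spectrum is smooth across
    the dispersion-cone edge where the raw data spectrum has an
    integrable singularity.  Components below the cone (evanescent set)
    are zeroed; the kz = 0 bin, which sits exactly on the cone edge, is
    filled by even-quadratic extrapolation from its neighbours.

    A one-sided line cannot distinguish a source from its mirror image
    in the detector plane, so the result is the even-in-depth part of f
    cropped to the image window (depth >= 0).  With a finite aperture,
    components travelling nearly parallel to the line (kz << |k1|) are
    only partially recovered; the error this leaves on smooth phantoms
    is characterized in the test suite.
    """
    gv = _values(g)
    if geom.detector_stride != 1:
        raise ValueError("fft_reconstruct requires the full uniform "
                         "detector line (detector_stride == 1)")
    if gv.shape != (geom.n_det, geom.n_t):
        raise ValueError(f"data shape {gv.shape} does not match geometry")
    m, dt, dx, c = geom.m, geom.dt, geom.dx, geom.c
    n_t = geom.n_t
    P = lateral_pad * m
    off = (P - m) // 2
    gpad = np.zeros((P, n_t))
    gpad[off: off + m] = gv
    # cosine transform in t via an even extension (trapezoid weights)
    ge = np.concatenate([gpad, gpad[:, -2:0:-1]], axis=1)
    ct = 0.5 * dt * np.fft.fft(ge, axis=1).real[:, : n_t]
    omega_grid = np.pi * np.arange(n_t) / ((n_t - 1) * dt)
    Ghat = dx * np.fft.fft(ct, axis=0)  # (k1, omega)
    k1 = 2.0 * np.pi * np.fft.fftfreq(P, d=dx)
    # scale on the measured (k1, omega) grid, zeroing the evanescent set
    kz_of_w = np.sqrt(np.maximum(
        (omega_grid[None, :] / c) ** 2 - (k1[:, None]) ** 2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        sf = np.where(omega_grid[None, :] > 0,
                      4.0 * c * c * kz_of_w / omega_grid[None, :], 0.0)
    sf[omega_grid[None, :] <= c * np.abs(k1)[:, None]] = 0.0
    scaled = sf * Ghat
    # remap omega -> depth wavenumber on a uniform kz grid
    kz = 2.0 * np.pi * np.fft.fftfreq(2 * m, d=dx)
    omega_map = c * np.sqrt(k1[:, None] ** 2 + kz[None, :] ** 2)
    F_e = np.empty((P, 2 * m), dtype=complex)
    for i in range(P):
        F_e[i] = (np.interp(omega_map[i], omega_grid, scaled[i].real,
                            right=0.0)
                  + 1j * np.interp(omega_map[i], omega_grid,
                                   scaled[i].imag, right=0.0))
    # kz = 0 bin: even and smooth in kz, fit a + b kz^2 through bins 1, 2
    F_e[:, 0] = (4.0 * F_e[:, 1] - F_e[:, 2]) / 3.0
    img = np.fft.ifft2(F_e) / (dx * dx)  # axes (x1, z)
    imag_resid = np.abs(img.imag).max()
    out = img.real.T[:m, off: off + m]  # rows = depth, cols = lateral
    if imag_resid > 1e-10 * max(np.abs(out).max(), 1e-300):
        raise FloatingPointError(
            "conjugate symmetry violated: imaginary residual "
            f"{imag_resid:.2e}")
    return out


_SPECTRAL_CFL = 2.0 / (np.pi * np.sqrt(2.0))


def time_reversal(g, geom: AcousticGeometry) -> np.ndarray:
    """Reconstruct by re-emitting the data in time-reversed order.

    Leapfrog stepping with a spectral Laplacian on the padded grid; the
    recorded pressure is enforced as a time-varying Dirichlet condition
    at the detector nodes, and an exponential damping layer on the three
    non-detector edges absorbs the otherwise-periodic wrap-around.
    Returns the field after the full reversed record, restricted to the
    image window.
    """
    gv = _values(g)
    if gv.shape != (geom.n_det, geom.n_t):
        raise ValueError(f"data shape {gv.shape} does not match geometry")
    if geom.c * geom.dt / geom.dx > _SPECTRAL_CFL:
        raise ValueError(
            f"c*dt/dx = {geom.c * geom.dt / geom.dx:.3f} exceeds the "
            f"spectral leapfrog stability limit {_SPECTRAL_CFL:.3f}")
    n = geom.padded_size
    K2 = geom.wavenumber_magnitude() ** 2
    damp = _damping_mask(geom)
    det_cols = geom.col_offset + geom.detector_cols
    cdt2 = (geom.c * geom.dt) ** 2
    p_prev = np.zeros((n, n))
    p_cur = np.zeros((n, n))
    p_cur[0, det_cols] = gv[:, geom.n_t - 1]
    for k in range(geom.n_t - 2, -1, -1):
        lap = np.fft.ifft2(-K2 * np.fft.fft2(p_cur)).real
        p_next = 2.0 * p_cur - p_prev + cdt2 * lap
        p_next *= damp
        p_cur = p_cur * damp
        p_next[0, det_cols] = gv[:, k]
        p_prev, p_cur = p_cur, p_next
    off = geom.col_offset
    return p_cur[: geom.m, off: off + geom.m]


def _damping_mask(geom: AcousticGeometry) -> np.ndarray:
    """Exponential absorbing layer on the bottom / left / right edges."""
    n = geom.padded_size
    w = max(geom.m // 8, 4)
    sigma = np.zeros((n, n))
    edge = (np.arange(w)[::-1] + 1.0) / w
    sigma[:, :w] += edge[::-1][None, ::-1] ** 2  # left
    sigma[:, -w:] += (edge[::-1] ** 2)[None, :]  # right
    sigma[-w:, :] += (edge[::-1] ** 2)[:, None]  # bottom (top = detectors)
    return np.exp(-0.5 * sigma)


def iterative_time_reversal(g, geom: AcousticGeometry, n_iter: int = 5
                            ) -> tuple[np.ndarray, list[float]]:
    """Neumann-series refinement of time reversal.

    f_(n+1) = f_n - TR(A f_n - g), starting from f_0 = TR(g).  Returns
    the final iterate and the data-residual norms ||A f_n - g|| for
    n = 0 .. n_iter.
    """
    gv = _values(g)
    f = time_reversal(gv, geom)
    residuals = [float(np.linalg.norm(propagate(f, geom).values - gv))]
    for _ in range(n_iter):
        r = propagate(f, geom).values - gv
        f = f - time_reversal(r, geom)
        residuals.append(
            float(np.linalg.norm(propagate(f, geom).values - gv)))
    return f, residuals


def _as_operator(A):
    """Entries, output image shape, and sigma_max estimator for either a
    ForwardMatrix or a plain dense matrix."""
    if isinstance(A, ForwardMatrix):
        m = A.geometry.m
        return np.asarray(A.entries, float), (m, m), A.sigma_max
    entries = np.asarray(A, dtype=float)
    return entries, (entries.shape[1],), \
        lambda: float(np.linalg.norm(entries, 2))


def _step_size(sigma_max, cfg: VariationalConfig) -> float:
    return cfg.step if cfg.step is not None else 1.0 / sigma_max() ** 2


def gradient_descent(A, g, cfg: VariationalConfig
                     ) -> tuple[np.ndarray, list[float]]:
    """Landweber iteration for the least-squares problem min ||A f - g||^2.

    Runs ``cfg.n_iter`` steps of f <- f - eta A^T (A f - g) from f = 0
    and returns the final image together with the trace of the data
    misfit E(f) = 0.5 ||A f - g||^2 (n_iter + 1 values).  With the
    default step eta = 1/sigma_max^2 < 2/sigma_max^2 the trace is
    non-increasing.  ``A`` may be a ForwardMatrix (the result is an
    m-by-m image) or any dense matrix (the result is a flat vector).
    """
    entries, shape, smax = _as_operator(A)
    gv = _values(g).ravel()
    eta = _step_size(smax, cfg)
    f = np.zeros(entries.shape[1])
    trace = []
    for _ in range(cfg.n_iter):
        r = entries @ f - gv
        trace.append(0.5 * float(np.sum(r * r)))
        f = f - eta * (entries.T @ r)
    r = entries @ f - gv
    trace.append(0.5 * float(np.sum(r * r)))
    return f.reshape(shape), trace


def _tv_prox(h: np.ndarray, weight: float, n_iter: int) -> np.ndarray:
    """Isotropic TV proximal map by a fixed number of dual (Chambolle)
    projection iterations."""
    if weight <= 0:
        return h
    p = np.zeros((2,) + h.shape)
    tau = 0.25

    def divergence(p):
        div_p = np.zeros_like(h)
        div_p[:-1] += p[0, :-1]
        div_p[1:] -= p[0, :-1]
        div_p[:, :-1] += p[1, :, :-1]
        div_p[:, 1:] -= p[1, :, :-1]
        return div_p

    for _ in range(n_iter):
        u = h - weight * divergence(p)
        gx = np.zeros_like(h)
        gy = np.zeros_like(h)
        gx[:-1] = u[1:] - u[:-1]
        gy[:, :-1] = u[:, 1:] - u[:, :-1]
        norm = np.sqrt(gx * gx + gy * gy)
        p[0] = (p[0] - (tau / weight) * gx) / (1.0 + (tau / weight) * norm)
        p[1] = (p[1] - (tau / weight) * gy) / (1.0 + (tau / weight) * norm)
    return h - weight * divergence(p)


def proximal_gradient(A, g, cfg: VariationalConfig) -> np.ndarray:
    """Proximal-gradient iteration: gradient step on the data term, then
    the proximal map of the regularizer (identity / non-negativity clip /
    fixed-iteration dual TV).  The TV prox requires a 2D image, hence a
    ForwardMatrix."""
    entries, shape, smax = _as_operator(A)
    if cfg.regularizer == "tv" and len(shape) != 2:
        raise ValueError("tv regularizer needs an image-shaped operator")
    gv = _values(g).ravel()
    eta = _step_size(smax, cfg)
    f = np.zeros(entries.shape[1])
    for _ in range(cfg.n_iter):
        f = f - eta * (entries.T @ (entries @ f - gv))
        if cfg.regularizer == "nonneg":
            f = np.maximum(f, 0.0)
        elif cfg.regularizer == "tv":
            f = _tv_prox(f.reshape(shape), eta * cfg.reg_weight,
                         cfg.tv_inner_iters).ravel()
    return f.reshape(shape)


def tikhonov_solve(A, g, alpha: float) -> np.ndarray:
    """Closed-form quadratically regularized solution
    f = (A^T A + alpha I)^(-1) A^T g via a symmetric positive-definite
    solve."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    entries, shape, _ = _as_operator(A)
    M = entries.shape[1]
    H = entries.T @ entries + alpha * np.eye(M)
    b = entries.T @ _values(g).ravel()
    cho = scipy.linalg.cho_factor(H, check_finite=False)
    fv = scipy.linalg.cho_solve(cho, b, check_finite=False)
    resid = np.linalg.norm(H @ fv - b)
    if resid > 1e-8 * max(np.linalg.norm(b), 1e-300):
        raise FloatingPointError(
            f"normal-equation residual {resid:.2e} too large")
    return fv.reshape(shape)


@dataclass
class NullspaceProjector:
    """Orthogonal projector onto null(A), stored densely (M x M)."""

    matrix: np.ndarray
    fingerprint: str
    rank: int

    def __call__(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, float)
        shape = image.shape
        return (self.matrix @ image.ravel()).reshape(shape)


def nullspace_projector(A: ForwardMatrix,
                        rank_rtol: float = 1e-10) -> NullspaceProjector:
    """Projector onto the null space of A via a rank-revealing SVD.

    Adding P v to a reconstruction leaves A f unchanged, which is the
    basis of data-consistent post-processing.  Dense decomposition: only
    intended for small systems (m <= 32 enforced).
    """
    if A.geometry.m > 32:
        raise ValueError("nullspace_projector requires m <= 32 "
                         "(full dense decomposition)")
    At = np.asarray(A.entries, dtype=np.float64)
    _, s, Vt = np.linalg.svd(At, full_matrices=True)
    rank = int(np.sum(s > rank_rtol * s[0]))
    Vnull = Vt[rank:].T
    P = Vnull @ Vnull.T
    return NullspaceProjector(P, A.fingerprint, rank)


def data_consistent_correct(f0: np.ndarray, correction: np.ndarray,
                            P: NullspaceProjector) -> np.ndarray:
    """Apply a correction restricted to components invisible to A:
    returns f0 + P(correction), so the data fit of f0 is preserved."""
    return np.asarray(f0, float) + P(correction)
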