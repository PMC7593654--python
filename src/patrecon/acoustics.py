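"""Homogeneous-medium 2D acoustic forward model for photoacoustic tomography.

The initial-value problem

    p_tt = c^2 Laplacian(p),   p(x, 0) = f(x),   p_t(x, 0) = 0

has, for a homogeneous medium, the exact spectral solution

    p_hat(k, t) = f_hat(k) * cos(c |k| t),

which this module evaluates on a zero-padded periodic grid.  The
measurement operator samples the pressure field at point detectors placed
on a line along the top edge of the image (a one-sided, limited-view
geometry).  Because the map f -> g is linear, it can be assembled once as
a dense matrix A with adjoint A^T, which is the workhorse object for the
variational and learned reconstruction modules.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "AcousticGeometry", "TimeSeries", "ForwardMatrix", "NoiseModel",
    "propagate", "assemble_forward_matrix", "apply_forward",
    "apply_adjoint", "add_noise", "save_matrix", "load_matrix",
]


@dataclass(frozen=True)
class AcousticGeometry:
    """Discretization of the acoustic forward operator.

    Parameters
    ----------
    m : int
        Image grid size (pixels per side); the image occupies rows
        ``0..m-1`` with the detector line on row 0.
    dx : float
        Grid spacing (dimensionless by default).
    c : float
        Sound speed.
    dt : float
        Time step.  Must satisfy ``c * dt / dx <= 1``.
    n_t : int or None
        Number of time samples; the default records until the signal from
        the far corner (diagonal extent ``2*sqrt(2)*m*dx``) has reached
        the detector line.
    detector_stride : int
        Keep every ``detector_stride``-th node of row 0 as a detector
        (1 = full-width line).
    pad_factor : int
        The propagation grid has side ``pad_factor * m``; padding delays
        periodic wrap-around of out-going waves.
    """

    m: int
    dx: float = 1.0
    c: float = 1.0
    dt: float = 0.3
    n_t: int | None = None
    detector_stride: int = 1
    pad_factor: int = 4

    def __post_init__(self):
        if self.m < 4:
            raise ValueError(f"m must be >= 4, got {self.m}")
        if self.dx <= 0 or self.c <= 0 or self.dt <= 0:
            raise ValueError("dx, c, dt must be positive")
        if self.c * self.dt / self.dx > 1.0:
            raise ValueError(
                f"c*dt/dx = {self.c * self.dt / self.dx:.3f} > 1: "
                "time step too large for the grid")
        if self.pad_factor < 2:
            raise ValueError("pad_factor must be >= 2")
        if self.detector_stride < 1 or self.detector_stride >= self.m:
            raise ValueError("detector_stride must be in [1, m)")
        if self.n_t is None:
            n_t = int(np.ceil(2.0 * np.sqrt(2.0) * self.m * self.dx
                              / (self.c * self.dt)))
            object.__setattr__(self, "n_t", n_t)
        if self.n_t < 2:
            raise ValueError("n_t must be >= 2")

    # -- derived quantities -------------------------------------------------

    @property
    def padded_size(self) -> int:
        return self.pad_factor * self.m

    @property
    def col_offset(self) -> int:
        """Column of the padded grid where the image window starts."""
        return (self.padded_size - self.m) // 2

    @property
    def detector_cols(self) -> np.ndarray:
        """Detector node columns in image coordinates (row 0)."""
        return np.arange(0, self.m, self.detector_stride)

    @property
    def n_det(self) -> int:
        return len(self.detector_cols)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_t) * self.dt

    def wavenumber_magnitude(self) -> np.ndarray:
        """|k| on the padded FFT grid."""
        n = self.padded_size
        k1 = 2.0 * np.pi * np.fft.fftfreq(n, d=self.dx)
        return np.sqrt(k1[:, None] ** 2 + k1[None, :] ** 2)

    @property
    def fingerprint(self) -> str:
        key = (self.m, self.dx, self.c, self.dt, self.n_t,
               self.detector_stride, self.pad_factor)
        return hashlib.sha1(repr(key).encode()).hexdigest()[:16]

    def pad_image(self, f: np.ndarray) -> np.ndarray:
        n = self.padded_size
        out = np.zeros((n, n), dtype=float)
        out[: self.m, self.col_offset: self.col_offset + self.m] = f
        return out


@dataclass
class TimeSeries:
    """Detector data g: an (n_det, n_t) array tagged with the geometry."""

    values: np.ndarray
    fingerprint: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be 2D (n_det, n_t)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class NoiseModel:
    """Additive i.i.d. Gaussian measurement noise.

    ``relative_std`` is the standard deviation as a fraction of the
    maximum absolute measurement amplitude (default 1%).
    """

    relative_std: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.relative_std < 0:
            raise ValueError("relative_std must be >= 0")


def _check_image(f: np.ndarray, geom: AcousticGeometry) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.shape != (geom.m, geom.m):
        raise ValueError(
            f"image shape {f.shape} does not match geometry m={geom.m}")
    return f


def propagate(f: np.ndarray, geom: AcousticGeometry,
              time_chunk: int = 64) -> TimeSeries:
    """Propagate an initial pressure image and sample it at the detectors.

    Exact spectral solution of the wave initial-value problem on the
    padded grid; sample k of detector d is the pressure at the detector
    node at time ``k * dt``.  Linear in ``f``; signed inputs are allowed
    (required for adjoint arithmetic).
    """
    f = _check_image(f, geom)
    n = geom.padded_size
    F = np.fft.fft2(geom.pad_image(f))
    K = geom.wavenumber_magnitude()
    t = geom.times
    det_cols = geom.col_offset + geom.detector_cols
    g = np.empty((geom.n_det, geom.n_t))
    for start in range(0, geom.n_t, time_chunk):
        tk = t[start: start + time_chunk]
        cosk = np.cos(geom.c * K[None, :, :] * tk[:, None, None])
        # evaluate the inverse 2D FFT on row 0 only: sum over the row
        # frequencies, then a 1D inverse FFT along the columns
        line = np.fft.ifft((F[None, :, :] * cosk).sum(axis=1) / n, axis=1)
        g[:, start: start + len(tk)] = line[:, det_cols].real.T
    return TimeSeries(g, geom.fingerprint)


@dataclass
class ForwardMatrix:
    """Dense matrix representation of the acoustic forward operator.

    ``entries`` has shape (T, M) with ``T = n_det * n_t`` and ``M = m**2``;
    row ``d * n_t + k`` is detector d at time sample k, column ``r * m + c``
    is the image pixel (r, c).  The adjoint is the matrix transpose.
    """

    entries: np.ndarray
    geometry: AcousticGeometry
    precision: str = "float64"
    _sigma_max: float | None = field(default=None, repr=False, compare=False)

    @property
    def fingerprint(self) -> str:
        return self.geometry.fingerprint

    @property
    def shape(self):
        return self.entries.shape

    def sigma_max(self, n_iter: int = 60, seed: int = 0) -> float:
        """Largest singular value, estimated by power iteration (cached)."""
        if self._sigma_max is None:
            A = self.entries
            rng = np.random.default_rng(seed)
            v = rng.standard_normal(A.shape[1])
            v /= np.linalg.norm(v)
            s = 0.0
            for _ in range(n_iter):
                w = A.T @ (A @ v)
                s = np.linalg.norm(w)
                if s == 0:
                    break
                v = w / s
            self._sigma_max = float(np.sqrt(s))
        return self._sigma_max


def assemble_forward_matrix(geom: AcousticGeometry,
                            precision: str = "float64",
                            memory_budget_bytes: int = 4 << 30,
                            ) -> ForwardMatrix:
    """Assemble the dense forward matrix A for a geometry.

    Column j of A equals the vectorized output of ``propagate`` applied to
    the unit image at pixel j.  Assembly exploits the translation
    invariance of the propagator: for each time sample the map from image
    to pressure field is a circulant convolution, so one kernel per time
    step suffices instead of one propagation per pixel.

    Refuses to allocate if the dense storage would exceed
    ``memory_budget_bytes`` (size estimated with
    :func:`patrecon.learned.estimate_dense_layer_memory`).
    """
    from .learned import estimate_dense_layer_memory  # local: avoid cycle

    if precision not in ("float32", "float64"):
        raise ValueError(f"precision must be float32|float64, got {precision}")
    itemsize = 4 if precision == "float32" else 8
    M = geom.m ** 2
    T = geom.n_det * geom.n_t
    need = estimate_dense_layer_memory(M, T, itemsize)
    if need > memory_budget_bytes:
        raise MemoryError(
            f"forward matrix would need {need} bytes "
            f"({need / 2**30:.1f} GiB) > budget {memory_budget_bytes}")

    n = geom.padded_size
    m = geom.m
    K = geom.wavenumber_magnitude()
    t = geom.times
    det_cols = geom.col_offset + geom.detector_cols
    # entry[d, r, c] = kernel[(0 - r) mod n, (det_col_d - (off + c)) mod n]
    row_idx = (-np.arange(m)) % n
    col_idx = (det_cols[:, None, None]
               - (geom.col_offset + np.arange(m))[None, None, :]) % n
    A = np.empty((T, M), dtype=precision)
    det_rows = np.arange(geom.n_det) * geom.n_t
    for k in range(geom.n_t):
        kernel = np.fft.ifft2(np.cos(geom.c * K * t[k])).real
        block = kernel[row_idx[None, :, None], col_idx]
        A[det_rows + k, :] = block.reshape(geom.n_det, M)
    return ForwardMatrix(A, geom, precision)


def apply_forward(A: ForwardMatrix, f: np.ndarray) -> TimeSeries:
    """g = A vec(f), reshaped to (n_det, n_t)."""
    geom = A.geometry
    f = _check_image(f, geom)
    g = (A.entries @ f.ravel()).reshape(geom.n_det, geom.n_t)
    return TimeSeries(np.asarray(g, dtype=float), geom.fingerprint)


def apply_adjoint(A: ForwardMatrix, g: TimeSeries | np.ndarray) -> np.ndarray:
    """f = A^T vec(g), reshaped to (m, m)."""
    geom = A.geometry
    if isinstance(g, TimeSeries):
        if g.fingerprint != A.fingerprint:
            raise ValueError(
                "time series fingerprint does not match matrix geometry")
        gv = g.values
    else:
        gv = np.asarray(g, dtype=float)
    if gv.shape != (geom.n_det, geom.n_t):
        raise ValueError(
            f"data shape {gv.shape} does not match geometry "
            f"({geom.n_det}, {geom.n_t})")
    return np.asarray(A.entries.T @ gv.ravel(), dtype=float
                      ).reshape(geom.m, geom.m)


def add_noise(g: TimeSeries, noise: NoiseModel) -> TimeSeries:
    """Return g + eps with eps ~ N(0, (relative_std * max|g|)^2), seeded."""
    if noise.relative_std == 0:
        return TimeSeries(g.values.copy(), g.fingerprint)
    rng = np.random.default_rng(noise.seed)
    std = noise.relative_std * np.max(np.abs(g.values))
    eps = rng.normal(0.0, std, size=g.values.shape)
    return TimeSeries(g.values + eps, g.fingerprint)


# -- persistence ------------------------------------------------------------

def save_matrix(path, A: ForwardMatrix) -> None:
    g = A.geometry
    with h5py.File(path, "w") as h:
        d = h.create_dataset("A", data=A.entries)
        d.attrs.update({
            "m": g.m, "dx": g.dx, "c": g.c, "dt": g.dt, "n_t": g.n_t,
            "detector_indices": g.detector_cols,
            "detector_stride": g.detector_stride,
            "pad_factor": g.pad_factor, "precision": A.precision,
            "fingerprint": g.fingerprint,
        })


def load_matrix(path) -> ForwardMatrix:
    with h5py.File(path, "r") as h:
        d = h["A"]
        a = d.attrs
        geom = AcousticGeometry(
            m=int(a["m"]), dx=float(a["dx"]), c=float(a["c"]),
            dt=float(a["dt"]), n_t=int(a["n_t"]),
            detector_stride=int(a["detector_stride"]),
            pad_factor=int(a["pad_factor"]))
        if a["fingerprint"] != geom.fingerprint:
            raise ValueError("stored fingerprint does not match attributes")
        return ForwardMatrix(d[()], geom, str(a["precision"]))
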