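"""Learned reconstruction architectures.

Three prototypical ways of putting a neural network into the PAT
reconstruction pipeline, ordered by how often the acoustic model is used:

* **fully learned** (:func:`build_fully_learned`) — one network maps the
  raw time series directly to the image: three dense layers with ELU
  nonlinearity and bias, reshaped to an image and post-processed by a
  small CNN (3 layers, 32 channels) with a final 1-channel ReLU layer
  that enforces non-negativity of the initial pressure.  The model never
  sees the acoustic operator, so it must learn the (non-local)
  data-to-image geometry from scratch, and its dense layers tie it to a
  fixed acquisition geometry.

* **post-processing** (:func:`build_postproc`) — a classical operator
  (by default the adjoint) produces an initial image and a residual
  U-Net (3 scales, 2 convs per scale, channel schedule 32/64/128,
  max-pool down, transposed-conv up, concatenating skips) learns a
  correction.  With the final layer zero-initialized the untrained
  network is exactly the identity on its input.

* **learned gradient scheme** (:func:`build_learned_gradient`) — an
  unrolled iterative reconstruction: starting from f0 = A^T g, each of N
  blocks receives the current iterate and the data-consistency gradient
  A^T (A f - g) as a two-channel image and adds a learned residual
  update.  Per-block parameters are untied.

:func:`estimate_dense_layer_memory` quantifies why the fully learned
route does not scale: a single dense layer between data and image space
stores (voxels x samples) weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .acoustics import ForwardMatrix, TimeSeries

__all__ = [
    "FullyLearnedSpec", "PostprocUNetSpec", "LearnedGradientSpec",
    "FullyLearnedReconstructor", "PostprocUNetReconstructor",
    "LearnedGradientReconstructor", "build_fully_learned",
    "build_postproc", "build_learned_gradient",
    "estimate_dense_layer_memory", "format_gib",
]


def estimate_dense_layer_memory(image_voxels: int, data_samples: int,
                                bytes_per_element: int) -> int:
    """Bytes needed to store a dense layer between data and image space."""
    if min(image_voxels, data_samples, bytes_per_element) < 1:
        raise ValueError("all arguments must be positive integers")
    return int(image_voxels) * int(data_samples) * int(bytes_per_element)


def format_gib(n_bytes: int) -> str:
    """Format a byte count in units of 2^30 bytes."""
    return f"{n_bytes / 2**30:.1f} GiB"


# -- architecture specs -----------------------------------------------------

@dataclass(frozen=True)
class FullyLearnedSpec:
    """Dense widths default to m^2 per hidden layer (set at build time);
    the last width must equal m^2 so the output can be reshaped to an
    image."""

    dense_widths: tuple[int, int, int] | None = None
    cnn_channels: int = 32
    cnn_layers: int = 3
    kernel: int = 3
    seed: int = 0


@dataclass(frozen=True)
class PostprocUNetSpec:
    scales: int = 3
    convs_per_scale: int = 2
    base_channels: int = 32
    kernel: int = 3
    seed: int = 0

    def channel_schedule(self) -> list[int]:
        return [self.base_channels * 2 ** s for s in range(self.scales)]


@dataclass(frozen=True)
class LearnedGradientSpec:
    n_unrolled: int = 5
    channels: int = 32
    conv_layers: int = 3
    kernel: int = 3
    seed: int = 0


# -- fully learned ----------------------------------------------------------

class FullyLearnedReconstructor(nn.Module):
    """Dense stack + small CNN mapping raw time series to the image."""

    def __init__(self, spec: FullyLearnedSpec, n_det: int, n_t: int,
                 m: int):
        widths = spec.dense_widths or (m * m, m * m, m * m)
        if len(widths) != 3:
            raise ValueError("dense_widths must have exactly 3 entries")
        if widths[-1] != m * m:
            raise ValueError(
                f"last dense width {widths[-1]} must equal m^2 = {m * m} "
                "so the output can be reshaped to an image")
        self.spec = spec
        self.n_det, self.n_t, self.m = n_det, n_t, m
        rng = np.random.default_rng(spec.seed)
        sizes = [n_det * n_t, *widths]
        self.dense = [nn.Linear(sizes[i], sizes[i + 1], rng, f"dense{i}")
                      for i in range(3)]
        chans = [1] + [spec.cnn_channels] * spec.cnn_layers
        self.convs = [nn.Conv2d(chans[i], chans[i + 1], spec.kernel, rng,
                                f"conv{i}") for i in range(spec.cnn_layers)]
        self.final = nn.Conv2d(spec.cnn_channels, 1, spec.kernel, rng,
                               "final")

    def forward(self, g: np.ndarray) -> nn.Tensor:
        """g: (B, n_det, n_t) raw time series -> (B, m, m) image, >= 0.

        Each sample is normalized by its maximum absolute amplitude
        before entering the dense layers.
        """
        g = np.asarray(g, float)
        if g.ndim == 2:
            g = g[None]
        if g.shape[1:] != (self.n_det, self.n_t):
            raise ValueError(
                f"data shape {g.shape[1:]} does not match the trained "
                f"geometry ({self.n_det}, {self.n_t}); dense layers are "
                "specific to a fixed acquisition")
        B = g.shape[0]
        norm = np.abs(g).reshape(B, -1).max(axis=1)
        norm[norm == 0] = 1.0
        x = nn.Tensor(g.reshape(B, -1) / norm[:, None])
        for lin in self.dense:
            x = nn.elu(lin(x))
        x = nn.reshape(x, (B, 1, self.m, self.m))
        for conv in self.convs:
            x = nn.relu(conv(x))
        x = nn.relu(self.final(x))
        return nn.reshape(x, (B, self.m, self.m))

    __call__ = forward

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_fully_learned(spec: FullyLearnedSpec, n_det: int, n_t: int,
                        m: int) -> FullyLearnedReconstructor:
    return FullyLearnedReconstructor(spec, n_det, n_t, m)


# -- post-processing residual U-Net ----------------------------------------

class _UNet(nn.Module):
    def __init__(self, spec: PostprocUNetSpec, rng: np.random.Generator):
        ch = spec.channel_schedule()  # e.g. [32, 64, 128]
        k = spec.kernel
        self.enc = []
        c_in = 1
        for s in range(spec.scales - 1):
            stage = []
            for j in range(spec.convs_per_scale):
                stage.append(nn.Conv2d(c_in, ch[s], k, rng,
                                       f"enc{s}_{j}"))
                c_in = ch[s]
            self.enc.append(stage)
        self.bottom = []
        for j in range(spec.convs_per_scale):
            self.bottom.append(nn.Conv2d(c_in, ch[-1], k, rng,
                                         f"bottom{j}"))
            c_in = ch[-1]
        self.up = []
        self.dec = []
        for s in range(spec.scales - 2, -1, -1):
            self.up.append(nn.ConvTranspose2d(c_in, ch[s], rng, f"up{s}"))
            stage = []
            c_in = 2 * ch[s]  # concatenated skip
            for j in range(spec.convs_per_scale):
                stage.append(nn.Conv2d(c_in, ch[s], k, rng,
                                       f"dec{s}_{j}"))
                c_in = ch[s]
            self.dec.append(stage)
        self.final = nn.Conv2d(c_in, 1, k, rng, "final", zero_init=True)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        skips = []
        for stage in self.enc:
            for conv in stage:
                x = nn.relu(conv(x))
            skips.append(x)
            x = nn.maxpool2d(x)
        for conv in self.bottom:
            x = nn.relu(conv(x))
        for up, stage in zip(self.up, self.dec):
            x = nn.relu(up(x))
            x = nn.concat_channels(x, skips.pop())
            for conv in stage:
                x = nn.relu(conv(x))
        return self.final(x)


class PostprocUNetReconstructor(nn.Module):
    """Residual U-Net acting on an initial classical reconstruction.

    ``forward`` consumes initial-reconstruction images (the training
    pipeline builds them once); ``reconstruct`` runs initializer +
    network on raw data.
    """

    def __init__(self, spec: PostprocUNetSpec, m: int,
                 initializer: str = "adjoint"):
        if m % 2 ** (spec.scales - 1) != 0:
            raise ValueError(
                f"image size {m} not divisible by 2^{spec.scales - 1}")
        self.spec = spec
        self.m = m
        self.initializer = initializer
        self.unet = _UNet(spec, np.random.default_rng(spec.seed))

    def forward(self, f0: np.ndarray) -> nn.Tensor:
        f0 = np.asarray(f0, float)
        if f0.ndim == 2:
            f0 = f0[None]
        if f0.shape[1:] != (self.m, self.m):
            raise ValueError(f"image shape {f0.shape[1:]} != "
                             f"({self.m}, {self.m})")
        x = nn.Tensor(f0[:, None])
        out = nn.add(x, self.unet(x))
        return nn.reshape(out, f0.shape)

    __call__ = forward

    def reconstruct(self, A: ForwardMatrix, g) -> np.ndarray:
        from .acoustics import apply_adjoint
        from . import classical
        gv = g.values if isinstance(g, TimeSeries) else np.asarray(g, float)
        if self.initializer == "adjoint":
            f0 = apply_adjoint(A, gv)
        elif self.initializer == "das":
            f0 = classical.delay_and_sum(gv, A.geometry)
        else:
            raise ValueError(f"unknown initializer {self.initializer!r}")
        with nn.no_grad():
            return self.forward(f0[None]).data[0]

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_postproc(spec: PostprocUNetSpec, m: int,
                   initializer: str = "adjoint"
                   ) -> PostprocUNetReconstructor:
    return PostprocUNetReconstructor(spec, m, initializer)


# -- unrolled learned gradient scheme ---------------------------------------

class _ResidualBlock(nn.Module):
    """(f, scaled gradient) -> residual update: conv layers with ReLU and
    bias, then a linear 1-channel conv without bias (zero-initialized so
    the untrained scheme reduces to f0 = A^T g)."""

    def __init__(self, spec: LearnedGradientSpec, idx: int,
                 rng: np.random.Generator):
        k = spec.kernel
        chans = [2] + [spec.channels] * spec.conv_layers
        self.convs = [nn.Conv2d(chans[i], chans[i + 1], k, rng,
                                f"block{idx}.conv{i}")
                      for i in range(spec.conv_layers)]
        self.final = nn.Conv2d(spec.channels, 1, k, rng,
                               f"block{idx}.final", bias=False,
                               zero_init=True)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for conv in self.convs:
            x = nn.relu(conv(x))
        return self.final(x)


class LearnedGradientReconstructor(nn.Module):
    """Unrolled gradient descent with learned per-iteration updates.

    f_(n+1) = f_n + block_n(f_n, s * A^T(A f_n - g)), f_0 = A^T g, where
    s = grad_scale (default 1/sigma_max(A)^2) normalizes the gradient
    image scale across geometries.
    """

    def __init__(self, spec: LearnedGradientSpec, A: ForwardMatrix,
                 grad_scale: float | str = "auto"):
        self.spec = spec
        self.A = A
        self.m = A.geometry.m
        self.n_det, self.n_t = A.geometry.n_det, A.geometry.n_t
        self.grad_scale = (1.0 / A.sigma_max() ** 2
                           if grad_scale == "auto" else float(grad_scale))
        rng = np.random.default_rng(spec.seed)
        self.blocks = [_ResidualBlock(spec, i, rng)
                       for i in range(spec.n_unrolled)]

    def _check_data(self, g) -> np.ndarray:
        if isinstance(g, TimeSeries):
            if g.fingerprint != self.A.fingerprint:
                raise ValueError("time series fingerprint does not match "
                                 "the forward matrix geometry")
            g = g.values
        g = np.asarray(g, dtype=self.A.entries.dtype)
        if g.ndim == 2:
            g = g[None]
        if g.shape[1:] != (self.n_det, self.n_t):
            raise ValueError(f"data shape {g.shape[1:]} != "
                             f"({self.n_det}, {self.n_t})")
        return g

    def gradient_image(self, f: nn.Tensor, g_flat: np.ndarray
                       ) -> nn.Tensor:
        """A^T (A f - g) as a flattened batch, through the autodiff tape."""
        Af = nn.matmul(f, self.A.entries.T)
        return nn.matmul(nn.sub(Af, g_flat), self.A.entries)

    def iterate(self, f: nn.Tensor, g_flat: np.ndarray, idx: int
                ) -> nn.Tensor:
        """One unrolled iteration with block ``idx``."""
        B = f.data.shape[0]
        d = nn.scale(self.gradient_image(f, g_flat), self.grad_scale)
        two = nn.concat_channels(
            nn.reshape(f, (B, 1, self.m, self.m)),
            nn.reshape(d, (B, 1, self.m, self.m)))
        upd = self.blocks[idx](two)
        return nn.add(f, nn.reshape(upd, (B, self.m * self.m)))

    def forward(self, g, n_blocks: int | None = None) -> nn.Tensor:
        g = self._check_data(g)
        B = g.shape[0]
        g_flat = g.reshape(B, -1)
        f = nn.Tensor(g_flat @ self.A.entries)  # f0 = A^T g
        n = len(self.blocks) if n_blocks is None else n_blocks
        for i in range(n):
            f = self.iterate(f, g_flat, i)
        return nn.reshape(f, (B, self.m, self.m))

    __call__ = forward

    def reconstruct(self, g) -> np.ndarray:
        with nn.no_grad():
            out = self.forward(g)
        return out.data[0] if out.data.shape[0] == 1 else out.data

    def set_fixed_step(self, eta: float) -> None:
        """Configure every block to implement the plain gradient step
        (f, d) -> -eta * d exactly (the degenerate scheme whose only
        parameter is the step length).  Uses the identity
        x = relu(x) - relu(-x) to pass the signed gradient through the
        ReLU layers."""
        for block in self.blocks:
            for conv in block.convs:
                conv.weight.data[:] = 0.0
                if conv.bias is not None:
                    conv.bias.data[:] = 0.0
            c0 = block.convs[0]
            k = c0.weight.data.shape[-1] // 2
            # channel 0 carries relu(d), channel 1 carries relu(-d)
            c0.weight.data[0, 1, k, k] = 1.0
            c0.weight.data[1, 1, k, k] = -1.0
            for conv in block.convs[1:]:
                conv.weight.data[0, 0, k, k] = 1.0
                conv.weight.data[1, 1, k, k] = 1.0
            block.final.weight.data[:] = 0.0
            # output = -eta/grad_scale * (relu(d) - relu(-d)) applied to
            # the scaled gradient equals -eta * raw gradient
            block.final.weight.data[0, 0, k, k] = -eta / self.grad_scale
            block.final.weight.data[0, 1, k, k] = eta / self.grad_scale

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_learned_gradient(spec: LearnedGradientSpec, A: ForwardMatrix,
                           grad_scale: float | str = "auto"
                           ) -> LearnedGradientReconstructor:
    return LearnedGradientReconstructor(spec, A, grad_scale)
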