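"""Supervised training for the learned reconstructors.

Covers the standard regimes:

* :func:`train_supervised` — minimize the mean squared error between
  network output and ground truth with Adam (initial learning rate 1e-4,
  batch size 4 by default), with an optional L1 penalty on the
  parameters (used for the fully learned model to curb overfitting).
* :func:`train_end_to_end_unrolled` — the same loss backpropagated
  through every unrolled iterate of a learned gradient scheme,
  forward/adjoint products included.
* :func:`train_greedy_unrolled` — block-wise training: block n is fitted
  against the ground truth with blocks 0..n-1 frozen; the inputs to
  block n (iterate and gradient image) can then be precomputed once,
  decoupling training from model evaluation.
* :func:`transfer_update` — resume from a checkpoint on a new dataset at
  a reduced learning rate, optionally updating only a subset of layers.

Everything is seeded; a checkpoint carries its full provenance (config,
seeds, dataset manifest) so runs are reproducible bit for bit on one
machine.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .acoustics import ForwardMatrix, NoiseModel, add_noise, \
    apply_adjoint, apply_forward
from .learned import LearnedGradientReconstructor

__all__ = [
    "TrainConfig", "PairedDataset", "make_training_pairs",
    "train_supervised", "train_end_to_end_unrolled",
    "train_greedy_unrolled", "transfer_update", "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Supervised-training settings (squared-L2 loss, Adam)."""

    learning_rate: float = 1e-4
    batch_size: int = 4
    total_iterations: int = 50_000
    param_l1_weight: float = 0.0
    validation_fraction: float = 0.1
    log_interval: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass
class PairedDataset:
    """Aligned (input, target) arrays plus a regeneration manifest."""

    inputs: np.ndarray
    targets: np.ndarray
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.inputs) != len(self.targets):
            raise ValueError("input/target counts differ")

    def __len__(self):
        return len(self.inputs)


def make_training_pairs(images: np.ndarray, A: ForwardMatrix,
                        noise: NoiseModel | None, mode: str,
                        manifest: dict | None = None) -> PairedDataset:
    """Simulate measurement data for ground-truth images.

    mode="raw" pairs the noisy time series g_i with f_i (for fully
    learned and unrolled schemes); mode="postproc" pairs the adjoint
    reconstruction A^T g_i with f_i.  Per-image noise seeds are derived
    from the noise model's base seed so the dataset is a pure function
    of (images, A, noise, mode).
    """
    if mode not in ("raw", "postproc"):
        raise ValueError(f"mode must be raw|postproc, got {mode!r}")
    images = np.asarray(images, float)
    n = len(images)
    inputs = []
    for i in range(n):
        g = apply_forward(A, images[i])
        if noise is not None and noise.relative_std > 0:
            seed_i = int(np.random.SeedSequence(
                (noise.seed, i)).generate_state(1)[0] % (2 ** 31))
            g = add_noise(g, NoiseModel(noise.relative_std, seed_i))
        if mode == "raw":
            inputs.append(g.values)
        else:
            inputs.append(apply_adjoint(A, g))
    record = {
        "mode": mode,
        "noise_relative_std": 0.0 if noise is None else noise.relative_std,
        "noise_seed": 0 if noise is None else noise.seed,
        "geometry_fingerprint": A.fingerprint,
        "n": n,
    }
    if manifest:
        record["images"] = manifest
    return PairedDataset(np.stack(inputs), images.copy(), record)


def _split(n: int, fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(round(fraction * n))
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def _batch_stream(n_train: int, batch_size: int, total: int, seed: int):
    """Yield per-iteration index batches, reshuffling every epoch."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_train)
    pos = 0
    for _ in range(total):
        if pos + batch_size > n_train:
            order = rng.permutation(n_train)
            pos = 0
        yield order[pos: pos + batch_size]
        pos += batch_size


def _eval_loss(model, inputs, targets, batch_size=8) -> float:
    if len(inputs) == 0:
        return float("nan")
    total, count = 0.0, 0
    with nn.no_grad():
        for s in range(0, len(inputs), batch_size):
            out = model(inputs[s: s + batch_size])
            diff = out.data - targets[s: s + batch_size]
            total += float(np.sum(diff * diff))
            count += diff.size
    return total / count


def train_supervised(model, dataset: PairedDataset, cfg: TrainConfig,
                     frozen: set[str] | None = None
                     ) -> tuple[dict, pd.DataFrame]:
    """Minimize mean squared error on the dataset; returns (checkpoint,
    history).  The checkpoint holds the final parameters and full
    provenance; the history records train/validation loss every
    ``log_interval`` iterations.  Aborts on non-finite loss.
    """
    train_idx, val_idx = _split(len(dataset), cfg.validation_fraction,
                                cfg.seed)
    if len(train_idx) == 0:
        raise ValueError("empty training split")
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate,
                  l1_weight=cfg.param_l1_weight, frozen=frozen)
    rows = []
    stream = _batch_stream(len(train_idx),
                           min(cfg.batch_size, len(train_idx)),
                           cfg.total_iterations, cfg.seed + 1)
    for it, batch in enumerate(stream, start=1):
        idx = train_idx[batch]
        loss = nn.mse_loss(model(dataset.inputs[idx]),
                           dataset.targets[idx])
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"non-finite training loss at iteration {it}: {loss.data}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if it % cfg.log_interval == 0 or it == cfg.total_iterations:
            rows.append({
                "iteration": it,
                "train_loss": float(loss.data),
                "val_loss": _eval_loss(model, dataset.inputs[val_idx],
                                       dataset.targets[val_idx]),
            })
    history = pd.DataFrame(rows,
                           columns=["iteration", "train_loss", "val_loss"])
    checkpoint = {
        "state": model.state_dict(),
        "provenance": {
            "config": dataclasses.asdict(cfg),
            "dataset_manifest": dataset.manifest,
            "n_train": int(len(train_idx)),
            "n_val": int(len(val_idx)),
            "frozen": sorted(frozen) if frozen else [],
        },
    }
    return checkpoint, history


def train_end_to_end_unrolled(model: LearnedGradientReconstructor,
                              dataset: PairedDataset, cfg: TrainConfig
                              ) -> tuple[dict, pd.DataFrame]:
    """End-to-end training of an unrolled scheme: gradients flow through
    all N iterates including the forward/adjoint products.  Requires raw
    time-series inputs."""
    if dataset.manifest.get("mode", "raw") != "raw":
        raise ValueError("end-to-end training needs raw time-series pairs")
    ckpt, history = train_supervised(model, dataset, cfg)
    ckpt["provenance"]["training_mode"] = "end_to_end"
    return ckpt, history


class _BlockHead(nn.Module):
    """Loss head for greedy training on precomputed block inputs."""

    def __init__(self, lgs: LearnedGradientReconstructor, idx: int):
        self.block = lgs.blocks[idx]
        self.m = lgs.m

    def __call__(self, packed: np.ndarray) -> nn.Tensor:
        # packed: (B, 2, m, m): current iterate and scaled gradient
        x = nn.Tensor(packed)
        upd = self.block(x)
        f = nn.Tensor(packed[:, 0])
        return nn.add(f, nn.reshape(upd, f.data.shape))


class _OnTheFlyHead(nn.Module):
    """Greedy head that recomputes the frozen prefix for every batch."""

    def __init__(self, lgs: LearnedGradientReconstructor, idx: int):
        self._lgs = [lgs]  # boxed: keep prefix out of parameter discovery
        self.block = lgs.blocks[idx]
        self.idx = idx

    def __call__(self, g: np.ndarray) -> nn.Tensor:
        lgs = self._lgs[0]
        g_flat = np.asarray(g, dtype=lgs.A.entries.dtype
                            ).reshape(len(g), -1)
        with nn.no_grad():
            f = nn.Tensor(g_flat @ lgs.A.entries)
            for j in range(self.idx):
                f = lgs.iterate(f, g_flat, j)
        out = lgs.iterate(nn.Tensor(f.data), g_flat, self.idx)
        return nn.reshape(out, (len(g), lgs.m, lgs.m))


def train_greedy_unrolled(model: LearnedGradientReconstructor,
                          dataset: PairedDataset, cfg: TrainConfig,
                          precompute_gradients: bool = True
                          ) -> tuple[dict, list[pd.DataFrame]]:
    """Greedy per-block training of an unrolled gradient scheme.

    Block n is trained against the ground truth while blocks 0..n-1 stay
    bitwise frozen; since the inputs to block n depend only on the
    frozen prefix, the iterates and gradient images can be computed once
    per block (``precompute_gradients=True``) or on the fly (False; the
    same numbers, kept as a cross-check of the decoupling).  Returns the
    checkpoint and one loss history per block.
    """
    if dataset.manifest.get("mode", "raw") != "raw":
        raise ValueError("greedy training needs raw time-series pairs")
    g_all = dataset.inputs.reshape(len(dataset), -1) \
        .astype(model.A.entries.dtype, copy=False)
    histories = []
    for idx in range(len(model.blocks)):
        if precompute_gradients:
            with nn.no_grad():
                f_cur = nn.Tensor(g_all @ model.A.entries)
                for j in range(idx):
                    f_cur = model.iterate(f_cur, g_all, j)
                d = model.gradient_image(nn.Tensor(f_cur.data),
                                         g_all).data * model.grad_scale
            packed = np.stack([
                f_cur.data.reshape(-1, model.m, model.m),
                d.reshape(-1, model.m, model.m)], axis=1)
            head = _BlockHead(model, idx)
            block_ds = PairedDataset(packed, dataset.targets,
                                     {"mode": "greedy-precomputed"})
        else:
            head = _OnTheFlyHead(model, idx)
            block_ds = PairedDataset(dataset.inputs, dataset.targets,
                                     {"mode": "greedy-onthefly"})
        _, hist = train_supervised(head, block_ds, cfg)
        histories.append(hist)
    checkpoint = {
        "state": model.state_dict(),
        "provenance": {
            "config": dataclasses.asdict(cfg),
            "dataset_manifest": dataset.manifest,
            "training_mode": "greedy",
            "precompute_gradients": bool(precompute_gradients),
        },
    }
    return checkpoint, histories


def transfer_update(model, checkpoint: dict, dataset: PairedDataset,
                    cfg: TrainConfig,
                    freeze_mask: set[str] | None = None,
                    lr_factor: float = 0.1
                    ) -> tuple[dict, pd.DataFrame]:
    """Update training on a new dataset from a pretrained checkpoint.

    The learning rate is reduced (default to 1/10 of ``cfg``'s); layers
    named in ``freeze_mask`` keep their pretrained weights, so passing
    all parameter names reproduces the checkpoint exactly.
    """
    model.load_state_dict(checkpoint["state"])
    reduced = dataclasses.replace(
        cfg, learning_rate=cfg.learning_rate * lr_factor)
    ckpt, history = train_supervised(model, dataset, reduced,
                                     frozen=freeze_mask)
    ckpt["provenance"]["transfer_from"] = checkpoint["provenance"]
    ckpt["provenance"]["learning_rate"] = reduced.learning_rate
    return ckpt, history


def save_checkpoint(path, checkpoint: dict) -> None:
    arrays = {f"param/{k}": v for k, v in checkpoint["state"].items()}
    arrays["provenance_json"] = np.array(
        json.dumps(checkpoint["provenance"]))
    np.savez(path, **arrays)


def load_checkpoint(path) -> dict:
    with np.load(path, allow_pickle=False) as z:
        state = {k[len("param/"):]: z[k] for k in z.files
                 if k.startswith("param/")}
        prov = json.loads(str(z["provenance_json"]))
    return {"state": state, "provenance": prov}
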