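"""Image-quality metrics and the prior-shift generalization benchmark.

Reconstruction quality is summarized by two standard metrics:

* PSNR — peak signal-to-noise ratio, ``20 log10(range / RMSE)`` with the
  range convention ``max(gt)`` and a cap of 200 dB for identical images;
* SSIM — mean local structural similarity with a Gaussian window
  (width 11, sigma 1.5) and stabilizers K1 = 0.01, K2 = 0.03.

:func:`run_scenario_experiment` trains the three learned reconstruction
approaches under controlled train/test priors and reports mean +/- std of
both metrics per (approach, scenario).  The three stock scenarios probe
robustness to a shift of the image prior:

(i)   consistent — train and test on the piecewise-constant family;
(ii)  shifted    — train on piecewise-constant, test on the smooth family;
(iii) combined   — train and test on a mixture of both families.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import nn
from .acoustics import (AcousticGeometry, NoiseModel,
                        assemble_forward_matrix)
from .learned import (FullyLearnedSpec, LearnedGradientSpec,
                      PostprocUNetSpec, build_fully_learned,
                      build_learned_gradient, build_postproc)
from .phantom import PhantomSpec, generate_dataset
from .training import (TrainConfig, make_training_pairs,
                       train_end_to_end_unrolled, train_supervised)

__all__ = ["psnr", "ssim", "ScenarioSpec", "ExperimentConfig",
           "desk_preset", "default_scenarios", "run_scenario_experiment",
           "PSNR_CAP"]

PSNR_CAP = 200.0


def psnr(rec: np.ndarray, gt: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB, range = max(gt), capped at 200."""
    rec = np.asarray(rec, float)
    gt = np.asarray(gt, float)
    if rec.shape != gt.shape:
        raise ValueError("shape mismatch")
    rng = float(gt.max())
    if rng <= 0:
        raise ValueError("ground truth is identically zero: PSNR range "
                         "undefined")
    rmse = float(np.sqrt(np.mean((rec - gt) ** 2)))
    if rmse == 0:
        return PSNR_CAP
    return min(20.0 * np.log10(rng / rmse), PSNR_CAP)


def ssim(rec: np.ndarray, gt: np.ndarray,
         data_range: float | None = None) -> float:
    """Mean local SSIM with a Gaussian window (11 taps, sigma = 1.5).

    ``data_range`` defaults to max(gt).  Local means/variances are
    Gaussian-weighted (population covariance); the filter-radius strip
    at the edges is excluded from the mean, following the reference
    formulation.
    """
    rec = np.asarray(rec, float)
    gt = np.asarray(gt, float)
    if rec.shape != gt.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        data_range = float(gt.max())
        if data_range <= 0:
            raise ValueError("ground truth is identically zero: specify "
                             "data_range")
    sigma, truncate = 1.5, 3.5
    pad = int(truncate * sigma + 0.5)

    def filt(img):
        return gaussian_filter(img, sigma, truncate=truncate,
                               mode="reflect")

    ux, uy = filt(rec), filt(gt)
    vx = filt(rec * rec) - ux * ux
    vy = filt(gt * gt) - uy * uy
    vxy = filt(rec * gt) - ux * uy
    C1 = (0.01 * data_range) ** 2
    C2 = (0.03 * data_range) ** 2
    S = ((2 * ux * uy + C1) * (2 * vxy + C2)) / \
        ((ux * ux + uy * uy + C1) * (vx + vy + C2))
    return float(S[pad:-pad, pad:-pad].mean())


# -- scenario experiment ----------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """Train/test prior assignment for one benchmark case."""

    id: str
    train_families: tuple[str, ...]
    test_families: tuple[str, ...]
    n_train: int
    n_test: int
    train_seed: int
    test_seed: int

    def __post_init__(self):
        if self.train_seed == self.test_seed:
            raise ValueError("train and test base seeds must differ "
                             "(disjoint manifests)")


@dataclass(frozen=True)
class ExperimentConfig:
    """Scaled-down experimental protocol (the full-scale published
    protocol uses thousands of samples and 5e4 Adam iterations)."""

    m: int = 32
    n_train: int = 200
    n_test: int = 40
    iterations: int = 2000
    batch_size: int = 4
    learning_rate: float = 1e-4
    noise_relative_std: float = 0.01
    noise_on_test: bool = True
    fully_l1_weight: float = 1e-6
    lgs_unrolled: int = 5
    seed: int = 0
    approaches: tuple[str, ...] = ("fully", "postproc", "lgs")
    dtype: str = "float32"  # training precision (metrics use float64)


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s % (2 ** 31)) for s in
            np.random.SeedSequence(seed).generate_state(n)]


def desk_preset(seed: int = 0) -> ExperimentConfig:
    """Benchmark protocol sized for a single workstation CPU: m = 32,
    140 training / 30 test pairs, 500 Adam iterations, two unrolled
    iterations for the learned gradient scheme."""
    return ExperimentConfig(m=32, n_train=140, n_test=30,
                            iterations=500, lgs_unrolled=2, seed=seed)


def default_scenarios(cfg: ExperimentConfig) -> list[ScenarioSpec]:
    s = _sub_seeds(cfg.seed, 6)
    return [
        ScenarioSpec("consistent", ("piecewise",), ("piecewise",),
                     cfg.n_train, cfg.n_test, s[0], s[1]),
        ScenarioSpec("shifted", ("piecewise",), ("smooth",),
                     cfg.n_train, cfg.n_test, s[2], s[3]),
        ScenarioSpec("combined", ("piecewise", "smooth"),
                     ("piecewise", "smooth"),
                     cfg.n_train, cfg.n_test, s[4], s[5]),
    ]


def _family_mix(families: tuple[str, ...], n: int, m: int, base_seed: int
                ) -> np.ndarray:
    """n images split evenly over the listed families."""
    per = [n // len(families)] * len(families)
    per[0] += n - sum(per)
    chunks = []
    for fam, cnt, seed in zip(families, per,
                              _sub_seeds(base_seed, len(families))):
        spec = PhantomSpec(family=fam, image_size=m, seed=seed)
        images, _ = generate_dataset(spec, cnt)
        chunks.append(images)
    return np.concatenate(chunks)


def _train_approach(approach: str, A, train_raw, train_post, cfg, seed):
    tc = TrainConfig(learning_rate=cfg.learning_rate,
                     batch_size=cfg.batch_size,
                     total_iterations=cfg.iterations, seed=seed)
    geom = A.geometry
    if approach == "fully":
        model = build_fully_learned(
            FullyLearnedSpec(seed=seed), geom.n_det, geom.n_t, geom.m)
        tc = dataclasses.replace(tc,
                                 param_l1_weight=cfg.fully_l1_weight)
        train_supervised(model, train_raw, tc)
        return model
    if approach == "postproc":
        model = build_postproc(PostprocUNetSpec(seed=seed), geom.m)
        train_supervised(model, train_post, tc)
        return model
    if approach == "lgs":
        model = build_learned_gradient(
            LearnedGradientSpec(n_unrolled=cfg.lgs_unrolled, seed=seed), A)
        train_end_to_end_unrolled(model, train_raw, tc)
        return model
    raise ValueError(f"unknown approach {approach!r}")


def _evaluate(approach: str, model, A, test_raw, test_post,
              targets) -> tuple[list[float], list[float]]:
    ssims, psnrs = [], []
    with nn.no_grad():
        for i in range(len(targets)):
            if approach == "postproc":
                rec = model(test_post[i][None]).data[0]
            else:
                rec = model(test_raw[i][None]).data[0]
            ssims.append(ssim(rec, targets[i]))
            psnrs.append(psnr(rec, targets[i]))
    return ssims, psnrs


def run_scenario_experiment(cfg: ExperimentConfig,
                            scenarios: list[ScenarioSpec] | None = None,
                            A=None,
                            ) -> tuple[pd.DataFrame, dict]:
    """Train and evaluate every approach under every scenario.

    Returns a tidy report (one row per approach x scenario with mean and
    std of SSIM and PSNR over the test set) and a provenance dict from
    which the experiment can be regenerated exactly.  A prebuilt forward
    matrix for the experiment geometry may be passed to avoid
    reassembly.
    """
    if scenarios is None:
        scenarios = default_scenarios(cfg)
    geom = AcousticGeometry(m=cfg.m)
    if A is None:
        A = assemble_forward_matrix(geom, precision=cfg.dtype)
    elif A.geometry.fingerprint != geom.fingerprint:
        raise ValueError("prebuilt matrix does not match the experiment "
                         "geometry")
    model_seeds = _sub_seeds(cfg.seed + 1, len(scenarios)
                             * len(cfg.approaches))
    rows = []
    seed_iter = iter(model_seeds)
    for sc in scenarios:
        train_images = _family_mix(sc.train_families, sc.n_train, cfg.m,
                                   sc.train_seed)
        test_images = _family_mix(sc.test_families, sc.n_test, cfg.m,
                                  sc.test_seed)
        noise = NoiseModel(cfg.noise_relative_std, sc.train_seed)
        train_raw = make_training_pairs(train_images, A, noise, "raw")
        train_post = make_training_pairs(train_images, A, noise,
                                         "postproc")
        tnoise = NoiseModel(cfg.noise_relative_std, sc.test_seed) \
            if cfg.noise_on_test else None
        test_raw = make_training_pairs(test_images, A, tnoise, "raw")
        test_post = make_training_pairs(test_images, A, tnoise,
                                        "postproc")
        for approach in cfg.approaches:
            seed = next(seed_iter)
            with nn.default_dtype(np.dtype(cfg.dtype)):
                model = _train_approach(approach, A, train_raw,
                                        train_post, cfg, seed)
                ssims, psnrs = _evaluate(approach, model, A,
                                         test_raw.inputs,
                                         test_post.inputs, test_images)
            rows.append({
                "method": approach, "case": sc.id,
                "ssim_mean": float(np.mean(ssims)),
                "ssim_std": float(np.std(ssims)),
                "psnr_mean": float(np.mean(psnrs)),
                "psnr_std": float(np.std(psnrs)),
                "n_test": len(ssims),
            })
    report = pd.DataFrame(rows)
    provenance = {
        "config": dataclasses.asdict(cfg),
        "scenarios": [dataclasses.asdict(s) for s in scenarios],
        "geometry_fingerprint": geom.fingerprint,
        "metrics": {"ssim_window": 11, "ssim_sigma": 1.5,
                    "ssim_K": [0.01, 0.03],
                    "psnr_range": "max(gt)", "psnr_cap_db": PSNR_CAP},
    }
    return report, provenance
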