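"""Domain-randomized training: segmenter pretraining and the main loop.

Every iteration of the main loop draws a brand-new synthetic pair — fresh
contrast, orientation, spacing, thickness, bias, noise, deformation and
lesion — so the network never sees the same nuisance condition twice.  The
objective is  L = Lreg + lambda * Lseg  with the segmentation term computed
by a previously trained, frozen segmenter applied to the regression output;
gradients flow through the frozen net into the regression weights only.

Full-scale reference settings (Adam 1e-4, 250k iterations, lambda = 0.25)
are documented in ``OptimConfig``; the desk-scale preset trains a small net
on 32^3 phantoms in minutes on one CPU and is what the tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .acquisition import TrainingSample, make_training_sample
from .config import GeneratorConfig
from .losses import (
    LossConfig,
    one_hot,
    regression_loss,
    regression_loss_grad,
    soft_dice_loss,
    soft_dice_loss_grad,
)
from .nn import Adam, NetworkSpec, NetworkState, build_regression_net, build_segmentation_net
from .phantom import LesionBank
from .volumes import LabelVolume

__all__ = [
    "OptimConfig",
    "desk_scale_spec",
    "pretrain_segmenter",
    "train_synthsr",
    "heldout_l1",
]


@dataclass
class OptimConfig:
    """Adam settings.  Full-scale reference: lr 1e-4, 250,000 iterations
    (about two GPU-weeks); desk scale: lr 1e-3 (the customary Adam default
    for small nets), a few hundred iterations."""

    learning_rate: float = 1e-4
    n_iterations: int = 300
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")


def desk_scale_spec(base_features: int = 8, n_levels: int = 3) -> NetworkSpec:
    """A small network that trains in minutes on one CPU at 32^3."""
    return NetworkSpec(n_levels=n_levels, base_features=base_features)


PairSource = Callable[[int], tuple[np.ndarray, LabelVolume]] | Sequence


def _draw_pair(source, idx: int, rng: np.random.Generator):
    if callable(source):
        return source(int(rng.integers(2 ** 31 - 1)))
    return source[int(rng.integers(len(source)))]


def pretrain_segmenter(
    pair_source: PairSource,
    codes: list[int],
    spec: NetworkSpec | None = None,
    optim: OptimConfig | None = None,
    dice_smooth: float = 1e-5,
) -> tuple[NetworkState, pd.DataFrame]:
    """Supervised pretraining of the segmentation net on (image, labels) pairs.

    ``pair_source`` is either a sequence of pairs or a callable(seed) that
    generates one; images are expected in target (wm1) units.  The returned
    network is frozen — the main training loop never updates it.
    """
    optim = optim or OptimConfig(learning_rate=3e-3, n_iterations=500)
    if len(codes) < 2:
        raise ValueError("segmentation needs at least 2 label classes")
    state = build_segmentation_net(spec, n_labels=len(codes), seed=optim.seed)
    adam = Adam(state.net.parameters(), lr=optim.learning_rate)
    rng = np.random.default_rng(optim.seed)
    log = []
    for it in range(optim.n_iterations):
        img, labels = _draw_pair(pair_source, it, rng)
        x = img.data if hasattr(img, "data") and not isinstance(img, np.ndarray) else img
        probs = state.net.forward(np.asarray(x, dtype=np.float32)[None])
        loss = soft_dice_loss(labels, probs, codes, dice_smooth)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite segmenter loss at iteration {it}")
        # compound objective: soft Dice + inverse-frequency-weighted
        # cross-entropy.  Dice alone cold-starts badly on rare classes
        # (a never-predicted small structure gets a vanishing gradient);
        # the weighted CE term keeps every present class learning.
        g = one_hot(labels, codes)
        freq = g.sum(axis=(1, 2, 3))
        w = np.where(freq > 0, 1.0 / np.maximum(freq, 1.0), 0.0)
        w *= (freq > 0).sum() / max(w.sum(), 1e-12)
        p_safe = np.maximum(probs, 1e-8)
        ce = float(-(w[:, None, None, None] * g * np.log(p_safe)).sum() / g[0].size)
        dp = soft_dice_loss_grad(labels, probs, codes, dice_smooth)
        dp -= (w[:, None, None, None] * g) / p_safe / g[0].size
        state.net.zero_grad()
        state.net.backward(dp.astype(np.float32))
        adam.step(state.net.gradients())
        log.append({"iteration": it, "loss_seg": loss, "loss_ce": ce})
    state.frozen = True
    state.meta["codes"] = [int(c) for c in codes]
    return state, pd.DataFrame(log)


def train_synthsr(
    label_source: Callable[[int], LabelVolume] | Sequence[LabelVolume],
    gen_cfg: GeneratorConfig,
    loss_cfg: LossConfig | None = None,
    optim: OptimConfig | None = None,
    segmenter: NetworkState | None = None,
    lesion_bank: LesionBank | None = None,
    spec: NetworkSpec | None = None,
) -> tuple[NetworkState, pd.DataFrame]:
    """Train the regression net on freshly generated samples.

    Each iteration: draw a label map, run the full domain-randomized
    generator, forward the degraded input, and take one Adam step on
    Lreg + lambda * Lseg.  The segmenter (if given) must be frozen; its
    parameters receive no update, only gradients passing through to the
    regression output.  Aborts on a non-finite loss, reporting the seed of
    the offending sample so it can be regenerated for inspection.
    """
    loss_cfg = loss_cfg or LossConfig()
    optim = optim or OptimConfig(learning_rate=1e-3)
    if segmenter is not None and not segmenter.frozen:
        raise ValueError("segmenter must be frozen before training the regressor")
    if loss_cfg.lam > 0 and segmenter is None:
        raise ValueError("lambda > 0 requires a segmenter")
    state = build_regression_net(spec or desk_scale_spec(), seed=optim.seed)
    adam = Adam(state.net.parameters(), lr=optim.learning_rate)
    rng = np.random.default_rng(optim.seed)
    sample_seeds = rng.integers(0, 2 ** 31 - 1, optim.n_iterations)
    codes = segmenter.meta.get("codes") if segmenter is not None else None
    log = []
    for it in range(optim.n_iterations):
        s = int(sample_seeds[it])
        labels = label_source(s) if callable(label_source) else \
            label_source[s % len(label_source)]
        sample = make_training_sample(labels, gen_cfg, seed=s, lesion_bank=lesion_bank)
        x = sample.x.data.astype(np.float32)[None]
        y = sample.y.data
        yhat = state.net.forward(x)[0]
        lreg = regression_loss(y, yhat, "mean")
        dyhat = regression_loss_grad(y, yhat)
        lseg = np.nan
        if segmenter is not None:
            probs = segmenter.net.forward(yhat.astype(np.float32)[None])
            lseg = soft_dice_loss(sample.labels, probs, codes, loss_cfg.dice_smooth)
            if loss_cfg.lam > 0:
                dp = soft_dice_loss_grad(sample.labels, probs, codes, loss_cfg.dice_smooth)
                segmenter.net.zero_grad()
                dyhat_seg = segmenter.net.backward(dp.astype(np.float32))[0]
                segmenter.net.zero_grad()  # frozen: discard its parameter grads
                dyhat = dyhat + loss_cfg.lam * dyhat_seg.astype(np.float64)
        total = lreg + (loss_cfg.lam * lseg if segmenter is not None and
                        loss_cfg.lam > 0 else 0.0)
        if not np.isfinite(total):
            raise RuntimeError(
                f"non-finite loss at iteration {it}; offending sample seed {s}"
            )
        state.net.zero_grad()
        state.net.backward(dyhat[None].astype(np.float32))
        adam.step(state.net.gradients())
        log.append({
            "iteration": it, "sample_seed": s, "loss": total,
            "loss_reg": lreg, "loss_seg": lseg,
            "loss_reg_sum": lreg * y.size,
        })
    state.meta["trained_iterations"] = optim.n_iterations
    return state, pd.DataFrame(log)


def heldout_l1(
    state: NetworkState, samples: Sequence[TrainingSample]
) -> pd.DataFrame:
    """Per-sample mean L1 of the prediction and of the identity baseline.

    The baseline is the degraded input itself (pure interpolation): the
    network is useful only if it beats feeding the input straight through.
    """
    rows = []
    for i, s in enumerate(samples):
        yhat = state.net.forward(s.x.data.astype(np.float32)[None])[0]
        rows.append({
            "sample": i,
            "l1_model": regression_loss(s.y.data, yhat, "mean"),
            "l1_baseline": regression_loss(s.y.data, s.x.data, "mean"),
        })
    return pd.DataFrame(rows)
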