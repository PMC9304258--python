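"""Optimisation of the denoising networks with the Charbonnier loss.

The loss is the Charbonnier penalty ``rho(x) = sqrt(x**2 + eps**2)``, a
differentiable surrogate for the absolute error, applied between the final
composed output and the clean target (eps = 1e-3 by default).  The
learning rate starts at 1e-3 and is halved every 2000 steps down to a
floor of 1e-6; the optimiser is Adam with default moments, with its
learning rate overridden by the schedule at every step.  One batch holds
16 patches of 96 x 96 at full scale; the desk-scale profile shrinks the
patch size and step count so a full run fits in minutes on one CPU core.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .eedn_core import EEDN, save_checkpoint
from .nn import functional as F
from .noise_sim import PatchDataset

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "charbonnier_loss", "lr_schedule", "train"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    patch_size: int = 96
    lr_init: float = 1e-3
    lr_halve_every: int = 2000
    lr_floor: float = 1e-6
    epsilon: float = 1e-3
    max_steps: int = 40_000
    seed: int = 0
    eval_every: int = 0  # 0 disables held-out evaluation
    loss_reduction: str = "batchmean"

    def __post_init__(self) -> None:
        if self.lr_floor > self.lr_init:
            raise ValueError("lr_floor must not exceed lr_init")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    @classmethod
    def desk(cls, seed: int = 7) -> "TrainConfig":
        """Desk-scale profile: 500 steps on 32x32 patches."""
        return cls(patch_size=32, max_steps=500, seed=seed)


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    eval_steps: list[int] = field(default_factory=list)
    eval_psnr: list[float] = field(default_factory=list)
    eval_ssim: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "loss", "lr"])
            for i, (l, r) in enumerate(zip(self.loss, self.lr)):
                writer.writerow([i, l, r])


def charbonnier_loss(pred, target, epsilon: float = 1e-3, reduction: str = "sum") -> float:
    """Charbonnier penalty ``sum_i sqrt((target_i - pred_i)**2 + eps**2)``.

    Accepts arrays or tensors; shapes must match.  With identical inputs
    the loss equals ``k * eps`` for ``k`` elements, since ``rho(0) = eps``.
    """
    p = pred if isinstance(pred, nn.Tensor) else nn.Tensor(np.asarray(pred))
    t = target if isinstance(target, nn.Tensor) else nn.Tensor(np.asarray(target))
    return float(F.charbonnier(p, t, epsilon=epsilon, reduction=reduction).data)


def lr_schedule(step: int, config: TrainConfig) -> float:
    """``max(lr_floor, lr_init / 2**floor(step / lr_halve_every))``."""
    if step < 0:
        raise ValueError("step must be >= 0")
    # float power underflows to 0.0 for huge step counts instead of
    # overflowing the integer exponent
    return max(config.lr_floor, config.lr_init * 0.5 ** (step // config.lr_halve_every))


def train(
    model: nn.Module,
    dataset: PatchDataset,
    config: TrainConfig,
    checkpoint_path: str | Path | None = None,
) -> tuple[nn.Module, TrainHistory]:
    """Optimise a network on a patch dataset.

    Patches are visited in seeded shuffled order (reshuffled each epoch);
    the loss compares the composed output against the clean patch in the
    [0, 1] normalised domain.  A non-finite loss aborts with a diagnostic
    checkpoint when a checkpoint path was given.  Training is reproducible:
    the whole loss trace is a pure function of (model seed, data, config).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    opt = nn.Adam(params, lr=config.lr_init)
    history = TrainHistory()
    n = len(dataset)
    batch = min(config.batch_size, n)
    maxval = float(2**dataset.bit_depth - 1)
    order = rng.permutation(n)
    pos = 0
    for step in range(config.max_steps):
        if pos + batch > n:
            order = rng.permutation(n)
            pos = 0
        idx = order[pos : pos + batch]
        pos += batch
        x = nn.Tensor(dataset.noisy[idx, None] / maxval)
        target = nn.Tensor(dataset.clean[idx, None] / maxval)
        _, _, _, i_output = model(x)
        loss = F.charbonnier(i_output, target, epsilon=config.epsilon, reduction=config.loss_reduction)
        value = float(loss.data)
        if not np.isfinite(value):
            if checkpoint_path is not None and hasattr(model, "config"):
                save_checkpoint(model, checkpoint_path)
            raise RuntimeError(f"non-finite loss at step {step}")
        opt.lr = lr_schedule(step, config)
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.loss.append(value)
        history.lr.append(opt.lr)
        if config.eval_every and (step + 1) % config.eval_every == 0:
            logger.info("step %d: loss %.5f lr %.2e", step, value, opt.lr)
    if checkpoint_path is not None and hasattr(model, "config"):
        save_checkpoint(model, checkpoint_path)
    return model, history
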