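"""Alternating dual-discriminator GAN training.

Each step makes one joint discriminator update (holistic-image D₁ and edge
D₂ maximise the shared adversarial objective) followed by one generator
update on the full weighted loss.  The learning rate halves every 5 epochs
down to a floor, and training halts when the validation NMSE has not
improved for a patience window.  The two residual-learning switches of the
generator span the four ablation variants (GRLR, GRnLR, nGRLR, nGRnLR).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import nmse as eval_nmse
from .evaluation import psnr as eval_psnr
from .evaluation import ssim as eval_ssim
from .losses import (
    LossWeights,
    RandomConvExtractor,
    _t_mean_log,
    loss_total,
    t_loss_adversarial,
    t_loss_fmse_mask,
    t_loss_fmse_unmask,
    t_loss_imse,
    t_loss_perceptual,
)
from .networks import Discriminator, DiscriminatorConfig, Generator, GeneratorConfig
from .nn import Adam, Tensor, magnitude, no_grad, sobel_magnitude
from .physics import AcquiredSample, CoilSet, SamplingMask

__all__ = [
    "TrainConfig",
    "TrainState",
    "TrainingData",
    "lr_schedule",
    "early_stop",
    "Trainer",
    "run_ablation",
    "reconstruct",
    "save_checkpoint",
    "load_checkpoint",
    "ABLATION_VARIANTS",
]

ABLATION_VARIANTS = ("GRLR", "GRnLR", "nGRLR", "nGRnLR")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule and model configuration for one run."""

    batch_size: int = 12
    lr_initial: float = 1e-3
    lr_min: float = 1e-5
    lr_decay: float = 0.5
    lr_decay_every: int = 5
    adam_beta1: float = 0.5  # optimiser first-moment coefficient
    patience: int = 8
    max_epochs: int = 20
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)

    def __post_init__(self) -> None:
        if self.lr_min > self.lr_initial:
            raise ValueError("lr_min must not exceed lr_initial")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainState:
    """Append-only run history; ``best_epoch`` tracks the minimum val NMSE."""

    epoch: int = 0
    step: int = 0
    loss_history: list[dict] = field(default_factory=list)
    val_nmse_history: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_nmse: float = np.inf
    best_state: dict | None = None


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Step decay: ``max(lr_min, lr_initial · decay^⌊epoch/every⌋)``."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return max(cfg.lr_min, cfg.lr_initial * cfg.lr_decay ** (epoch // cfg.lr_decay_every))


def early_stop(nmse_history: list[float], patience: int = 8) -> bool:
    """True iff the running minimum has not decreased for `patience` epochs."""
    if not nmse_history:
        raise ValueError("history must be non-empty")
    h = np.asarray(nmse_history, dtype=float)
    best_idx = int(np.argmin(h))  # first occurrence: later ties do not reset
    return (len(h) - 1 - best_idx) >= patience


class TrainingData:
    """Sample bundles packed into contiguous arrays for batching."""

    def __init__(self, samples: list[AcquiredSample], coils: CoilSet):
        if not samples:
            raise ValueError("empty sample list")
        self.coils = coils
        self.mask: SamplingMask = samples[0].mask
        to2ch = lambda z: np.stack([z.real, z.imag], axis=0).astype(np.float32)
        self.x_u = np.stack([to2ch(s.zero_filled) for s in samples])
        self.x_t = np.stack([to2ch(s.target) for s in samples])
        self.coil_targets = np.stack([s.coil_images for s in samples]).astype(np.complex64)
        self.kspace = np.stack([s.kspace for s in samples]).astype(np.complex64)
        self.kspace_full = np.stack([s.kspace_full for s in samples]).astype(np.complex64)

    def __len__(self) -> int:
        return self.x_u.shape[0]


def _to_complex(batch2ch: np.ndarray) -> np.ndarray:
    return batch2ch[:, 0].astype(np.complex128) + 1j * batch2ch[:, 1].astype(np.complex128)


class Trainer:
    """One training run of the dual-discriminator GAN."""

    def __init__(self, train: TrainingData, val: TrainingData, cfg: TrainConfig):
        self.train_data = train
        self.val_data = val
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.G = Generator(cfg.generator, seed=cfg.seed)
        self.adversarial = cfg.weights.mu + cfg.weights.nu > 0
        self.D1 = Discriminator(cfg.discriminator, seed=cfg.seed + 1)
        self.D2 = Discriminator(cfg.discriminator, seed=cfg.seed + 2)
        self.extractor = RandomConvExtractor(seed=cfg.seed + 3)
        self.optG = Adam(self.G.parameters(), cfg.lr_initial, beta1=cfg.adam_beta1)
        self.optD = Adam(
            self.D1.parameters() + self.D2.parameters(), cfg.lr_initial, beta1=cfg.adam_beta1
        )
        self.state = TrainState()

    # -- single optimisation step -----------------------------------------

    def train_step(self, idx: np.ndarray) -> dict:
        """One D update then one G update on the batch ``idx``."""
        td, w = self.train_data, self.cfg.weights
        xu = Tensor(td.x_u[idx])
        xt = Tensor(td.x_t[idx])
        real_mag = magnitude(xt)
        logs: dict[str, float] = {}

        if self.adversarial:
            with no_grad():
                fake_const = Tensor(self.G(xu).data)
            fake_mag = magnitude(fake_const)
            d1_real, d1_fake = self.D1(real_mag), self.D1(fake_mag)
            d2_real = self.D2(sobel_magnitude(real_mag))
            d2_fake = self.D2(sobel_magnitude(fake_mag))
            _, disc_term = t_loss_adversarial(d1_real, d1_fake, d2_real, d2_fake, w)
            self.optD.zero_grad()
            (-disc_term).backward()
            self.optD.step()
            logs["disc_term"] = disc_term.item()

        fake = self.G(xu)
        comps: dict[str, Tensor] = {
            "imse": t_loss_imse(fake, td.coil_targets[idx], td.coils),
            "fmse_mask": t_loss_fmse_mask(fake, td.kspace[idx], td.coils, td.mask),
            "fmse_unmask": t_loss_fmse_unmask(fake, td.kspace_full[idx], td.coils, td.mask),
            "perceptual": t_loss_perceptual(fake, xt, self.extractor),
        }
        if self.adversarial:
            fm = magnitude(fake)
            d1_fake = self.D1(fm)
            d2_fake = self.D2(sobel_magnitude(fm))
            comps["adv_gen"] = -w.mu * _t_mean_log(d1_fake) - w.nu * _t_mean_log(d2_fake)
        total = loss_total(comps, w)
        if not np.isfinite(total.item()):
            raise FloatingPointError(f"non-finite training loss at step {self.state.step}")
        self.optG.zero_grad()
        self.optD.zero_grad()
        total.backward()
        self.optG.step()
        self.optD.zero_grad()

        logs.update({k: v.item() for k, v in comps.items()})
        logs["total"] = total.item()
        logs["step"] = self.state.step
        self.state.step += 1
        self.state.loss_history.append(logs)
        return logs

    # -- validation --------------------------------------------------------

    def validate(self, data: TrainingData | None = None, batch_size: int = 16) -> float:
        """Mean per-slice NMSE of reconstructions on magnitude images."""
        data = data or self.val_data
        recons = reconstruct(self.G, data.x_u, batch_size=batch_size)
        targets = _to_complex(data.x_t)
        return float(np.mean([eval_nmse(np.abs(r), np.abs(t)) for r, t in zip(recons, targets)]))

    # -- full run ----------------------------------------------------------

    def run(
        self,
        max_epochs: int | None = None,
        n_steps: int | None = None,
        early_stopping: bool = True,
    ) -> TrainState:
        """Train for ``max_epochs`` (or until ``n_steps`` generator updates).

        Validation NMSE is computed once per epoch; the best generator state
        is retained on the state object.
        """
        cfg = self.cfg
        max_epochs = cfg.max_epochs if max_epochs is None else max_epochs
        n = len(self.train_data)
        while self.state.epoch < max_epochs:
            lr = lr_schedule(self.state.epoch, cfg)
            self.optG.lr = lr
            self.optD.lr = lr
            perm = self.rng.permutation(n)
            for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
                self.train_step(perm[start : start + cfg.batch_size])
                if n_steps is not None and self.state.step >= n_steps:
                    break
            val = self.validate()
            self.state.val_nmse_history.append(val)
            if val < self.state.best_val_nmse:
                self.state.best_val_nmse = val
                self.state.best_epoch = self.state.epoch
                self.state.best_state = self.G.state_dict()
            self.state.epoch += 1
            if n_steps is not None and self.state.step >= n_steps:
                break
            if early_stopping and early_stop(self.state.val_nmse_history, cfg.patience):
                break
        return self.state

    def epoch_metrics(self, data: TrainingData | None = None) -> dict:
        """NMSE/PSNR/SSIM of current generator on a dataset (magnitudes)."""
        data = data or self.val_data
        recons = np.abs(np.stack(reconstruct(self.G, data.x_u)))
        targets = np.abs(_to_complex(data.x_t))
        vals = {"nmse": [], "psnr": [], "ssim": []}
        for r, t in zip(recons, targets):
            peak = float(t.max()) or 1.0
            vals["nmse"].append(eval_nmse(r / peak, t / peak))
            vals["psnr"].append(eval_psnr(r / peak, t / peak))
            vals["ssim"].append(eval_ssim(r / peak, t / peak))
        return {k: float(np.mean(v)) for k, v in vals.items()}

    def save_logs(self, rundir: str | Path) -> None:
        rundir = Path(rundir)
        rundir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.state.loss_history).to_csv(rundir / "losses.csv", index=False)
        pd.DataFrame(
            {"epoch": range(len(self.state.val_nmse_history)),
             "val_nmse": self.state.val_nmse_history}
        ).to_csv(rundir / "validation.csv", index=False)


def reconstruct(G: Generator, x_u: np.ndarray, batch_size: int = 16) -> list[np.ndarray]:
    """Run the generator in eval mode over (N, 2, H, W) inputs.

    Returns complex (H, W) reconstructions.
    """
    was_training = G.training
    G.eval()
    out: list[np.ndarray] = []
    with no_grad():
        for start in range(0, x_u.shape[0], batch_size):
            y = G(Tensor(x_u[start : start + batch_size])).data
            out.extend(_to_complex(y))
    G.train(was_training)
    return out


def run_ablation(
    train: TrainingData,
    val: TrainingData,
    base_cfg: TrainConfig,
    n_epochs: int = 3,
    variants: tuple[str, ...] = ABLATION_VARIANTS,
) -> pd.DataFrame:
    """Train the GR/LR ablation grid with early stopping disabled.

    Returns one row per (variant, epoch) with validation NMSE/PSNR/SSIM and
    the mean generator loss of that epoch — the quantities tracked in the
    residual-learning ablation.
    """
    rows = []
    for variant in variants:
        gcfg = replace(
            base_cfg.generator,
            use_global_residual=variant.startswith("GR"),
            use_local_residual="nLR" not in variant,
        )
        cfg = replace(base_cfg, generator=gcfg)
        trainer = Trainer(train, val, cfg)
        for epoch in range(n_epochs):
            start_step = trainer.state.step
            trainer.run(max_epochs=epoch + 1, early_stopping=False)
            epoch_losses = [
                h["total"] for h in trainer.state.loss_history if h["step"] >= start_step
            ]
            metrics = trainer.epoch_metrics()
            rows.append(
                {
                    "variant": variant,
                    "epoch": epoch,
                    "val_nmse": trainer.state.val_nmse_history[-1],
                    "val_psnr": metrics["psnr"],
                    "val_ssim": metrics["ssim"],
                    "gen_loss": float(np.mean(epoch_losses)) if epoch_losses else np.nan,
                }
            )
    return pd.DataFrame(rows)


# -- checkpointing ----------------------------------------------------------


def save_checkpoint(path: str | Path, G: Generator, extra: dict | None = None) -> None:
    """Single-file checkpoint: generator weights + embedded config."""
    cfg_json = json.dumps(
        {"generator": G.cfg.__dict__, "extra": extra or {}}, default=str
    )
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **G.state_dict())


def load_checkpoint(path: str | Path) -> tuple[Generator, dict]:
    """Rebuild a generator from a checkpoint file."""
    with np.load(path) as z:
        cfg_json = json.loads(bytes(z["__config__"]).decode())
        state = {k: z[k] for k in z.files if k != "__config__"}
    gcfg = GeneratorConfig(**cfg_json["generator"])
    G = Generator(gcfg)
    G.load_state_dict(state)
    return G, cfg_json.get("extra", {})
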