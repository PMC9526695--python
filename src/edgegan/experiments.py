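"""Self-contained desk-scale experiments.

These functions define the package's reference benchmarks at a size a
single CPU handles in minutes: 64×64 phantoms, a 4-coil simulated array and
a Gaussian 2-D 30 % trajectory.  They are used both by the test suite and
by ``scripts/acceptance.py``, so the study conditions live in exactly one
place.

* :func:`toy_training_benchmark` — train the dual-discriminator GAN for a
  fixed number of generator steps on 200 training phantoms and compare the
  reconstructions' held-out PSNR and edge-NMSE against the zero-filled
  baseline.
* :func:`ablation_benchmark` — the residual-learning grid (GRLR / GRnLR /
  nGRLR / nGRnLR) at equal steps with early stopping disabled, repeated
  over seeds.
* :func:`mask_fraction_trend` — zero-filled PSNR across Gaussian 2-D
  sampling fractions 10–50 %, averaged over mask seeds.
"""

from __future__ import annotations

import numpy as np

from .evaluation import edge_nmse, psnr
from .losses import LossWeights
from .networks import DiscriminatorConfig, GeneratorConfig
from .physics import NoiseSpec, add_noise, fourier
from .synthetic import PhantomSpec, make_coilset, make_phantom, make_samples, split_dataset
from .trajectories import TrajectorySpec, gaussian2d_mask
from .training import TrainConfig, Trainer, TrainingData, reconstruct, run_ablation

__all__ = ["toy_training_benchmark", "ablation_benchmark", "mask_fraction_trend", "noise_calibration"]

DESK_SHAPE = (64, 64)
DESK_COILS = 4


def _desk_dataset(n_train: int, n_val: int, n_test: int, fraction: float, seed: int):
    H, W = DESK_SHAPE
    coils = make_coilset(H, W, DESK_COILS, seed=seed)
    mask = gaussian2d_mask(TrajectorySpec("gaussian2d", fraction, (H, W), seed=seed))
    samples = make_samples(n_train + n_val + n_test, PhantomSpec(shape=(H, W)),
                           coils, mask, None, seed=seed)
    split = split_dataset(len(samples), (n_train, n_val, n_test), seed=seed)
    pick = lambda idx: TrainingData([samples[i] for i in idx], coils)
    return pick(split.train_idx), pick(split.val_idx), pick(split.test_idx), coils, mask


def _metrics_vs_zero_filled(trainer: Trainer, td: TrainingData) -> dict:
    recons = reconstruct(trainer.G, td.x_u)
    targets = td.x_t[:, 0] + 1j * td.x_t[:, 1]
    zf = td.x_u[:, 0] + 1j * td.x_u[:, 1]
    rows = {"recon_psnr": [], "zf_psnr": [], "recon_edge_nmse": [], "zf_edge_nmse": []}
    for r, z, t in zip(recons, zf, targets):
        t = np.abs(t)
        peak = float(t.max()) or 1.0
        tn = t / peak
        rows["recon_psnr"].append(psnr(np.abs(r) / peak, tn))
        rows["zf_psnr"].append(psnr(np.abs(z) / peak, tn))
        rows["recon_edge_nmse"].append(edge_nmse(np.abs(r) / peak, tn))
        rows["zf_edge_nmse"].append(edge_nmse(np.abs(z) / peak, tn))
    return {k: float(np.mean(v)) for k, v in rows.items()}


def toy_training_benchmark(
    seed: int = 0,
    n_steps: int = 300,
    n_train: int = 200,
    n_val: int = 40,
    n_test: int = 60,
    fraction: float = 0.3,
    batch_size: int = 8,
) -> dict:
    """Train at desk scale and report held-out PSNR / edge-NMSE vs zero filling.

    Returns a dict with mean test-set PSNR of the reconstructions and of the
    zero-filled inputs, the PSNR gain in dB, and the mean edge-NMSE of both.
    """
    train_td, val_td, test_td, _, _ = _desk_dataset(n_train, n_val, n_test, fraction, seed)
    cfg = TrainConfig(
        batch_size=batch_size,
        max_epochs=10_000,
        seed=seed,
        weights=LossWeights(),
        generator=GeneratorConfig(base_channels=16),
        discriminator=DiscriminatorConfig(base_channels=16),
    )
    trainer = Trainer(train_td, val_td, cfg)
    state = trainer.run(n_steps=n_steps, early_stopping=False)
    out = _metrics_vs_zero_filled(trainer, test_td)
    out["psnr_gain_db"] = out["recon_psnr"] - out["zf_psnr"]
    out["steps"] = state.step
    return out


def ablation_benchmark(
    seed: int = 0,
    n_seeds: int = 3,
    n_epochs: int = 2,
    n_train: int = 40,
    n_val: int = 16,
    fraction: float = 0.3,
) -> dict:
    """Residual-learning ablation at equal steps, repeated over ``n_seeds``.

    For each seed, all four GR/LR variants train with early stopping
    disabled; a seed counts as a "win" when both GR-enabled variants end at
    lower validation NMSE than the plain nGRnLR model.
    """
    wins = 0
    per_seed = []
    for k in range(n_seeds):
        s = seed + k
        train_td, val_td, _, _, _ = _desk_dataset(n_train, n_val, 4, fraction, s)
        cfg = TrainConfig(
            batch_size=8, max_epochs=10_000, seed=s,
            generator=GeneratorConfig(base_channels=16),
            discriminator=DiscriminatorConfig(base_channels=16),
        )
        curves = run_ablation(train_td, val_td, cfg, n_epochs=n_epochs)
        final = curves[curves.epoch == curves.epoch.max()].set_index("variant")["val_nmse"]
        win = final["GRLR"] < final["nGRnLR"] and final["GRnLR"] < final["nGRnLR"]
        wins += int(win)
        per_seed.append({v: float(final[v]) for v in final.index})
    return {"wins": wins, "n_seeds": n_seeds, "final_val_nmse": per_seed}


def mask_fraction_trend(
    seed: int = 0,
    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
    n_seeds: int = 5,
) -> dict:
    """Zero-filled PSNR vs Gaussian 2-D sampling fraction on a fixed phantom."""
    H, W = DESK_SHAPE
    coils = make_coilset(H, W, DESK_COILS, seed=seed)
    x = make_phantom(PhantomSpec(shape=(H, W), seed=seed))
    peak = float(np.abs(x).max()) or 1.0
    means = []
    for frac in fractions:
        vals = []
        for k in range(n_seeds):
            mask = gaussian2d_mask(
                TrajectorySpec("gaussian2d", frac, (H, W), seed=seed + 1000 * k)
            )
            from .synthetic import assemble_sample

            s = assemble_sample(x, coils, mask, None)
            vals.append(psnr(np.abs(s.zero_filled) / peak, np.abs(s.target) / peak))
        means.append(float(np.mean(vals)))
    return {
        "fractions": list(fractions),
        "zf_psnr": means,
        "monotonic": bool(np.all(np.diff(means) > 0)),
    }


def noise_calibration(
    levels: tuple[float, ...] = (0.2, 0.3, 0.5), shape: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> dict:
    """Empirical noise level achieved by the k-space noise model per target NL."""
    rng = np.random.default_rng(seed)
    img = rng.random(shape)
    k = fourier(img, "forward")
    S = float(np.mean(np.abs(k) ** 2))
    out = {}
    for nl in levels:
        noisy = add_noise(k, NoiseSpec(nl=nl, seed=seed + int(nl * 1000)))
        N = float(np.mean(np.abs(noisy - k) ** 2))
        out[nl] = N / (N + S)
    return out
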