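"""Reconstruction quality metrics and report assembly.

All metrics act on magnitude images normalised to [0, 1] with peak = 1:
NMSE (reference-normalised squared error), PSNR (capped at 100 dB for exact
equality), SSIM (11×11 Gaussian window, σ = 1.5, C1 = (0.01)², C2 = (0.03)²)
and edge-NMSE (NMSE between Sobel edge maps) — the edge-domain analogue of
the holistic error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .edge_ops import sobel

__all__ = ["nmse", "psnr", "ssim", "edge_nmse", "line_profile", "MetricReport", "evaluate_pairs", "PSNR_CAP"]

PSNR_CAP = 100.0


def _mag(x: np.ndarray) -> np.ndarray:
    return np.abs(np.asarray(x)).astype(np.float64)


def nmse(x_hat: np.ndarray, x: np.ndarray) -> float:
    """Normalised mean squared error ‖x̂ − x‖² / ‖x‖² on magnitudes."""
    a, b = _mag(x_hat), _mag(x)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = float(np.sum(b**2))
    if denom == 0.0:
        raise ValueError("reference image has zero norm")
    return float(np.sum((a - b) ** 2)) / denom


def psnr(x_hat: np.ndarray, x: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images return the cap."""
    a, b = _mag(x_hat), _mag(x)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP
    return min(10.0 * np.log10(peak**2 / mse), PSNR_CAP)


def ssim(x_hat: np.ndarray, x: np.ndarray) -> float:
    """Mean structural similarity with the standard Gaussian-window setting."""
    a, b = _mag(x_hat), _mag(x)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(
        structural_similarity(
            b, a, data_range=1.0, gaussian_weights=True, sigma=1.5,
            win_size=11, use_sample_covariance=False,
        )
    )


def edge_nmse(x_hat: np.ndarray, x: np.ndarray) -> float:
    """NMSE between the Sobel edge maps of the two magnitude images."""
    return nmse(sobel(_mag(x_hat)), sobel(_mag(x)))


def line_profile(img: np.ndarray, row_index: int) -> np.ndarray:
    """Magnitude values along one row, for profile overlay plots."""
    m = _mag(img)
    if not (0 <= row_index < m.shape[0]):
        raise IndexError(f"row {row_index} out of range for height {m.shape[0]}")
    return m[row_index].copy()


@dataclass
class MetricReport:
    """Per-slice metrics with mean±std aggregates and run descriptors."""

    per_slice: pd.DataFrame
    descriptors: dict = field(default_factory=dict)

    METRICS = ("nmse", "psnr", "ssim", "edge_nmse")

    @property
    def aggregate(self) -> pd.DataFrame:
        return self.per_slice[list(self.METRICS)].agg(["mean", "std"])

    def to_json_dict(self) -> dict:
        agg = self.aggregate
        return {
            "descriptors": self.descriptors,
            "n_slices": int(len(self.per_slice)),
            **{
                m: {"mean": float(agg.loc["mean", m]), "std": float(agg.loc["std", m])}
                for m in self.METRICS
            },
        }

    def save(self, csv_path=None, json_path=None) -> None:
        if csv_path is not None:
            self.per_slice.to_csv(csv_path, index=False)
        if json_path is not None:
            import json

            with open(json_path, "w") as f:
                json.dump(self.to_json_dict(), f, indent=2)


def _normalize(img: np.ndarray, ref_peak: float) -> np.ndarray:
    return _mag(img) / ref_peak


def evaluate_pairs(
    predictions: list[np.ndarray] | np.ndarray,
    references: list[np.ndarray] | np.ndarray,
    descriptors: dict | None = None,
) -> MetricReport:
    """Compute all metrics per slice pair and assemble a report.

    Each pair is normalised by the reference's peak magnitude before the
    metrics are computed, so PSNR/SSIM use peak = 1 consistently.
    """
    rows = []
    for i, (p, r) in enumerate(zip(predictions, references, strict=True)):
        peak = float(_mag(r).max()) or 1.0
        pn, rn = _normalize(p, peak), _normalize(r, peak)
        rows.append(
            {
                "slice": i,
                "nmse": nmse(pn, rn),
                "psnr": psnr(pn, rn),
                "ssim": ssim(pn, rn),
                "edge_nmse": edge_nmse(pn, rn),
            }
        )
    return MetricReport(pd.DataFrame(rows), descriptors or {})
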