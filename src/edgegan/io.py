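"""Dataset serialization.

HDF5 layout (one file per simulated acquisition run):

* ``/kspace``         — (N, Q, H, W) complex64, fully sampled coil k-space
* ``/sensitivities``  — (Q, H, W) complex64 (or (N, Q, H, W) per-slice maps)
* ``/mask``           — (H, W) uint8 binary trajectory
* attrs: ``fraction`` (target sampling fraction), ``trajectory`` (kind),
  ``noise_level`` (NL already applied to /kspace).

Undersampling is applied on load (``y = mask * kspace``), so one file serves
both the fully sampled references and the acquired measurements.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .physics import AcquiredSample, CoilSet, SamplingMask, coil_combine, fourier, zero_filled

__all__ = ["save_dataset", "load_dataset", "export_nifti", "export_png", "mask_to_png"]


def save_dataset(
    path: str | Path,
    samples: list[AcquiredSample],
    coils: CoilSet,
    trajectory: str = "unknown",
    noise_level: float = 0.0,
) -> None:
    """Write acquired samples to the HDF5 layout above."""
    if not samples:
        raise ValueError("no samples to save")
    mask = samples[0].mask
    kspace = np.stack([s.kspace_full for s in samples]).astype(np.complex64)
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kspace)
        f.create_dataset("sensitivities", data=coils.maps.astype(np.complex64))
        f.create_dataset("mask", data=mask.data)
        f.attrs["fraction"] = mask.target_fraction
        f.attrs["expected_ones"] = mask.expected_ones
        f.attrs["trajectory"] = trajectory
        f.attrs["noise_level"] = noise_level


def load_dataset(path: str | Path) -> tuple[list[AcquiredSample], CoilSet, dict]:
    """Read an HDF5 dataset back into per-slice sample bundles."""
    with h5py.File(path, "r") as f:
        kspace = np.asarray(f["kspace"], dtype=np.complex128)
        sens = np.asarray(f["sensitivities"], dtype=np.complex128)
        mask_data = np.asarray(f["mask"], dtype=np.uint8)
        attrs = dict(f.attrs)
    coils = CoilSet(sens if sens.ndim == 3 else sens[0])
    mask = SamplingMask(
        mask_data,
        float(attrs.get("fraction", mask_data.mean())),
        expected_ones=int(attrs.get("expected_ones", mask_data.sum())),
    )
    samples = []
    for k_full in kspace:
        y = k_full * mask.data[None]
        coil_imgs = fourier(k_full, "inverse")
        samples.append(
            AcquiredSample(
                coil_images=coil_imgs,
                kspace=y,
                kspace_full=k_full,
                target=coil_combine(coil_imgs, coils),
                zero_filled=zero_filled(y, coils),
                mask=mask,
            )
        )
    return samples, coils, attrs


def export_nifti(images: np.ndarray, path: str | Path) -> None:
    """Save a stack (or single slice) of magnitude images as NIfTI-1."""
    import nibabel as nib

    arr = np.abs(np.asarray(images)).astype(np.float32)
    if arr.ndim == 2:
        arr = arr[..., None]
    elif arr.ndim == 3:  # (N, H, W) -> (H, W, N)
        arr = np.moveaxis(arr, 0, -1)
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))


def export_png(img: np.ndarray, path: str | Path, vmax: float | None = None) -> None:
    """Save a magnitude image as 8-bit PNG, linearly scaled to [0, vmax]."""
    import imageio.v3 as iio

    arr = np.abs(np.asarray(img, dtype=np.float64))
    if vmax is None:
        vmax = float(arr.max()) or 1.0
    scaled = np.clip(arr / vmax, 0.0, 1.0)
    iio.imwrite(str(path), (scaled * 255).round().astype(np.uint8))


def mask_to_png(mask: SamplingMask, path: str | Path) -> None:
    """Save a sampling mask as a 0/255 PNG."""
    import imageio.v3 as iio

    iio.imwrite(str(path), (mask.data * 255).astype(np.uint8))
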