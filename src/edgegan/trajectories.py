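"""K-space undersampling trajectory generators.

Three Cartesian trajectory families, each hitting its sampling quota exactly:

* ``gaussian2d`` — points drawn without replacement with probability
  proportional to a centered 2-D Gaussian density (variable-density random
  sampling; retains exactly ``round(ρ·H·W)`` points).
* ``gaussian1d`` — whole phase-encode lines drawn with Gaussian density over
  the line index (retains exactly ``round(ρ·W)`` full columns).
* ``poisson2d`` — variable-density Poisson-disc dart throwing followed by a
  random trim/fill to the exact point quota.

Exact quotas make a "Gaussian 2D 30%" mask a checkable object rather than a
statistical statement.  All generators are deterministic in their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physics import SamplingMask

__all__ = ["TrajectorySpec", "gaussian2d_mask", "gaussian1d_mask", "poisson2d_mask", "make_mask", "poisson_local_radius"]

KINDS = ("gaussian2d", "gaussian1d", "poisson2d")


@dataclass(frozen=True)
class TrajectorySpec:
    """Parameters of one undersampling trajectory.

    sigma_scale: Gaussian density width as a fraction of the grid half-extent.
    min_radius_scale: base Poisson-disc exclusion radius in pixels at the
        k-space center; the radius grows linearly towards the edge.
    center_fraction: optional fraction of a fully sampled central block/lines
        (calibration region), counted inside the quota. Defaults to 0.
    """

    kind: str
    fraction: float
    shape: tuple[int, int]
    seed: int = 0
    sigma_scale: float = 0.25
    min_radius_scale: float = 1.0
    center_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise ValueError(f"shape must be a positive (H, W), got {self.shape}")
        if not (0.0 <= self.center_fraction < 1.0):
            raise ValueError("center_fraction must be in [0, 1)")


def _gaussian_density_2d(H: int, W: int, sigma_scale: float) -> np.ndarray:
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    sy = max(sigma_scale * H / 2.0, 1e-6)
    sx = max(sigma_scale * W / 2.0, 1e-6)
    yy, xx = np.mgrid[0:H, 0:W]
    return np.exp(-0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))


def _center_block_flat(H: int, W: int, center_fraction: float) -> np.ndarray:
    """Flat indices of a centered block holding ~center_fraction of samples."""
    if center_fraction <= 0.0:
        return np.empty(0, dtype=np.int64)
    h = max(1, int(round(np.sqrt(center_fraction) * H)))
    w = max(1, int(round(np.sqrt(center_fraction) * W)))
    y0, x0 = (H - h) // 2, (W - w) // 2
    yy, xx = np.mgrid[y0 : y0 + h, x0 : x0 + w]
    return (yy * W + xx).ravel()


def _to_mask(flat_idx: np.ndarray, spec: TrajectorySpec, expected: int) -> SamplingMask:
    H, W = spec.shape
    data = np.zeros(H * W, dtype=np.uint8)
    data[flat_idx] = 1
    return SamplingMask(data.reshape(H, W), spec.fraction, expected_ones=expected)


def gaussian2d_mask(spec: TrajectorySpec) -> SamplingMask:
    """Variable-density random point mask with centered Gaussian density."""
    if spec.kind != "gaussian2d":
        raise ValueError(f"spec.kind is {spec.kind!r}, expected 'gaussian2d'")
    H, W = spec.shape
    quota = int(round(spec.fraction * H * W))
    if quota > H * W:
        raise ValueError("quota exceeds grid size")
    rng = np.random.default_rng(spec.seed)
    forced = _center_block_flat(H, W, spec.center_fraction)
    if forced.size >= quota:
        forced = forced[:quota]
        return _to_mask(forced, spec, quota)
    p = _gaussian_density_2d(H, W, spec.sigma_scale).ravel()
    p[forced] = 0.0
    p /= p.sum()
    drawn = rng.choice(H * W, size=quota - forced.size, replace=False, p=p)
    return _to_mask(np.concatenate([forced, drawn]), spec, quota)


def gaussian1d_mask(spec: TrajectorySpec, axis: int = 1) -> SamplingMask:
    """Line mask: whole phase-encode lines with Gaussian density over index.

    ``axis=1`` (default) selects columns, i.e. the phase-encode direction is
    the width axis; ``axis=0`` selects rows.
    """
    if spec.kind != "gaussian1d":
        raise ValueError(f"spec.kind is {spec.kind!r}, expected 'gaussian1d'")
    H, W = spec.shape
    n_lines = W if axis == 1 else H
    other = H if axis == 1 else W
    quota_lines = int(round(spec.fraction * n_lines))
    if quota_lines > n_lines:
        raise ValueError("line quota exceeds line count")
    rng = np.random.default_rng(spec.seed)
    n_forced = int(round(spec.center_fraction * n_lines))
    c = (n_lines - 1) / 2.0
    idx = np.arange(n_lines)
    forced = idx[np.argsort(np.abs(idx - c), kind="stable")][:n_forced]
    forced = forced[:quota_lines]
    sigma = max(spec.sigma_scale * n_lines / 2.0, 1e-6)
    p = np.exp(-0.5 * ((idx - c) / sigma) ** 2)
    p[forced] = 0.0
    if quota_lines > forced.size:
        p /= p.sum()
        drawn = rng.choice(n_lines, size=quota_lines - forced.size, replace=False, p=p)
        lines = np.concatenate([forced, drawn])
    else:
        lines = forced
    data = np.zeros((H, W), dtype=np.uint8)
    if axis == 1:
        data[:, lines] = 1
    else:
        data[lines, :] = 1
    return SamplingMask(data, spec.fraction, expected_ones=quota_lines * other)


def poisson_local_radius(spec: TrajectorySpec) -> np.ndarray:
    """Per-pixel exclusion radius for the Poisson-disc stage.

    Base radius ``min_radius_scale`` pixels at the k-space center, growing
    linearly to 3× at the grid corner — the variable-density profile that
    concentrates samples at low frequencies.
    """
    H, W = spec.shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    d = np.sqrt(((yy - cy) / max(cy, 1)) ** 2 + ((xx - cx) / max(cx, 1)) ** 2)
    d = d / max(float(d.max()), 1e-9)
    return spec.min_radius_scale * (1.0 + 2.0 * d)


def _poisson_dart_throw(spec: TrajectorySpec, rng: np.random.Generator) -> np.ndarray:
    """Greedy dart throwing over a shuffled pixel order. Returns flat indices."""
    H, W = spec.shape
    radius = poisson_local_radius(spec)
    occupied = np.zeros((H, W), dtype=bool)
    order = rng.permutation(H * W)
    accepted: list[int] = []
    for flat in order:
        y, x = divmod(int(flat), W)
        r = radius[y, x]
        ri = int(np.ceil(r))
        y0, y1 = max(0, y - ri), min(H, y + ri + 1)
        x0, x1 = max(0, x - ri), min(W, x + ri + 1)
        window = occupied[y0:y1, x0:x1]
        if window.any():
            wy, wx = np.nonzero(window)
            dist2 = (wy + y0 - y) ** 2 + (wx + x0 - x) ** 2
            if (dist2 < r * r).any():
                continue
        occupied[y, x] = True
        accepted.append(int(flat))
    return np.asarray(accepted, dtype=np.int64)


def poisson2d_mask(spec: TrajectorySpec) -> SamplingMask:
    """Variable-density Poisson-disc mask trimmed/filled to the exact quota."""
    if spec.kind != "poisson2d":
        raise ValueError(f"spec.kind is {spec.kind!r}, expected 'poisson2d'")
    H, W = spec.shape
    quota = int(round(spec.fraction * H * W))
    if quota > H * W:
        raise ValueError("quota exceeds grid size")
    rng = np.random.default_rng(spec.seed)
    forced = _center_block_flat(H, W, spec.center_fraction)[:quota]
    pts = _poisson_dart_throw(spec, rng)
    pts = np.setdiff1d(pts, forced, assume_unique=False)
    pts = np.concatenate([forced, pts])
    if pts.size > quota:
        keep = rng.choice(pts.size - forced.size, size=quota - forced.size, replace=False)
        pts = np.concatenate([forced, pts[forced.size :][keep]])
    elif pts.size < quota:
        rest = np.setdiff1d(np.arange(H * W), pts, assume_unique=False)
        fill = rng.choice(rest.size, size=quota - pts.size, replace=False)
        pts = np.concatenate([pts, rest[fill]])
    return _to_mask(pts, spec, quota)


def make_mask(spec: TrajectorySpec, **kwargs) -> SamplingMask:
    """Dispatch to the generator named by ``spec.kind``."""
    return {
        "gaussian2d": gaussian2d_mask,
        "gaussian1d": gaussian1d_mask,
        "poisson2d": poisson2d_mask,
    }[spec.kind](spec, **kwargs)
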