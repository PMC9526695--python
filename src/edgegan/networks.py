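"""Reconstruction networks.

* ``Generator`` — an improved U-Net operating on 2-channel (real/imaginary)
  images: four stride-2 downsampling blocks, each followed by a residual
  block and a frequency-channel-attention (FCA) block, then four stride-2
  transposed-convolution upsampling blocks with skip concatenation between
  same-scale levels.  Two residual-learning switches produce four ablation
  variants from one code path: *global* residual learning (GR) adds the
  network input to its output, turning the generator into a refinement of
  the zero-filled image; *local* residual learning (LR) enables the 1×1
  shortcut inside each encoder residual block.

* ``Discriminator`` — an 11-conv-layer CNN scoring a 1-channel image
  (magnitude, or Sobel edge map for the edge discriminator): six stride-2
  3×3 convs, two 1×1 convs, a residual block of three 1×1 convs with an
  identity shortcut, then a fully-connected layer and a logistic output.

* FCA squeeze — channels are partitioned evenly into ``n`` groups; group
  ``i`` is summarised by its orthonormal 2-D DCT-II coefficient at a preset
  frequency index.  With ``n = 1`` and the DC index this reduces to global
  average pooling times √(H·W), i.e. the squeeze-and-excite special case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, channel_contract, concat

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "zigzag_indices",
    "dct2_basis",
    "fca_squeeze",
    "FCABlock",
    "Generator",
    "Discriminator",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """U-Net generator hyperparameters. ``depth`` is fixed at 4 scale levels."""

    base_channels: int = 64
    use_global_residual: bool = True
    use_local_residual: bool = True
    fca_n_frequencies: int = 16
    in_channels: int = 2
    out_channels: int = 2
    attention: str = "fca"  # "fca" | "se" | "none"
    depth: int = 4

    def __post_init__(self) -> None:
        if self.depth != 4:
            raise ValueError("generator depth is fixed at 4 down/up block pairs")
        if self.attention not in ("fca", "se", "none"):
            raise ValueError(f"unknown attention kind {self.attention!r}")
        for c in self.level_channels:
            if self.attention == "fca" and c % self.fca_n_frequencies != 0:
                raise ValueError(
                    f"fca_n_frequencies={self.fca_n_frequencies} must divide channel count {c}"
                )

    @property
    def level_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * (2**i) for i in range(self.depth))


@dataclass(frozen=True)
class DiscriminatorConfig:
    """11-layer CNN discriminator: 6 stride-2 convs + 2 1×1 + 3-conv residual."""

    base_channels: int = 32
    in_channels: int = 1
    n_downs: int = 6
    conv_layers: int = field(default=11)

    def __post_init__(self) -> None:
        if self.n_downs + 5 != self.conv_layers:
            raise ValueError("conv_layers must equal n_downs + 5 (= 11 by default)")

    @property
    def min_input(self) -> int:
        return 2**self.n_downs


def zigzag_indices(n: int, H: int = 8, W: int = 8) -> list[tuple[int, int]]:
    """First ``n`` 2-D DCT frequency indices in JPEG zigzag order."""
    if n > H * W:
        raise ValueError(f"cannot pick {n} distinct frequencies on a {H}×{W} grid")
    out: list[tuple[int, int]] = []
    for d in range(H + W - 1):
        diag = range(d + 1)
        for u in (diag if d % 2 == 1 else reversed(diag)):
            v = d - u
            if u < H and v < W:
                out.append((u, v))
                if len(out) == n:
                    return out
    return out


def dct2_basis(u: int, v: int, H: int, W: int) -> np.ndarray:
    """Orthonormal 2-D DCT-II basis function at frequency (u, v)."""
    if not (0 <= u < H and 0 <= v < W):
        raise ValueError(f"DCT index ({u}, {v}) invalid for {H}×{W}")
    h = np.arange(H)
    w = np.arange(W)
    au = np.sqrt((1.0 if u == 0 else 2.0) / H)
    av = np.sqrt((1.0 if v == 0 else 2.0) / W)
    bu = au * np.cos(np.pi * u * (2 * h + 1) / (2 * H))
    bv = av * np.cos(np.pi * v * (2 * w + 1) / (2 * W))
    return np.outer(bu, bv)


def _fca_basis(C: int, n: int, freq_indices: list[tuple[int, int]], H: int, W: int) -> np.ndarray:
    if C % n != 0:
        raise ValueError(f"n={n} must divide channel count C={C}")
    if len(freq_indices) != n:
        raise ValueError(f"need {n} frequency indices, got {len(freq_indices)}")
    group = C // n
    basis = np.empty((C, H, W))
    for i, (u, v) in enumerate(freq_indices):
        basis[i * group : (i + 1) * group] = dct2_basis(u, v, H, W)
    return basis


def fca_squeeze(
    f: Tensor | np.ndarray, n: int, freq_indices: list[tuple[int, int]]
) -> Tensor | np.ndarray:
    """Squeeze an (N, C, H, W) feature block to a length-C vector per sample.

    Channels are split into ``n`` equal groups; every channel in group ``i``
    is contracted against the orthonormal DCT-II template at
    ``freq_indices[i]``.  Accepts a plain array (returns an array) or a
    Tensor (returns a differentiable Tensor).
    """
    arr = f.data if isinstance(f, Tensor) else np.asarray(f)
    if arr.ndim != 4:
        raise ValueError(f"expected (N, C, H, W), got shape {arr.shape}")
    N, C, H, W = arr.shape
    basis = _fca_basis(C, n, freq_indices, H, W)
    if isinstance(f, Tensor):
        return channel_contract(f, basis)
    return np.einsum("nchw,chw->nc", arr, basis, optimize=True)


class FCABlock(nn.Module):
    """Channel attention: DCT squeeze → FC reduce → FC expand → sigmoid scale."""

    def __init__(self, channels: int, n_frequencies: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.n = n_frequencies
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)
        self._basis_cache: dict[tuple[int, int], np.ndarray] = {}

    def _basis(self, H: int, W: int) -> np.ndarray:
        # zigzag index set is rebuilt per spatial size so every template is a
        # valid frequency of the feature map at that scale
        key = (H, W)
        if key not in self._basis_cache:
            idx = zigzag_indices(self.n, H, W)
            self._basis_cache[key] = _fca_basis(self.channels, self.n, idx, H, W)
        return self._basis_cache[key]

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        squeezed = channel_contract(x, self._basis(H, W))  # (N, C)
        w = self.fc2(self.fc1(squeezed).leaky_relu(0.2)).sigmoid()
        return x * w.reshape(N, C, 1, 1)


class _ResidualBlock(nn.Module):
    """Two 3×3 convs (BN+LeakyReLU after the first only) with an optional
    1×1 shortcut conv carrying the local-residual path."""

    def __init__(self, cin: int, cout: int, shortcut: bool, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, 1, 1, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, 1, 1, rng=rng)
        self.shortcut = nn.Conv2d(cin, cout, 1, 1, 0, rng=rng) if shortcut else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv2(self.bn1(self.conv1(x)).leaky_relu(0.2))
        if self.shortcut is not None:
            h = h + self.shortcut(x)
        return h.leaky_relu(0.2)


class _DownBlock(nn.Module):
    def __init__(self, cin: int, cout: int, cfg: GeneratorConfig, rng: np.random.Generator):
        super().__init__()
        self.down = nn.Conv2d(cin, cout, 3, 2, 1, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.res = _ResidualBlock(cout, cout, cfg.use_local_residual, rng)
        if cfg.attention == "fca":
            self.att = FCABlock(cout, cfg.fca_n_frequencies, rng=rng)
        elif cfg.attention == "se":
            self.att = FCABlock(cout, 1, rng=rng)  # DC-only squeeze = SE behaviour
        else:
            self.att = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.res(self.bn(self.down(x)).leaky_relu(0.2))
        return self.att(h) if self.att is not None else h


class _UpBlock(nn.Module):
    """Stride-2 deconv, optional skip concatenation, then a channel-fusing
    residual-style pair of convs without shortcut (the decoder drops both the
    local shortcut and the attention block)."""

    def __init__(self, cin: int, cskip: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.up = nn.ConvTranspose2d(cin, cout, 4, 2, 1, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.fuse = _ResidualBlock(cout + cskip, cout, shortcut=False, rng=rng)

    def forward(self, x: Tensor, skip: Tensor | None) -> Tensor:
        h = self.bn(self.up(x)).leaky_relu(0.2)
        if skip is not None:
            h = concat([h, skip], axis=1)
        return self.fuse(h)


class Generator(nn.Module):
    """Improved U-Net mapping a zero-filled 2-channel image to a reconstruction."""

    def __init__(self, cfg: GeneratorConfig = GeneratorConfig(), seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg.level_channels  # e.g. (64, 128, 256, 512)
        self.down1 = _DownBlock(cfg.in_channels, c[0], cfg, rng)
        self.down2 = _DownBlock(c[0], c[1], cfg, rng)
        self.down3 = _DownBlock(c[1], c[2], cfg, rng)
        self.down4 = _DownBlock(c[2], c[3], cfg, rng)
        self.up1 = _UpBlock(c[3], c[2], c[2], rng)
        self.up2 = _UpBlock(c[2], c[1], c[1], rng)
        self.up3 = _UpBlock(c[1], c[0], c[0], rng)
        self.up4 = _UpBlock(c[0], 0, c[0], rng)
        self.out_conv = nn.Conv2d(c[0], cfg.out_channels, 3, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[-2:]
        if H % 16 or W % 16:
            raise ValueError(f"input size {H}×{W} must be divisible by 16")
        f1 = self.down1(x)  # H/2
        f2 = self.down2(f1)  # H/4
        f3 = self.down3(f2)  # H/8
        f4 = self.down4(f3)  # H/16
        h = self.up1(f4, f3)
        h = self.up2(h, f2)
        h = self.up3(h, f1)
        h = self.up4(h, None)
        out = self.out_conv(h)
        if self.cfg.use_global_residual:
            out = out + x
        return out


class Discriminator(nn.Module):
    """11-conv-layer CNN with a logistic scalar output per input image."""

    def __init__(self, cfg: DiscriminatorConfig = DiscriminatorConfig(), seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        b = cfg.base_channels
        widths = [min(b * (2**i), 8 * b) for i in range(cfg.n_downs)]
        layers: list[nn.Module] = []
        cin = cfg.in_channels
        for w in widths:
            layers += [nn.Conv2d(cin, w, 3, 2, 1, rng=rng), nn.BatchNorm2d(w), nn.LeakyReLU(0.2)]
            cin = w
        layers += [nn.Conv2d(cin, cin // 2, 1, 1, 0, rng=rng), nn.BatchNorm2d(cin // 2), nn.LeakyReLU(0.2)]
        cin = cin // 2
        layers += [nn.Conv2d(cin, cin // 2, 1, 1, 0, rng=rng), nn.BatchNorm2d(cin // 2), nn.LeakyReLU(0.2)]
        cin = cin // 2
        self.features = nn.Sequential(*layers)
        # residual block: three 1×1 convs, identity shortcut
        self.rb1 = nn.Conv2d(cin, cin, 1, 1, 0, rng=rng)
        self.rb_bn1 = nn.BatchNorm2d(cin)
        self.rb2 = nn.Conv2d(cin, cin, 1, 1, 0, rng=rng)
        self.rb_bn2 = nn.BatchNorm2d(cin)
        self.rb3 = nn.Conv2d(cin, cin, 1, 1, 0, rng=rng)
        self.final_channels = cin
        self.fc = nn.Linear(cin, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[-2:]
        if H < self.cfg.min_input or W < self.cfg.min_input:
            raise ValueError(
                f"input {H}×{W} below discriminator minimum {self.cfg.min_input}"
            )
        h = self.features(x)
        r = self.rb_bn1(self.rb1(h)).leaky_relu(0.2)
        r = self.rb_bn2(self.rb2(r)).leaky_relu(0.2)
        r = self.rb3(r)
        h = (h + r).leaky_relu(0.2)
        N = h.shape[0]
        pooled = h.mean(axis=(2, 3)).reshape(N, self.final_channels)
        return self.fc(pooled).sigmoid().reshape(N)
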