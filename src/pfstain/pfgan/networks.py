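"""Networks for pathology-fidelity stain translation.

The generator is the ResNet encoder/decoder used throughout unpaired
image-to-image translation work: a 7x7 stem, two stride-2 downsampling
convolutions, residual blocks at the bottleneck (9 by default), then two
nearest-neighbour-upsample + 3x3 convolution stages and a 7x7 tanh head.
Upsampling by interpolation-then-convolution avoids transposed-convolution
checkerboard artifacts.

The encoder half (stem, downsampling, residual blocks) is exposed separately:
its intermediate activations feed the contrastive PatchNCE projection heads,
and its pooled output feeds the one-layer pathology-fidelity classifier that
scores a patch as EBER-positive or EBER-negative.

The discriminator is the standard patch-based (PatchGAN) convolutional
classifier scoring overlapping receptive fields rather than whole images.
"""

from __future__ import annotations

import numpy as np

from .. import nn
from ..nn.tensor import Tensor, concatenate

__all__ = [
    "ResnetGenerator",
    "PatchDiscriminator",
    "PatchSampleMLP",
    "FidelityClassifier",
    "sample_feature_patches",
]


class ResnetBlock(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(channels, channels, 3, rng, padding=1, pad_mode="reflect")
        self.norm1 = nn.InstanceNorm2d(channels)
        self.conv2 = nn.Conv2d(channels, channels, 3, rng, padding=1, pad_mode="reflect")
        self.norm2 = nn.InstanceNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return x + h


class ResnetGenerator(nn.Module):
    """Encoder/decoder translator between stain domains.

    Parameters
    ----------
    ngf:
        Base channel width (64 at full scale; smaller for desk-scale runs).
    n_blocks:
        Number of residual blocks at the bottleneck (default 9).
    n_down:
        Number of stride-2 downsampling stages; input spatial dimensions must
        be divisible by ``2 ** n_down``.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        ngf: int = 64,
        n_blocks: int = 9,
        n_down: int = 2,
        img_channels: int = 3,
    ):
        self.ngf = ngf
        self.n_blocks = n_blocks
        self.n_down = n_down
        self.stem = nn.Conv2d(img_channels, ngf, 7, rng, padding=3, pad_mode="reflect")
        self.stem_norm = nn.InstanceNorm2d(ngf)
        self.down = []
        ch = ngf
        for _ in range(n_down):
            self.down.append(
                nn.Sequential(
                    nn.Conv2d(ch, ch * 2, 3, rng, stride=2, padding=1),
                    nn.InstanceNorm2d(ch * 2),
                    nn.ReLU(),
                )
            )
            ch *= 2
        self.blocks = [ResnetBlock(ch, rng) for _ in range(n_blocks)]
        self.bottleneck_channels = ch
        self.up = []
        for _ in range(n_down):
            self.up.append(
                nn.Sequential(
                    nn.Conv2d(ch, ch // 2, 3, rng, padding=1),
                    nn.InstanceNorm2d(ch // 2),
                    nn.ReLU(),
                )
            )
            ch //= 2
        self.head = nn.Conv2d(ch, img_channels, 7, rng, padding=3, pad_mode="reflect")

    # Feature taps for PatchNCE: the raw image, the stem, each downsampling
    # stage, and the bottleneck output (mirrors the multi-depth sampling of
    # contrastive unpaired translation).
    def encode(self, x: Tensor, return_feats: bool = False):
        feats = [x]
        h = self.stem_norm(self.stem(x)).relu()
        feats.append(h)
        for stage in self.down:
            h = stage(h)
            feats.append(h)
        for block in self.blocks:
            h = block(h)
        feats.append(h)
        if return_feats:
            return h, feats
        return h

    def decode(self, h: Tensor) -> Tensor:
        for stage in self.up:
            h = stage(h.upsample_nearest(2))
        return self.head(h).tanh()

    def forward(self, x: Tensor) -> Tensor:
        self._check_size(x)
        return self.decode(self.encode(x))

    def _check_size(self, x: Tensor) -> None:
        div = 2**self.n_down
        h, w = x.shape[-2], x.shape[-1]
        if h % div or w % div:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by {div} "
                f"(network has {self.n_down} stride-2 stages)"
            )

    def feature_channels(self) -> list[int]:
        chans = [3, self.ngf]
        ch = self.ngf
        for _ in range(self.n_down):
            ch *= 2
            chans.append(ch)
        chans.append(ch)
        return chans


class PatchDiscriminator(nn.Module):
    """PatchGAN: stacked stride-2 convolutions ending in a 1-channel map."""

    def __init__(self, rng: np.random.Generator, ndf: int = 64, n_layers: int = 3):
        layers: list[nn.Module] = [
            nn.Conv2d(3, ndf, 4, rng, stride=2, padding=1),
            nn.LeakyReLU(0.2),
        ]
        ch = ndf
        for i in range(1, n_layers):
            prev, ch = ch, min(ndf * 2**i, ndf * 8)
            layers += [
                nn.Conv2d(prev, ch, 4, rng, stride=2, padding=1),
                nn.InstanceNorm2d(ch),
                nn.LeakyReLU(0.2),
            ]
        prev, ch = ch, min(ndf * 2**n_layers, ndf * 8)
        layers += [
            nn.Conv2d(prev, ch, 4, rng, stride=1, padding=1),
            nn.InstanceNorm2d(ch),
            nn.LeakyReLU(0.2),
            nn.Conv2d(ch, 1, 4, rng, stride=1, padding=1),
        ]
        self.net = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class PatchSampleMLP(nn.Module):
    """Two-layer perceptron projecting sampled encoder features.

    One head per tapped encoder depth; outputs are L2-normalised embeddings
    used as queries/keys in the PatchNCE contrastive loss.
    """

    def __init__(self, feature_channels: list[int], rng: np.random.Generator, dim: int = 64):
        self.dim = dim
        self.heads = [
            nn.Sequential(nn.Linear(c, dim, rng), nn.ReLU(), nn.Linear(dim, dim, rng))
            for c in feature_channels
        ]

    def project(self, feats: list[Tensor], locations: list[np.ndarray]) -> list[Tensor]:
        """Project features gathered at flat spatial `locations` per depth.

        Each element of `feats` is (N, C, H, W); the matching element of
        `locations` is an integer array (N, S) of flat H*W indices.
        """
        out = []
        for head, feat, loc in zip(self.heads, feats, locations):
            n, c, h, w = feat.shape
            flat = feat.reshape(n, c, h * w).transpose(0, 2, 1)  # N, HW, C
            rows = np.repeat(np.arange(n), loc.shape[1])
            gathered = flat[rows, loc.reshape(-1)]  # N*S, C
            z = head(gathered)
            norm = ((z * z).sum(axis=1, keepdims=True) + 1e-12) ** -0.5
            out.append(z * norm)
        return out


class FidelityClassifier(nn.Module):
    """One-layer head: pooled bottleneck features -> P(EBER-positive).

    Global average pooling over the spatial axes is the permutation-invariant
    reduction from the (N, C, H, W) encoder output to one vector per patch.
    """

    def __init__(self, in_channels: int, rng: np.random.Generator):
        self.fc = nn.Linear(in_channels, 1, rng)

    def forward(self, encoder_out: Tensor) -> Tensor:
        pooled = encoder_out.mean(axis=(2, 3))
        return self.fc(pooled).sigmoid().reshape(-1)


def sample_feature_patches(
    feats: list[Tensor], n_patches: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Draw per-depth flat spatial indices shared across a batch dimension.

    Returns one (N, S) index array per tapped depth, S = min(n_patches, H*W).
    The same locations must be reused for the paired (input, translated)
    feature stacks so that positives correspond spatially.
    """
    locations = []
    for feat in feats:
        n, _, h, w = feat.shape
        s = min(n_patches, h * w)
        loc = np.stack([rng.permutation(h * w)[:s] for _ in range(n)])
        locations.append(loc)
    return locations
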