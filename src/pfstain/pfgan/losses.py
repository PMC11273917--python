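"""Loss functions for pathology-fidelity stain translation.

The full objective is

    L = L_GAN(G, D, X, Y) + L_NCE(G, H, X) + L_NCE(G, H, Y) + lambda_PF * L_PF

where L_GAN is a least-squares adversarial loss, the two PatchNCE terms are
contrastive losses tying local features of the input and translated images
(the Y-domain term is the identity pass G(Y) vs Y), and L_PF is the
pathology-fidelity term: the mean L1 distance between the one-layer
classifier's prediction on pooled encoder features of real target-domain
patches and their (auto-annotated) positive/negative labels. With
lambda_PF = 0 the objective is exactly the contrastive-unpaired-translation
(CUT) objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn.tensor import Tensor, as_tensor, concatenate

__all__ = [
    "pf_loss",
    "patchnce_loss",
    "patchnce_loss_pairwise",
    "lsgan_loss",
    "LossWeights",
    "LossBreakdown",
]


@dataclass(frozen=True)
class LossWeights:
    """Objective weights; the adversarial and both NCE weights default to 1."""

    lambda_gan: float = 1.0
    lambda_nce_x: float = 1.0
    lambda_nce_y: float = 1.0
    lambda_pf: float = 1.0

    def __post_init__(self):
        for name, value in vars(self).items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass
class LossBreakdown:
    gan: float
    nce_x: float
    nce_y: float
    pf: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "gan": self.gan,
            "nce_x": self.nce_x,
            "nce_y": self.nce_y,
            "pf": self.pf,
            "total": self.total,
        }


def pf_loss(predictions, labels) -> Tensor:
    """Pathology-fidelity loss: mean |prediction - label| over the batch.

    Predictions are classifier outputs in [0, 1]; labels are hard {0, 1}
    positivity labels of real target-domain patches.
    """
    predictions = as_tensor(predictions)
    labels_arr = np.asarray(labels if not isinstance(labels, Tensor) else labels.data, dtype=np.float64)
    if predictions.shape != labels_arr.shape:
        raise ValueError(
            f"predictions and labels must have equal length: "
            f"{predictions.shape} vs {labels_arr.shape}"
        )
    if predictions.size == 0:
        raise ValueError("pf_loss requires a non-empty batch")
    if not np.isin(labels_arr, (0.0, 1.0)).all():
        raise ValueError("labels must be in {0, 1}")
    return (predictions - Tensor(labels_arr)).abs().mean()


def patchnce_loss(query, positive, negatives, tau: float = 0.07) -> Tensor:
    """Contrastive PatchNCE loss over sampled feature locations.

    Parameters
    ----------
    query:
        (N, D) embeddings from the translated image.
    positive:
        (N, D) embeddings from the matching locations of the input image.
    negatives:
        (N, K, D) embeddings from K other locations, K >= 1.
    tau:
        Softmax temperature (> 0).

    Each row is scored by a softmax cross-entropy over the (1 + K) cosine
    logits scaled by 1/tau, with the positive as the true class. Features are
    expected unit-normalised; zero-norm rows raise.
    """
    if tau <= 0:
        raise ValueError(f"temperature must be > 0, got {tau}")
    query, positive, negatives = as_tensor(query), as_tensor(positive), as_tensor(negatives)
    if negatives.ndim != 3 or negatives.shape[1] < 1:
        raise ValueError("negatives must be (N, K, D) with K >= 1")
    for name, t in (("query", query), ("positive", positive), ("negatives", negatives)):
        norms = np.linalg.norm(t.data, axis=-1)
        if np.any(norms < 1e-8):
            raise ValueError(f"zero-norm feature vector in {name}")
    n, d = query.shape
    l_pos = (query * positive).sum(axis=1, keepdims=True)  # (N, 1)
    l_neg = (negatives @ query.reshape(n, d, 1)).reshape(n, -1)  # (N, K)
    logits = concatenate([l_pos, l_neg], axis=1) * (1.0 / tau)
    # cross-entropy with the positive at index 0
    return (logits.logsumexp(axis=1).reshape(n) - logits[:, 0]).mean()


def patchnce_loss_pairwise(queries, keys, n_images: int, tau: float = 0.07) -> Tensor:
    """PatchNCE via the pairwise-logit form used during training.

    `queries` and `keys` are (n_images * S, D) stacked unit embeddings; for
    each query the matching key is the positive and the other S - 1 keys of
    the same image are the negatives. Mathematically identical to
    :func:`patchnce_loss` with the negatives materialised explicitly, but
    computes the (S, S) similarity matrix per image instead.
    """
    if tau <= 0:
        raise ValueError(f"temperature must be > 0, got {tau}")
    queries, keys = as_tensor(queries), as_tensor(keys)
    total, d = queries.shape
    if total % n_images:
        raise ValueError("embedding count must be a multiple of n_images")
    s = total // n_images
    if s < 2:
        raise ValueError("need at least 2 locations per image for negatives")
    q = queries.reshape(n_images, s, d)
    k = keys.reshape(n_images, s, d)
    logits = (q @ k.transpose(0, 2, 1)) * (1.0 / tau)  # (n, S, S)
    img_idx = np.repeat(np.arange(n_images), s)
    loc_idx = np.tile(np.arange(s), n_images)
    positives = logits[img_idx, loc_idx, loc_idx]  # diagonal per image
    return (logits.logsumexp(axis=2).reshape(n_images * s) - positives).mean()


def lsgan_loss(scores: Tensor, target_is_real: bool) -> Tensor:
    """Least-squares adversarial loss: mean (D(x) - target)^2, target in {0,1}."""
    target = 1.0 if target_is_real else 0.0
    diff = scores - target
    return (diff * diff).mean()
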