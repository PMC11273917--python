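"""Training and inference for the pathology-fidelity stain-translation GAN.

One training iteration follows the CUT update convention:

1. translate a source batch, ``fake = G(x)``;
2. update the discriminator on a least-squares real/fake objective with the
   generated batch detached;
3. update the generator, the PatchNCE projection heads and the fidelity
   classifier jointly on

       L_GAN(G, D) + L_NCE(x, G(x)) + L_NCE(y, G(y)) + lambda_PF * L_PF(y)

   where the identity pass G(y) supplies the target-domain NCE term and the
   PF term is the L1 classification loss of the one-layer head on pooled
   encoder features of the real target batch (so the PF gradient flows into
   the shared encoder).

The learning rate is constant until ``decay_start`` and then decays linearly
to zero at the final epoch. All randomness (weight init, data order, NCE
location sampling) derives from a single seed via independent child streams.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ..nn import Adam
from ..nn.tensor import Tensor
from .losses import (
    LossBreakdown,
    LossWeights,
    lsgan_loss,
    patchnce_loss_pairwise,
    pf_loss,
)
from .networks import (
    FidelityClassifier,
    PatchDiscriminator,
    PatchSampleMLP,
    ResnetGenerator,
    sample_feature_patches,
)

__all__ = [
    "TrainConfig",
    "Models",
    "TrainState",
    "NumericalError",
    "lr_at_epoch",
    "build_models",
    "total_loss",
    "discriminator_loss",
    "train",
    "stain",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


class NumericalError(RuntimeError):
    """A loss component became non-finite during training."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule and architecture sizes.

    Full-scale defaults: Adam(beta1=0.5, beta2=0.999) at 2e-4 for 200 epochs,
    batch size 4, linear learning-rate decay starting at the midpoint.
    """

    lr: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    epochs: int = 200
    batch_size: int = 4
    decay_start: int | None = None  # None -> epochs // 2
    seed: int = 0
    ngf: int = 64
    ndf: int = 64
    n_blocks: int = 9
    n_layers_d: int = 3
    nce_dim: int = 64
    n_nce_patches: int = 256
    tau: float = 0.07

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.decay_start is not None and not 0 <= self.decay_start <= self.epochs:
            raise ValueError("decay_start must lie in [0, epochs]")

    @property
    def decay_from(self) -> int:
        return self.epochs // 2 if self.decay_start is None else self.decay_start


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Learning rate at the start of `epoch`: flat, then linear to 0."""
    if not 0 <= epoch <= config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs}]")
    start = config.decay_from
    if epoch <= start:
        return config.lr
    return config.lr * (1.0 - (epoch - start) / (config.epochs - start))


@dataclass
class Models:
    generator: ResnetGenerator
    discriminator: PatchDiscriminator
    nce_head: PatchSampleMLP
    classifier: FidelityClassifier


@dataclass
class TrainState:
    models: Models
    config: TrainConfig
    weights: LossWeights
    epoch: int = 0
    history: list[dict[str, float]] = field(default_factory=list)


def build_models(config: TrainConfig) -> Models:
    """Construct all four networks reproducibly from the config seed."""
    init = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    gen = ResnetGenerator(init, ngf=config.ngf, n_blocks=config.n_blocks)
    disc = PatchDiscriminator(init, ndf=config.ndf, n_layers=config.n_layers_d)
    head = PatchSampleMLP(gen.feature_channels(), init, dim=config.nce_dim)
    cls = FidelityClassifier(gen.bottleneck_channels, init)
    return Models(gen, disc, head, cls)


def to_unit_range(patches: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float (N, 3, H, W) in [-1, 1]."""
    x = np.asarray(patches, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    return x.transpose(0, 3, 1, 2) / 127.5 - 1.0


def from_unit_range(x: np.ndarray) -> np.ndarray:
    """float (N, 3, H, W) in [-1, 1] -> uint8 (N, H, W, 3)."""
    img = np.clip((x + 1.0) * 127.5, 0, 255)
    return np.rint(img).astype(np.uint8).transpose(0, 2, 3, 1)


def _multilayer_nce(
    models: Models,
    feats_real: list[Tensor],
    feats_fake: list[Tensor],
    n_patches: int,
    tau: float,
    rng: np.random.Generator,
) -> Tensor:
    """PatchNCE averaged over encoder depths.

    Queries come from the translated image's features, positives from the
    same spatial locations of the real image's features, and negatives from
    the other sampled locations of the same image (internal negatives), via
    the pairwise-logit form of the loss.
    """
    locations = sample_feature_patches(feats_real, n_patches, rng)
    keys = models.nce_head.project(feats_real, locations)
    queries = models.nce_head.project(feats_fake, locations)
    n = feats_real[0].shape[0]
    total = None
    used = 0
    for q, k, loc in zip(queries, keys, locations):
        if loc.shape[1] < 2:
            continue  # no negatives available at this depth
        loss = patchnce_loss_pairwise(q, k, n, tau=tau)
        total = loss if total is None else total + loss
        used += 1
    if total is None:
        raise ValueError("need at least 2 sampled locations per depth for NCE")
    return total * (1.0 / used)


def total_loss(
    models: Models,
    batch_x: np.ndarray,
    batch_y: np.ndarray,
    labels_y: np.ndarray | None,
    weights: LossWeights,
    config: TrainConfig,
    rng_nce: np.random.Generator,
):
    """Generator-side objective on one batch pair.

    Returns ``(total, breakdown, fake)`` where `total` is the Tensor to
    backpropagate, `breakdown` records the unweighted components, and `fake`
    is the translated source batch (reused for the discriminator update).
    With ``lambda_pf = 0`` the total is exactly the CUT objective.
    """
    if len(batch_x) == 0 or len(batch_y) == 0:
        raise ValueError("batches must be non-empty")
    if weights.lambda_pf > 0 and labels_y is None:
        raise ValueError("target labels are required when lambda_pf > 0")
    x = Tensor(to_unit_range(batch_x))
    y = Tensor(to_unit_range(batch_y))

    h_x, feats_x = models.generator.encode(x, return_feats=True)
    fake = models.generator.decode(h_x)
    gan = lsgan_loss(models.discriminator(fake), target_is_real=True)
    _, feats_fake = models.generator.encode(fake, return_feats=True)
    nce_x = _multilayer_nce(models, feats_x, feats_fake, config.n_nce_patches, config.tau, rng_nce)

    enc_y, feats_y = models.generator.encode(y, return_feats=True)
    idt = models.generator.decode(enc_y)
    _, feats_idt = models.generator.encode(idt, return_feats=True)
    nce_y = _multilayer_nce(models, feats_y, feats_idt, config.n_nce_patches, config.tau, rng_nce)

    if weights.lambda_pf > 0:
        pf = pf_loss(models.classifier(enc_y), np.asarray(labels_y, dtype=np.float64))
        pf_value = pf.item()
    else:
        pf = None
        pf_value = float("nan")

    total = weights.lambda_gan * gan + weights.lambda_nce_x * nce_x + weights.lambda_nce_y * nce_y
    if pf is not None:
        total = total + weights.lambda_pf * pf
    breakdown = LossBreakdown(gan.item(), nce_x.item(), nce_y.item(), pf_value, total.item())
    return total, breakdown, fake


def discriminator_loss(models: Models, batch_y: np.ndarray, fake: Tensor) -> Tensor:
    """LSGAN discriminator objective; the generated batch is detached."""
    y = Tensor(to_unit_range(batch_y))
    real_term = lsgan_loss(models.discriminator(y), target_is_real=True)
    fake_term = lsgan_loss(models.discriminator(fake.detach()), target_is_real=False)
    return (real_term + fake_term) * 0.5


def _check_finite(breakdown: LossBreakdown, d_loss: float) -> None:
    values = dict(breakdown.as_dict(), discriminator=d_loss)
    for name, value in values.items():
        if name == "pf" and np.isnan(value):
            continue  # pf disabled
        if not np.isfinite(value):
            raise NumericalError(f"loss component '{name}' is non-finite ({value})")


def train(
    source_patches: np.ndarray,
    target_patches: np.ndarray,
    target_labels: np.ndarray | None,
    config: TrainConfig,
    weights: LossWeights | None = None,
) -> TrainState:
    """Train on unpaired uint8 patch stacks (N, H, W, 3).

    `target_labels` are the {0,1} positivity labels of the real target-domain
    patches, normally produced by the rule-based auto-annotation. Returns the
    final state with a per-epoch history of mean loss components.
    """
    weights = weights or LossWeights()
    if weights.lambda_pf > 0:
        if target_labels is None:
            raise ValueError("target labels are required when lambda_pf > 0")
        target_labels = np.asarray(target_labels, dtype=np.float64)
        if len(target_labels) != len(target_patches):
            raise ValueError("one label per target patch required")

    models = build_models(config)
    state = TrainState(models, config, weights)
    gen_params = (
        models.generator.parameters()
        + models.nce_head.parameters()
        + models.classifier.parameters()
    )
    opt_g = Adam(gen_params, lr=config.lr, betas=(config.beta1, config.beta2))
    opt_d = Adam(models.discriminator.parameters(), lr=config.lr, betas=(config.beta1, config.beta2))

    rng_data = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rng_nce = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    n_iter = min(len(source_patches), len(target_patches)) // config.batch_size
    if config.epochs > 0 and n_iter == 0:
        raise ValueError("fewer patches than one batch")

    for epoch in range(config.epochs):
        lr = lr_at_epoch(config, epoch)
        opt_g.lr = lr
        opt_d.lr = lr
        perm_x = rng_data.permutation(len(source_patches))
        perm_y = rng_data.permutation(len(target_patches))
        sums = {"gan": 0.0, "nce_x": 0.0, "nce_y": 0.0, "pf": 0.0, "total": 0.0, "d": 0.0}
        for it in range(n_iter):
            bx = source_patches[perm_x[it * config.batch_size : (it + 1) * config.batch_size]]
            by_idx = perm_y[it * config.batch_size : (it + 1) * config.batch_size]
            by = target_patches[by_idx]
            ly = None if target_labels is None else target_labels[by_idx]

            total, breakdown, fake = total_loss(
                models, bx, by, ly, weights, config, rng_nce
            )

            d_loss = discriminator_loss(models, by, fake)
            opt_d.zero_grad()
            d_loss.backward()
            _check_finite(breakdown, d_loss.item())
            opt_d.step()

            opt_g.zero_grad()
            models.discriminator.zero_grad()  # G's GAN term passed through D
            total.backward()
            opt_g.step()

            for key, val in breakdown.as_dict().items():
                sums[key] += val
            sums["d"] += d_loss.item()

        record = {k: v / n_iter for k, v in sums.items()}
        record["epoch"] = epoch
        record["lr"] = lr
        state.history.append(record)
        state.epoch = epoch + 1
    return state


def stain(patch: np.ndarray, state: TrainState) -> np.ndarray:
    """Translate one uint8 (H, W, 3) source-domain patch to the target style.

    Inference is deterministic: the networks have no stochastic layers.
    """
    x = Tensor(to_unit_range(patch))
    state.models.generator._check_size(x)
    out = state.models.generator.decode(state.models.generator.encode(x))
    return from_unit_range(out.data)[0]


def stain_batch(patches: np.ndarray, state: TrainState, batch_size: int = 8) -> np.ndarray:
    out = []
    for i in range(0, len(patches), batch_size):
        x = Tensor(to_unit_range(patches[i : i + batch_size]))
        state.models.generator._check_size(x)
        y = state.models.generator.decode(state.models.generator.encode(x))
        out.append(from_unit_range(y.data))
    return np.concatenate(out, axis=0)


def save_checkpoint(state: TrainState, path) -> None:
    """Serialise networks + config to a single .npz with a version tag."""
    arrays: dict[str, np.ndarray] = {}
    for tag, module in (
        ("G", state.models.generator),
        ("D", state.models.discriminator),
        ("H", state.models.nce_head),
        ("C", state.models.classifier),
    ):
        for name, value in module.state_dict().items():
            arrays[f"{tag}.{name}"] = value
    meta = {
        "version": CHECKPOINT_VERSION,
        "epoch": state.epoch,
        "config": asdict(state.config),
        "weights": asdict(state.weights),
        "history": state.history,
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> TrainState:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        config = TrainConfig(**meta["config"])
        models = build_models(config)
        for tag, module in (
            ("G", models.generator),
            ("D", models.discriminator),
            ("H", models.nce_head),
            ("C", models.classifier),
        ):
            prefix = f"{tag}."
            module.load_state_dict(
                {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)}
            )
    state = TrainState(models, config, LossWeights(**meta["weights"]))
    state.epoch = meta["epoch"]
    state.history = meta["history"]
    return state
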