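"""3D conditional adversarial network for DIR synthesis.

A U-shaped fully convolutional generator translates co-registered predictor
channels (T1w, PDw, T2w) into an artificial DIR patch; a PatchGAN
discriminator scores (predictors + candidate DIR) jointly over limited
receptive fields.  Training alternates one discriminator and one generator
Adam step per batch, minimizing binary cross entropy plus an L1
reconstruction term weighted by ``mae_weight``.  Whole volumes are predicted
by sliding-window inference with uniform overlap averaging.
"""

from __future__ import annotations

import dataclasses
import inspect
import json
from typing import Sequence

import numpy as np

from . import sampler
from .data import VolumeChannelStack
from .nn import (
    Adam,
    Conv3d,
    InstanceNorm3d,
    LeakyReLU,
    NearestUpsample3d,
    Sequential,
    Sigmoid,
    Tanh,
)

__all__ = [
    "NetworkConfig",
    "TrainingHistory",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "bce_loss",
    "generator_loss",
    "discriminator_loss",
    "receptive_field",
    "train",
    "predict_volume",
    "DirGan",
    "save_generator",
    "load_generator",
]

_EPS = 1e-7


@dataclasses.dataclass
class NetworkConfig:
    """Architecture and training hyperparameters of the translation network.

    Defaults reflect the full-scale configuration (five encoder levels, 32
    base filters, 128-cube patches, 350 epochs); tests and phantom pipelines
    shrink ``depth``/``base_filters``/``patch_edge``/``epochs`` and set
    ``samples_per_epoch`` explicitly.
    """

    depth: int = 5
    base_filters: int = 32
    kernel: int = 3
    leaky_slope: float = 0.2
    in_channels: int = 3
    mae_weight: float = 100.0
    lr: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    epochs: int = 350
    batch_size: int = 2
    patch_edge: int = 128
    epoch_multiplier: int = 8
    samples_per_epoch: int | None = None
    disc_base_filters: int = 32
    disc_stages: int = 3
    disc_kernel: int = 4
    augment: bool = True

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be at least 2")
        if self.patch_edge % 2 ** (self.depth - 1) != 0:
            raise ValueError("patch_edge must be divisible by 2**(depth-1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclasses.dataclass
class TrainingHistory:
    """Per-epoch loss curves of one training run."""

    g_mae: list[float] = dataclasses.field(default_factory=list)
    g_adv: list[float] = dataclasses.field(default_factory=list)
    d_loss: list[float] = dataclasses.field(default_factory=list)
    val_mae: list[float] = dataclasses.field(default_factory=list)


class Generator:
    """Encoder-decoder with skip concatenation; tanh output in [-1, 1]."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.config = config
        f, d, k, a = config.base_filters, config.depth, config.kernel, config.leaky_slope
        self.enc: list[Sequential] = []
        for i in range(d):
            cin = config.in_channels if i == 0 else f * 2 ** (i - 1)
            cout = f * 2**i
            stride = 1 if i == 0 else 2
            self.enc.append(
                Sequential(
                    Conv3d(cin, cout, k, stride, rng=rng),
                    InstanceNorm3d(cout),
                    LeakyReLU(a),
                )
            )
        self.dec: list[tuple[NearestUpsample3d, Sequential]] = []
        for i in range(d - 2, -1, -1):
            cin = f * 2 ** (i + 1) + f * 2**i  # upsampled + skip
            cout = f * 2**i
            self.dec.append(
                (
                    NearestUpsample3d(2),
                    Sequential(
                        Conv3d(cin, cout, k, 1, rng=rng),
                        InstanceNorm3d(cout),
                        LeakyReLU(a),
                    ),
                )
            )
        self.head = Sequential(Conv3d(f, 1, k, 1, rng=rng, init_gain=1.0), Tanh())

    def parameters(self):
        ps = [p for blk in self.enc for p in blk.parameters()]
        for up, conv in self.dec:
            ps += conv.parameters()
        return ps + self.head.parameters()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        d = self.config.depth
        if any(s % 2 ** (d - 1) for s in x.shape[2:]):
            raise ValueError(
                f"input extent {x.shape[2:]} not divisible by 2**(depth-1) = {2 ** (d - 1)}"
            )
        skips = []
        h = x
        for i, blk in enumerate(self.enc):
            h = blk.forward(h, train=train)
            if i < d - 1:
                skips.append(h)
        self._split_channels = []
        for j, (up, conv) in enumerate(self.dec):
            h = up.forward(h, train=train)
            skip = skips[d - 2 - j]
            self._split_channels.append(h.shape[1])
            h = np.concatenate([h, skip], axis=1)
            h = conv.forward(h, train=train)
        return self.head.forward(h, train=train)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        d = self.config.depth
        g = self.head.backward(gout)
        skip_grads: dict[int, np.ndarray] = {}
        for j in range(len(self.dec) - 1, -1, -1):
            up, conv = self.dec[j]
            g = conv.backward(g)
            cut = self._split_channels[j]
            skip_grads[d - 2 - j] = g[:, cut:]
            g = up.backward(g[:, :cut])
        for i in range(d - 1, 0, -1):
            g = self.enc[i].backward(g)
            g = g + skip_grads[i - 1]
        return self.enc[0].backward(g)


class Discriminator:
    """PatchGAN: strided conv stages, then a one-strided sigmoid score map."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.config = config
        k, a = config.disc_kernel, config.leaky_slope
        cin = config.in_channels + 1
        layers: list = []
        self._kernels, self._strides = [], []
        for j in range(config.disc_stages):
            cout = config.disc_base_filters * 2**j
            layers.append(Conv3d(cin, cout, k, stride=2, pad=1, rng=rng))
            if j > 0:
                layers.append(InstanceNorm3d(cout))
            layers.append(LeakyReLU(a))
            self._kernels.append(k)
            self._strides.append(2)
            cin = cout
        layers += [Conv3d(cin, 1, k, stride=1, pad=1, rng=rng, init_gain=1.0), Sigmoid()]
        self._kernels.append(k)
        self._strides.append(1)
        self.net = Sequential(*layers)

    def parameters(self):
        return self.net.parameters()

    @property
    def receptive_field_(self) -> int:
        return receptive_field(self._kernels, self._strides)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.net.forward(x, train=train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return self.net.backward(gout)

    def score(self, predictors: np.ndarray, candidate: np.ndarray, train: bool = True) -> np.ndarray:
        """Validity map for a candidate DIR conditioned on its predictors."""
        if predictors.shape[0] != candidate.shape[0] or predictors.shape[2:] != candidate.shape[2:]:
            raise ValueError("condition and candidate spatial extents differ")
        return self.forward(np.concatenate([predictors, candidate], axis=1), train=train)


def build_generator(config: NetworkConfig, seed: int | None = None) -> Generator:
    return Generator(config, np.random.default_rng(seed))


def build_discriminator(config: NetworkConfig, seed: int | None = None) -> Discriminator:
    return Discriminator(config, np.random.default_rng(seed))


def receptive_field(kernels: Sequence[int], strides: Sequence[int]) -> int:
    """Receptive field of one output element of a conv stack (closed form)."""
    r = 1
    jump = 1
    for k, s in zip(kernels, strides):
        r += (k - 1) * jump
        jump *= s
    return r


# ---------------------------------------------------------------------------
# losses


def bce_loss(pred: np.ndarray, target: float | np.ndarray) -> float:
    p = np.clip(np.asarray(pred, dtype=np.float64), _EPS, 1.0 - _EPS)
    t = np.broadcast_to(np.asarray(target, dtype=np.float64), p.shape)
    return float(np.mean(-t * np.log(p) - (1.0 - t) * np.log(1.0 - p)))


def _bce_grad(pred: np.ndarray, target: float) -> np.ndarray:
    p = np.clip(np.asarray(pred, dtype=np.float64), _EPS, 1.0 - _EPS)
    return ((p - target) / (p * (1.0 - p)) / p.size).astype(np.float32)


def generator_loss(
    validity_on_fake: np.ndarray, fake: np.ndarray, real: np.ndarray, mae_weight: float
) -> float:
    """BCE of the fake's validity against all-ones plus weighted L1 term."""
    if fake.shape != real.shape:
        raise ValueError("fake and real shapes differ")
    return bce_loss(validity_on_fake, 1.0) + mae_weight * float(np.mean(np.abs(fake - real)))


def discriminator_loss(validity_on_real: np.ndarray, validity_on_fake: np.ndarray) -> float:
    """Mean of BCE(real -> 1) and BCE(fake -> 0)."""
    return 0.5 * (bce_loss(validity_on_real, 1.0) + bce_loss(validity_on_fake, 0.0))


# ---------------------------------------------------------------------------
# training


def _draw_batch(
    volumes: Sequence[VolumeChannelStack],
    config: NetworkConfig,
    rng: np.random.Generator,
    augment_params: sampler.AugmentParams | None,
):
    xs, ys = [], []
    for _ in range(config.batch_size):
        vol = volumes[int(rng.integers(len(volumes)))]
        center = sampler.sample_patch_centers(vol.mask, 1, rng)[0]
        pair = sampler.extract_patch(vol, center, config.patch_edge)
        if augment_params is not None:
            pair = sampler.augment(pair, augment_params, rng)
        xs.append(pair.predictors)
        ys.append(pair.target)
    x = np.stack(xs).astype(np.float32)
    y = np.stack(ys)[:, None].astype(np.float32)
    return x, y


def train(
    train_volumes: Sequence[VolumeChannelStack],
    config: NetworkConfig,
    seed: int | None = None,
    val_volumes: Sequence[VolumeChannelStack] | None = None,
    augment_params: sampler.AugmentParams | None = None,
    log_every: int = 0,
) -> tuple[Generator, TrainingHistory]:
    """Alternating adversarial training of generator and discriminator.

    Per-epoch sample count follows the brain-voxel formula unless
    ``config.samples_per_epoch`` overrides it (scaled-down runs).  Raises on
    non-finite losses.  Returns the trained generator and loss history; the
    discriminator is reachable as ``generator.discriminator_``.
    """
    if not train_volumes:
        raise ValueError("need at least one training subject")
    if any(v.target is None for v in train_volumes):
        raise ValueError("all training volumes need a target channel")
    rng = np.random.default_rng(seed)
    gen = build_generator(config, int(rng.integers(2**31 - 1)))
    disc = build_discriminator(config, int(rng.integers(2**31 - 1)))
    g_opt = Adam(gen.parameters(), config.lr, config.beta1, config.beta2)
    d_opt = Adam(disc.parameters(), config.lr, config.beta1, config.beta2)

    n_samples = config.samples_per_epoch
    if n_samples is None:
        n_samples = sampler.epoch_size(
            [v.mask for v in train_volumes], config.patch_edge, config.epoch_multiplier
        )
    if n_samples < config.batch_size:
        raise ValueError(
            "epoch size below one batch; set samples_per_epoch for small cohorts"
        )
    n_batches = n_samples // config.batch_size

    if augment_params is None and config.augment:
        augment_params = sampler.AugmentParams()

    history = TrainingHistory()
    for epoch in range(config.epochs):
        e_mae = e_adv = e_d = 0.0
        for _ in range(n_batches):
            x, y = _draw_batch(train_volumes, config, rng, augment_params)

            # one generator forward serves both updates (the discriminator
            # treats the fake as a constant input)
            g_opt.zero_grad()
            fake = gen.forward(x, train=True)

            # --- discriminator step
            d_opt.zero_grad()
            v_real = disc.score(x, y, train=True)
            l_real = bce_loss(v_real, 1.0)
            disc.backward(0.5 * _bce_grad(v_real, 1.0))
            v_fake = disc.score(x, fake, train=True)
            l_fake = bce_loss(v_fake, 0.0)
            disc.backward(0.5 * _bce_grad(v_fake, 0.0))
            d_opt.step()
            d_l = 0.5 * (l_real + l_fake)

            # --- generator step against the updated discriminator
            v = disc.score(x, fake, train=True)
            adv = bce_loss(v, 1.0)
            mae = float(np.mean(np.abs(fake - y)))
            g_from_disc = disc.backward(_bce_grad(v, 1.0))[:, -1:]
            g_l1 = (config.mae_weight * np.sign(fake - y) / fake.size).astype(np.float32)
            gen.backward(g_from_disc + g_l1)
            g_opt.step()

            if not (np.isfinite(d_l) and np.isfinite(adv) and np.isfinite(mae)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: d={d_l} adv={adv} mae={mae}"
                )
            e_mae += mae
            e_adv += adv
            e_d += d_l
        history.g_mae.append(e_mae / n_batches)
        history.g_adv.append(e_adv / n_batches)
        history.d_loss.append(e_d / n_batches)
        if val_volumes:
            maes = []
            for v in val_volumes:
                pred = predict_volume(gen, v, config.patch_edge, config.patch_edge)
                m = v.mask.astype(bool)
                maes.append(float(np.mean(np.abs(pred[m] - v.target[m]))))
            history.val_mae.append(float(np.mean(maes)))
        if log_every and (epoch + 1) % log_every == 0:
            val = history.val_mae[-1] if history.val_mae else float("nan")
            print(
                f"epoch {epoch + 1}/{config.epochs} mae={history.g_mae[-1]:.4f} "
                f"adv={history.g_adv[-1]:.4f} d={history.d_loss[-1]:.4f} val={val:.4f}"
            )
    gen.discriminator_ = disc
    return gen, history


# ---------------------------------------------------------------------------
# whole-volume inference


def _as_patch_fn(generator):
    if hasattr(generator, "forward"):
        return lambda p: np.asarray(generator.forward(p[None].astype(np.float32), train=False))[0, 0]

    def fn(p):
        out = np.asarray(generator(p))
        return out[0] if out.ndim == 4 else out

    return fn


def predict_volume(
    generator,
    volumes: VolumeChannelStack,
    patch_edge: int,
    stride: int | None = None,
) -> np.ndarray:
    """Sliding-window prediction with uniform overlap averaging.

    The volume is zero-padded so windows tile it completely; overlapping
    window predictions are averaged with equal weight and the result trimmed
    back to the input grid.
    """
    stride = patch_edge if stride is None else int(stride)
    if stride <= 0 or stride > patch_edge:
        raise ValueError("stride must be in (0, patch_edge]")
    fn = _as_patch_fn(generator)
    x = np.asarray(volumes.predictors, dtype=np.float32)
    spatial = x.shape[1:]
    padded = [max(patch_edge, s) for s in spatial]
    x = np.pad(x, ((0, 0),) + tuple((0, p - s) for p, s in zip(padded, spatial)))

    def starts(dim: int) -> list[int]:
        pos = list(range(0, dim - patch_edge + 1, stride))
        if pos[-1] != dim - patch_edge:
            pos.append(dim - patch_edge)
        return pos

    acc = np.zeros(padded, dtype=np.float64)
    wgt = np.zeros(padded, dtype=np.float64)
    for i in starts(padded[0]):
        for j in starts(padded[1]):
            for k in starts(padded[2]):
                sl = (slice(i, i + patch_edge), slice(j, j + patch_edge), slice(k, k + patch_edge))
                acc[sl] += fn(x[(slice(None), *sl)])
                wgt[sl] += 1.0
    out = acc / wgt
    out = out[: spatial[0], : spatial[1], : spatial[2]]
    return np.clip(out, -1.0, 1.0)


# ---------------------------------------------------------------------------
# checkpointing


def save_generator(gen: Generator, path) -> None:
    """Save generator weights with the embedded architecture config."""
    arrays = {f"p{i}": p.data for i, p in enumerate(gen.parameters())}
    cfg = {k: v for k, v in dataclasses.asdict(gen.config).items()}
    np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_generator(path) -> Generator:
    with np.load(path) as z:
        cfg = json.loads(bytes(z["__config__"]).decode())
        gen = build_generator(NetworkConfig(**cfg), seed=0)
        for i, p in enumerate(gen.parameters()):
            p.data[...] = z[f"p{i}"]
    return gen


# ---------------------------------------------------------------------------
# estimator wrapper


class DirGan:
    """Estimator-style wrapper: ``fit`` on volume stacks, ``predict`` aDIR.

    Follows the scikit-learn parameter conventions (constructor stores
    hyperparameters untouched; ``get_params``/``set_params``; fitted
    attributes carry a trailing underscore) so the model slots into generic
    tooling, while the sample unit is a :class:`VolumeChannelStack`.
    """

    def __init__(
        self,
        depth: int = 5,
        base_filters: int = 32,
        kernel: int = 3,
        leaky_slope: float = 0.2,
        in_channels: int = 3,
        mae_weight: float = 100.0,
        lr: float = 2e-4,
        beta1: float = 0.5,
        beta2: float = 0.999,
        epochs: int = 350,
        batch_size: int = 2,
        patch_edge: int = 128,
        epoch_multiplier: int = 8,
        samples_per_epoch: int | None = None,
        disc_base_filters: int = 32,
        disc_stages: int = 3,
        disc_kernel: int = 4,
        augment: bool = True,
        stride: int | None = None,
        random_state: int | None = None,
    ):
        args = inspect.signature(DirGan.__init__).parameters
        for name in list(args)[1:]:
            setattr(self, name, locals()[name])

    # -- sklearn-style parameter plumbing ----------------------------------
    @classmethod
    def _param_names(cls) -> list[str]:
        return [p for p in inspect.signature(cls.__init__).parameters if p != "self"]

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params) -> "DirGan":
        valid = set(self._param_names())
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r} for DirGan")
            setattr(self, k, v)
        return self

    def _config(self) -> NetworkConfig:
        fields = {f.name for f in dataclasses.fields(NetworkConfig)}
        return NetworkConfig(**{k: v for k, v in self.get_params().items() if k in fields})

    # -- estimator API ------------------------------------------------------
    def fit(
        self,
        X: Sequence[VolumeChannelStack],
        y=None,
        val_volumes: Sequence[VolumeChannelStack] | None = None,
    ) -> "DirGan":
        self.config_ = self._config()
        self.generator_, self.history_ = train(
            list(X), self.config_, seed=self.random_state, val_volumes=val_volumes
        )
        self.discriminator_ = self.generator_.discriminator_
        return self

    def predict(self, X: Sequence[VolumeChannelStack]) -> list[np.ndarray]:
        if not hasattr(self, "generator_"):
            raise RuntimeError("DirGan instance is not fitted yet")
        return [
            predict_volume(self.generator_, v, self.patch_edge, self.stride or self.patch_edge)
            for v in X
        ]
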