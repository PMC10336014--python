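"""Three-channel conditional U-Net: architecture, training and reconstruction.

The network maps a (navigator, static-at-navigator, static-at-target) stack to
the data slice at the target position for the navigator's breathing state.

Reference architecture plan (the package's resolution of details the original
description leaves open; all sizes configurable through :class:`ArchConfig`):

* Encoder: four blocks of two padded 3x3 convolutions, each followed by a
  leaky ReLU (slope 0.1); the second convolution of the first three blocks
  doubles the feature count and a 2x2 max-pool follows each of them. Channel
  plan for 32 base filters: (3-32-64 | 64-64-128 | 128-128-256), then the
  bottleneck block expands to the 512-map latent space in its first
  convolution (256-512-512).
* Decoder: three blocks of two 3x3 transposed convolutions with dropout
  between them. The first (stride 2) up-samples and halves the filters
  (512-&gt;256-&gt;128-&gt;64), the second (stride 1) refines; the encoder skip at the
  new resolution is then concatenated onto the block output. A final 1x1
  convolution (linear, so predictions can take the full intensity range)
  produces the slice.

For 128x128x3 inputs and 32 base filters this plan has 6,804,993 trainable
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from liver4d._nn import Adam, Conv2d, ConvTranspose2d, Dropout, LeakyReLU, MaxPool2
from liver4d.core_io import NormParams, TrainingSample, Volume, denormalize


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ArchConfig:
    """U-Net shape hyper-parameters. Defaults reproduce the reference plan."""

    in_shape: tuple[int, int, int] = (128, 128, 3)  # (H, W, channels)
    base_filters: int = 32
    levels: int = 3               # number of max-pool steps
    leaky_slope: float = 0.1
    dropout_rate: float = 0.5
    encoder_kernel: int = 3
    decoder_kernel: int = 3

    def __post_init__(self) -> None:
        h, w, c = self.in_shape
        d = 2 ** self.levels
        if h % d or w % d:
            raise ValueError(
                f"spatial shape {h}x{w} must be divisible by 2^levels = {d}"
            )
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if not 0 < self.leaky_slope < 1:
            raise ValueError("leaky_slope must be in (0, 1)")

    @property
    def latent_features(self) -> int:
        return 2 ** (self.levels + 1) * self.base_filters


@dataclass
class TrainConfig:
    """Training recipe: Adam, MSE loss, best-validation-loss checkpointing."""

    learning_rate: float = 4e-4
    epochs: int = 200
    batch_size: int = 64
    seed: int = 0
    augment: "AugmentRanges | None" = None
    steps_per_epoch: int | None = None  # cap on batches per epoch (None = all)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")


@dataclass
class AugmentRanges:
    """Physiologically plausible jitter applied jointly to all four images.

    Defaults: in-plane translation up to +-5 voxels, rotation up to +-5
    degrees, global intensity scaling +-10%. All values are inclusive bounds;
    zeros disable the corresponding transform.
    """

    translate_vox: float = 5.0
    rotate_deg: float = 5.0
    intensity_scale: float = 0.10

    def __post_init__(self) -> None:
        if self.translate_vox < 0 or self.rotate_deg < 0 or self.intensity_scale < 0:
            raise ValueError("augmentation ranges must be non-negative")
        if self.translate_vox > 16 or self.rotate_deg > 20 or self.intensity_scale > 0.5:
            raise ValueError("augmentation ranges outside the physiological bounds")


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class UNet:
    """Encoder-decoder with skip concatenations per the reference plan."""

    def __init__(self, arch: ArchConfig, seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        f, L = arch.base_filters, arch.levels
        ke, kd = arch.encoder_kernel, arch.decoder_kernel
        act = lambda: LeakyReLU(arch.leaky_slope)  # noqa: E731

        self.enc_blocks: list[list] = []
        cin = arch.in_shape[2]
        for lvl in range(L):
            c1 = f * 2 ** lvl if lvl else f
            c2 = f * 2 ** (lvl + 1)
            self.enc_blocks.append(
                [Conv2d(cin, c1, ke, rng), act(), Conv2d(c1, c2, ke, rng), act()]
            )
            cin = c2
        self.pools = [MaxPool2() for _ in range(L)]
        latent = arch.latent_features
        self.bottleneck = [
            Conv2d(cin, latent, ke, rng), act(), Conv2d(latent, latent, ke, rng), act()
        ]

        self.dec_blocks: list[list] = []
        cin = latent
        for j in range(L):
            cup = f * 2 ** (L - j)
            self.dec_blocks.append(
                [
                    ConvTranspose2d(cin, cup, kd, 2, rng), act(),
                    Dropout(arch.dropout_rate, np.random.default_rng(rng.integers(2**31))),
                    ConvTranspose2d(cup, cup, kd, 1, rng), act(),
                ]
            )
            cin = cup + cup  # block output + encoder skip at that resolution
        self.final = Conv2d(cin, 1, 1, rng)

    # -- plumbing ----------------------------------------------------------

    def _layers(self):
        for block in self.enc_blocks:
            yield from block
        yield from self.bottleneck
        for block in self.dec_blocks:
            yield from block
        yield self.final

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads()]

    def zero_grads(self) -> None:
        for g in self.grads():
            g[:] = 0.0

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            p[:] = w

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                x = layer.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for layer in self.bottleneck:
            x = layer.forward(x, train)
        self._skip_channels = []
        for j, block in enumerate(self.dec_blocks):
            for layer in block:
                x = layer.forward(x, train)
            skip = skips[self.arch.levels - 1 - j]
            self._skip_channels.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
        return self.final.forward(x, train)

    def backward(self, dy: np.ndarray) -> None:
        dx = self.final.backward(dy)
        skip_grads: list[np.ndarray] = []
        for j in range(self.arch.levels - 1, -1, -1):
            c = self._skip_channels[j]
            dx, dskip = dx[:, :c], dx[:, c:]
            skip_grads.append(dskip)
            for layer in reversed(self.dec_blocks[j]):
                dx = layer.backward(dx)
        skip_grads.reverse()  # now indexed by decoder block j (deepest first)
        for layer in reversed(self.bottleneck):
            dx = layer.backward(dx)
        for lvl in range(self.arch.levels - 1, -1, -1):
            dx = self.pools[lvl].backward(dx)
            dx = dx + skip_grads[self.arch.levels - 1 - lvl]
            for layer in reversed(self.enc_blocks[lvl]):
                dx = layer.backward(dx)


@dataclass
class ModelHandle:
    """A predictor plus the bookkeeping needed to use and audit it."""

    net: UNet
    arch: ArchConfig
    norm: NormParams | None = None
    provenance: dict = field(default_factory=dict)
    history: "object | None" = None

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def predict(self, stacks: np.ndarray) -> np.ndarray:
        """Forward a (N, 3, H, W) batch; returns normalized (N, H, W)."""
        out = self.net.forward(np.asarray(stacks, dtype=np.float32))[:, 0]
        return out.astype(np.float64)

    def clone(self) -> "ModelHandle":
        new = ModelHandle(
            net=UNet(self.arch, seed=0),
            arch=self.arch,
            norm=self.norm,
            provenance=dict(self.provenance),
        )
        new.net.set_weights(self.net.get_weights())
        return new


def build_unet(arch: ArchConfig, seed: int = 0, provenance: dict | None = None) -> ModelHandle:
    """Construct an untrained U-Net with seeded Glorot initialization."""
    return ModelHandle(net=UNet(arch, seed=seed), arch=arch,
                       provenance=provenance or {"seed": seed})


# ---------------------------------------------------------------------------
# input assembly and augmentation
# ---------------------------------------------------------------------------

def assemble_input(sample: TrainingSample, norm: NormParams) -> np.ndarray:
    """Stack the three conditioning channels, z-scored with subject stats.

    Channel order is semantic: (navigator, static at navigator position,
    static at target position).
    """
    imgs = [sample.navigator, sample.static_at_nav, sample.static_at_target]
    shapes = {np.asarray(a).shape for a in imgs}
    if len(shapes) != 1:
        raise ValueError(f"channel images must share one shape, got {shapes}")
    return np.stack([(np.asarray(a, dtype=np.float64) - norm.mean) / norm.std for a in imgs])


def augment(
    sample: TrainingSample,
    rng: np.random.Generator,
    ranges: AugmentRanges | None = None,
) -> TrainingSample:
    """Apply one random rigid + intensity jitter jointly to all four images.

    The same translation/rotation moves navigator, label and both static
    channels so the navigator-label relation stays consistent; the intensity
    scale is shared too. Deterministic for a given generator state.
    """
    ranges = ranges or AugmentRanges()
    dy = rng.uniform(-ranges.translate_vox, ranges.translate_vox)
    dx = rng.uniform(-ranges.translate_vox, ranges.translate_vox)
    ang = rng.uniform(-ranges.rotate_deg, ranges.rotate_deg)
    scale = 1.0 + rng.uniform(-ranges.intensity_scale, ranges.intensity_scale)

    def tf(img: np.ndarray) -> np.ndarray:
        out = np.asarray(img, dtype=np.float64)
        if ang != 0.0:
            out = ndimage.rotate(out, ang, reshape=False, order=1, mode="nearest")
        if dy != 0.0 or dx != 0.0:
            out = ndimage.shift(out, (dy, dx), order=1, mode="nearest")
        return scale * out

    return TrainingSample(
        navigator=tf(sample.navigator),
        static_at_nav=tf(sample.static_at_nav),
        static_at_target=tf(sample.static_at_target),
        label=tf(sample.label),
        target_position=sample.target_position,
        subject_id=sample.subject_id,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _to_arrays(samples: Sequence[TrainingSample], norm: NormParams):
    from liver4d._nn import DTYPE

    X = np.stack([assemble_input(s, norm) for s in samples]).astype(DTYPE)
    Y = np.stack([(np.asarray(s.label, dtype=np.float64) - norm.mean) / norm.std
                  for s in samples])[:, None].astype(DTYPE)
    return X, Y


def _augment_batch(X, Y, rng, ranges: AugmentRanges):
    Xa = np.empty_like(X)
    Ya = np.empty_like(Y)
    for n in range(X.shape[0]):
        stack = np.concatenate([X[n], Y[n]])  # (4, H, W)
        ang = rng.uniform(-ranges.rotate_deg, ranges.rotate_deg)
        dy = rng.uniform(-ranges.translate_vox, ranges.translate_vox)
        dx = rng.uniform(-ranges.translate_vox, ranges.translate_vox)
        scale = 1.0 + rng.uniform(-ranges.intensity_scale, ranges.intensity_scale)
        if ang != 0.0:
            stack = ndimage.rotate(stack, ang, axes=(1, 2), reshape=False,
                                   order=1, mode="nearest")
        if dy != 0.0 or dx != 0.0:
            stack = ndimage.shift(stack, (0, dy, dx), order=1, mode="nearest")
        stack *= scale
        Xa[n], Ya[n] = stack[:3], stack[3:]
    return Xa, Ya


def train(
    model: ModelHandle,
    train_samples: Sequence[TrainingSample],
    val_samples: Sequence[TrainingSample],
    cfg: TrainConfig,
    norm: NormParams | None = None,
) -> tuple[ModelHandle, "pd.DataFrame"]:
    """Optimize the model with Adam/MSE and keep the best-validation weights.

    ``norm`` defaults to the model's stored normalization parameters; the
    samples are z-scored with it before batching. The returned history has one
    row per epoch (train and validation MSE); the checkpointed weights are
    those of the epoch with minimum validation loss.
    """
    import pandas as pd

    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be nonempty")
    norm = norm or model.norm
    if norm is None:
        raise ValueError("normalization parameters required for training")
    model.norm = norm

    rng = np.random.default_rng(cfg.seed)
    Xtr, Ytr = _to_arrays(train_samples, norm)
    Xva, Yva = _to_arrays(val_samples, norm)
    net = model.net
    opt = Adam(net.parameters(), lr=cfg.learning_rate)

    def val_loss() -> float:
        preds = []
        for s in range(0, Xva.shape[0], cfg.batch_size):
            preds.append(net.forward(Xva[s : s + cfg.batch_size], train=False))
        return float(np.mean((np.concatenate(preds) - Yva) ** 2))

    hist_tr, hist_va = [], []
    best_loss = np.inf
    best_weights = net.get_weights()
    n = Xtr.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        if cfg.steps_per_epoch is not None:
            order = order[: cfg.steps_per_epoch * cfg.batch_size]
        ep_losses = []
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]
            if cfg.augment is not None:
                xb, yb = _augment_batch(xb, yb, rng, cfg.augment)
            net.zero_grads()
            pred = net.forward(xb, train=True)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {_epoch}; diverging "
                    f"optimization (lr={cfg.learning_rate})"
                )
            net.backward(2.0 * err / err.size)
            opt.step(net.grads())
            ep_losses.append(loss)
        vl = val_loss()
        hist_tr.append(float(np.mean(ep_losses)))
        hist_va.append(vl)
        if vl < best_loss:
            best_loss = vl
            best_weights = net.get_weights()
    net.set_weights(best_weights)
    history = pd.DataFrame({"epoch": np.arange(len(hist_tr)), "train_loss": hist_tr,
                            "val_loss": hist_va})
    model.history = history
    return model, history


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def reconstruct_volume(
    model: ModelHandle,
    navigator: np.ndarray,
    static_volume: Volume,
    norm: NormParams | None = None,
    navigator_position: int | None = None,
    positions: Sequence[int] | None = None,
) -> Volume:
    """Predict every LR slice for one navigator in a single batch.

    Each LR position of the static volume supplies the third channel; the
    predicted slices are denormalized and stacked in position order into a
    volume for the navigator's time point. Mapping this over a navigator
    series yields a 2D+t or full 4D reconstruction.
    """
    norm = norm or model.norm
    if norm is None:
        raise ValueError("normalization parameters required for reconstruction")
    navigator = np.asarray(navigator, dtype=np.float64)
    h, w, _ = model.arch.in_shape
    if navigator.shape != (h, w):
        raise ValueError(
            f"navigator shape {navigator.shape} does not match the trained "
            f"input shape {(h, w)}"
        )
    if positions is None:
        positions = range(static_volume.shape[0])
    positions = list(positions)
    if navigator_position is None:
        navigator_position = static_volume.shape[0] // 2
    nav_static = static_volume.sagittal_slice(navigator_position)
    stacks = np.stack(
        [
            np.stack([
                (navigator - norm.mean) / norm.std,
                (nav_static - norm.mean) / norm.std,
                (static_volume.sagittal_slice(p) - norm.mean) / norm.std,
            ])
            for p in positions
        ]
    )
    pred = model.predict(stacks)  # (P, H, W) normalized, H=SI, W=AP
    out = np.zeros((len(positions),) + static_volume.shape[1:])
    for i, _p in enumerate(positions):
        out[i] = denormalize(pred[i], norm).T  # back to (AP, SI)
    return Volume(out, static_volume.spacing)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(model: ModelHandle, run_dir: "str | Path") -> "Path":
    """Write a run directory: weights.npz, manifest.json, history.csv."""
    import hashlib
    import json
    from dataclasses import asdict
    from pathlib import Path

    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    weights = model.net.get_weights()
    np.savez(run_dir / "weights.npz", **{f"w{i:03d}": w for i, w in enumerate(weights)})
    arch = asdict(model.arch)
    manifest = {
        "arch": arch,
        "provenance": model.provenance,
        "norm": None if model.norm is None else
            {"mean": model.norm.mean, "std": model.norm.std,
             "subject_id": model.norm.subject_id},
        "config_hash": hashlib.sha256(
            json.dumps(arch, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "n_params": model.n_params,
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if model.history is not None:
        model.history.to_csv(run_dir / "history.csv", index=False)
    return run_dir


def load_model(run_dir: "str | Path") -> ModelHandle:
    """Rebuild a ModelHandle from a run directory written by save_model."""
    import json
    from pathlib import Path

    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    arch_fields = dict(manifest["arch"])
    arch_fields["in_shape"] = tuple(arch_fields["in_shape"])
    arch = ArchConfig(**arch_fields)
    model = build_unet(arch, seed=0, provenance=manifest.get("provenance") or {})
    with np.load(run_dir / "weights.npz") as data:
        model.net.set_weights([data[k] for k in sorted(data.files)])
    if manifest.get("norm"):
        model.norm = NormParams(**manifest["norm"])
    return model
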