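"""Residual multi-scale CNN that predicts the streak-artifact image.

Sparse-view FBP reconstructions follow the additive corruption model
``f = x + n``: the clean (full-view) image plus a structured streak field.
Instead of learning the near-identity map ``f -> x``, the network learns the
residual map ``mu(f; theta) ~= n`` and the corrected image is recovered as
``x = f - mu(f)``.  The default architecture is a fully convolutional trunk
of inception blocks: an entry 3x3 conv + ReLU, a 3x3 conv to the trunk width
with BN + ReLU, a stack of inception blocks (parallel 1/3/5/7 conv branches,
each BN + ReLU, concatenated back to the trunk width), and a final 3x3 conv
to one channel.  Turning ``multiscale`` off replaces every inception block
with a plain 3x3 conv block of the same width and depth — the one-scale
baseline variant.

The network is resolution-agnostic (any square input >= 32 px).  Images are
normalized by their ``intensity_scale`` (4095 for 12-bit storage) on the way
in and the prediction is rescaled on the way out, so `correct_image`
operates in stored intensity units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import Adam, BatchNorm2D, Conv2D, InceptionBlock, ReLU, Sequential
from .phantoms import Image2D

__all__ = [
    "NetworkConfig",
    "TrainedModel",
    "build_network",
    "predict_artifact",
    "correct_image",
    "residual_loss",
    "MIN_INPUT_SIZE",
]

MIN_INPUT_SIZE = 32


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters of the artifact network."""

    trunk_channels: int = 64
    n_inception_blocks: int = 8
    inception_branch_kernels: tuple[int, ...] = (1, 3, 5, 7)
    entry_kernel: int = 3
    head_kernel: int = 3
    multiscale: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "inception_branch_kernels", tuple(self.inception_branch_kernels)
        )
        if self.n_inception_blocks < 1:
            raise ValueError("need at least one block")
        for k in (self.entry_kernel, self.head_kernel, *self.inception_branch_kernels):
            if k % 2 != 1 or k < 1:
                raise ValueError("all kernel sizes must be odd and positive")
        if self.multiscale and self.trunk_channels % len(self.inception_branch_kernels):
            raise ValueError(
                "trunk_channels must split evenly across the inception branches"
            )

    @classmethod
    def small(cls) -> "NetworkConfig":
        """Desk-scale variant: 2 inception blocks, 32-channel trunk."""
        return cls(trunk_channels=32, n_inception_blocks=2)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        d = json.loads(text)
        d["inception_branch_kernels"] = tuple(d["inception_branch_kernels"])
        return cls(**d)


@dataclass
class TrainedModel:
    """Network config + learned parameters + provenance of the training run."""

    config: NetworkConfig
    net: Sequential
    training_meta: dict = field(default_factory=dict)

    def n_parameters(self) -> int:
        return sum(
            layer.params[key].size
            for layer in self.net.iter_layers()
            for key in layer.params
        )

    def save(self, path) -> None:
        arrays = {
            name: layer.get_array(key) for name, layer, key in self.net.named_arrays()
        }
        np.savez(
            path,
            __config__=np.frombuffer(self.config.to_json().encode(), dtype=np.uint8),
            __meta__=np.frombuffer(
                json.dumps(self.training_meta).encode(), dtype=np.uint8
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as z:
            config = NetworkConfig.from_json(bytes(z["__config__"]).decode())
            meta = json.loads(bytes(z["__meta__"]).decode())
            model = build_network(config, seed=0)
            for name, layer, key in model.net.named_arrays():
                layer.set_array(key, z[name])
        model.training_meta = meta
        return model


def _make_block(config: NetworkConfig, rng, dtype) -> Sequential | InceptionBlock:
    c = config.trunk_channels
    if config.multiscale:
        return InceptionBlock(c, config.inception_branch_kernels, rng, dtype=dtype)
    return Sequential([
        Conv2D(c, c, 3, rng, dtype=dtype),
        BatchNorm2D(c, dtype=dtype),
        ReLU(),
    ])


def build_network(
    config: NetworkConfig, seed: int, dtype=np.float32
) -> TrainedModel:
    """Seeded, reproducible construction of an untrained artifact network."""
    rng = np.random.default_rng(seed)
    c = config.trunk_channels
    layers = [
        Conv2D(1, c, config.entry_kernel, rng, dtype=dtype),
        ReLU(),
        Conv2D(c, c, 3, rng, dtype=dtype),
        BatchNorm2D(c, dtype=dtype),
        ReLU(),
    ]
    for _ in range(config.n_inception_blocks):
        layers.append(_make_block(config, rng, dtype))
    # zero-initialized head: the untrained network predicts a zero artifact
    # image, so training starts from the identity correction and can only
    # improve on the raw sparse-view reconstruction
    layers.append(Conv2D(c, 1, config.head_kernel, rng, dtype=dtype, zero_init=True))
    return TrainedModel(config, Sequential(layers), {"seed": seed})


def predict_artifact(model: TrainedModel, f: Image2D) -> Image2D:
    """Predicted artifact image n_hat = mu(f; theta), in stored intensity units.

    Inference mode (BN running statistics), deterministic."""
    if f.size < MIN_INPUT_SIZE:
        raise ValueError(f"input must be at least {MIN_INPUT_SIZE} px per side")
    dtype = next(iter(model.net.iter_layers())).params["W"].dtype
    x = (f.pixels / f.intensity_scale).astype(dtype)[None, :, :, None]
    out = model.net.forward(x, training=False)[0, :, :, 0]
    return Image2D(
        np.asarray(out, dtype=np.float64) * f.intensity_scale,
        pixel_size=f.pixel_size,
        intensity_scale=f.intensity_scale,
    )


def correct_image(f: Image2D, n_hat: Image2D) -> Image2D:
    """Recover the clean image by residual subtraction: x = f - n."""
    if f.pixels.shape != n_hat.pixels.shape:
        raise ValueError("f and n_hat must have the same shape")
    return Image2D(
        f.pixels - n_hat.pixels,
        pixel_size=f.pixel_size,
        intensity_scale=f.intensity_scale,
    )


def _stack(batch) -> np.ndarray:
    arrs = [b.pixels if isinstance(b, Image2D) else np.asarray(b) for b in batch]
    return np.stack([np.asarray(a, dtype=np.float64) for a in arrs])


def residual_loss(predictions, inputs, targets) -> float:
    """Averaged squared residual error over a batch:

    ``l(theta) = (1 / 2N) * sum_i || n_hat_i - (f_i - x_i) ||^2``

    where the norm is the Frobenius norm over all pixels of image i.  This is
    the training objective; its minimizer makes mu(f) reproduce the artifact
    image f - x.
    """
    preds, fs, xs = _stack(predictions), _stack(inputs), _stack(targets)
    if preds.shape[0] == 0:
        raise ValueError("empty batch")
    if not (preds.shape == fs.shape == xs.shape):
        raise ValueError("batch shape mismatch")
    n = preds.shape[0]
    diff = preds - (fs - xs)
    return float(np.sum(diff * diff) / (2.0 * n))
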