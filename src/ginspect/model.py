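"""The dual-branch spectral-spatial classifier (FC-CNN).

A fully connected branch embeds the 396-point mean-reflectance curve through
dense layers of 512/1024/512/128 units (ReLU, dropout between), while a
convolutional branch embeds the stacked optimal-band images through five
blocks of [3x3 conv, stride 1, same padding -> batch norm -> ReLU -> 2x2 max
pool] with 64/128/128/64/32 filters, then flatten -> dropout -> dense(512).
The two embeddings are concatenated (128 + 512 = 640), passed through dropout
and a final dense + softmax over the classes.  Either branch can be dropped,
giving the pure-spectral (FCNN) and pure-image (CNN) ablations.

Kernel size, stride and padding follow from the parameter counts the
architecture is specified by (e.g. the first convolution of a 6-channel input
carries 3*3*6*64 + 64 = 3520 weights); batch normalization is counted at four
parameters per channel (scale, shift, moving mean, moving variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ModelSpecError

__all__ = [
    "FccnnSpec",
    "ModelSummary",
    "FCCNN",
    "build_spectral_branch",
    "build_image_branch",
    "build_fccnn",
    "count_parameters",
]


@dataclass
class FccnnSpec:
    """Architecture configuration.

    ``spectral_input_len=None`` drops the spectral branch (pure CNN);
    ``image_channels=0`` drops the image branch (pure FCNN).
    """

    spectral_input_len: int | None = 396
    image_shape: tuple[int, int] = (256, 1024)
    image_channels: int = 6
    spectral_units: tuple[int, ...] = (512, 1024, 512, 128)
    conv_filters: tuple[int, ...] = (64, 128, 128, 64, 32)
    post_flatten_dense: int = 512
    n_classes: int = 7
    dropout_spectral: float = 0.5
    dropout_image: float = 0.25
    dropout_head: float = 0.25

    def __post_init__(self) -> None:
        if self.spectral_input_len is None and self.image_channels == 0:
            raise ModelSpecError("at least one branch (spectral or image) is required")
        if self.spectral_input_len is not None and self.spectral_input_len < 1:
            raise ModelSpecError("spectral input length must be positive")
        if self.image_channels < 0:
            raise ModelSpecError("image_channels must be >= 0")
        if self.n_classes < 2:
            raise ModelSpecError("need at least two classes")


@dataclass
class ModelSummary:
    """Ordered per-layer (name, output shape, parameter count) records."""

    rows: list[tuple[str, str, int]] = field(default_factory=list)

    def add(self, name: str, shape: tuple | str, params: int) -> None:
        if isinstance(shape, tuple):
            shape = "(None, " + ", ".join(str(s) for s in shape) + ")"
        self.rows.append((name, shape, int(params)))

    @property
    def total(self) -> int:
        return sum(p for _, _, p in self.rows)

    def params_for(self, name: str) -> list[int]:
        """Parameter counts of every row whose layer name matches."""
        return [p for n, _, p in self.rows if n == name]

    def __str__(self) -> str:
        width = max(len(n) for n, _, _ in self.rows) if self.rows else 10
        lines = [f"{'Layer':<{width}}  {'Output shape':<24}  Weights"]
        for n, s, p in self.rows:
            lines.append(f"{n:<{width}}  {s:<24}  {p:,}")
        lines.append(f"Total weights: {self.total:,}")
        return "\n".join(lines)


class FCCNN:
    """The assembled network: optional branches plus the softmax head."""

    def __init__(
        self,
        spectral: nn.Sequential | None,
        image: nn.Sequential | None,
        head_dropout: nn.Dropout,
        head_dense: nn.Dense,
        summary: ModelSummary,
    ):
        self.spectral = spectral
        self.image = image
        self.head_dropout = head_dropout
        self.head_dense = head_dense
        self.summary = summary

    def forward(self, x_spec, x_img, training: bool = False) -> np.ndarray:
        feats = []
        if self.spectral is not None:
            feats.append(self.spectral.forward(x_spec, training=training))
        if self.image is not None:
            feats.append(self.image.forward(x_img, training=training))
        self._widths = [f.shape[1] for f in feats]
        z = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)
        z = self.head_dropout.forward(z, training=training)
        return self.head_dense.forward(z, training=training)

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.head_dense.backward(grad_logits)
        g = self.head_dropout.backward(g)
        offset = 0
        for branch, width in zip(
            [b for b in (self.spectral, self.image) if b is not None], self._widths
        ):
            branch.backward(g[:, offset : offset + width])
            offset += width

    def predict_proba(self, x_spec, x_img) -> np.ndarray:
        return nn.softmax(self.forward(x_spec, x_img, training=False))

    def predict(self, x_spec, x_img) -> np.ndarray:
        return self.predict_proba(x_spec, x_img).argmax(axis=1)

    def params_grads(self):
        for part in (self.spectral, self.image, self.head_dropout, self.head_dense):
            if part is not None:
                yield from part.params_grads()

    @property
    def param_count(self) -> int:
        total = self.head_dense.param_count
        for branch in (self.spectral, self.image):
            if branch is not None:
                total += branch.param_count
        return total


def build_spectral_branch(
    spec: FccnnSpec, rng: np.random.Generator | None = None
) -> tuple[nn.Sequential, ModelSummary]:
    """Dense 512 -> 1024 -> 512 -> 128 spectral feature extractor (ReLU after
    each layer, dropout between)."""
    if spec.spectral_input_len is None or spec.spectral_input_len < 1:
        raise ModelSpecError("spectral branch needs a positive input length")
    rng = rng or np.random.default_rng(0)
    summary = ModelSummary()
    summary.add("Input", (spec.spectral_input_len,), 0)
    layers: list[nn.Layer] = []
    n_in = spec.spectral_input_len
    for i, units in enumerate(spec.spectral_units):
        layers.append(nn.Dense(n_in, units, rng, relu=True))
        summary.add("Dense", (units,), n_in * units + units)
        if i < len(spec.spectral_units) - 1:
            layers.append(nn.Dropout(spec.dropout_spectral, rng))
            summary.add("Dropout", (units,), 0)
        n_in = units
    return nn.Sequential(layers), summary


def build_image_branch(
    spec: FccnnSpec, rng: np.random.Generator | None = None
) -> tuple[nn.Sequential, ModelSummary]:
    """Five conv/batch-norm/pool blocks followed by flatten -> dropout ->
    dense(512)."""
    c = spec.image_channels
    if c < 1:
        raise ModelSpecError("image branch needs at least one channel")
    h, w = spec.image_shape
    n_blocks = len(spec.conv_filters)
    if h % (2 ** n_blocks) or w % (2 ** n_blocks):
        raise ModelSpecError(
            f"image dims {h}x{w} must be divisible by 2^{n_blocks} for pooling"
        )
    rng = rng or np.random.default_rng(0)
    summary = ModelSummary()
    summary.add("Input", (h, w, c), 0)
    layers: list[nn.Layer] = []
    c_in = c
    for f in spec.conv_filters:
        layers += [nn.Conv3x3(c_in, f, rng), nn.BatchNorm(f), nn.ReLU(), nn.MaxPool2()]
        summary.add("Conv", (h, w, f), 9 * c_in * f + f)
        summary.add("BatchNorm", (h, w, f), 4 * f)
        h, w = h // 2, w // 2
        summary.add("MaxPooling", (h, w, f), 0)
        c_in = f
    flat = h * w * c_in
    layers.append(nn.Flatten())
    summary.add("Flatten", (flat,), 0)
    layers.append(nn.Dropout(spec.dropout_image, rng))
    summary.add("Dropout", (flat,), 0)
    layers.append(nn.Dense(flat, spec.post_flatten_dense, rng, relu=True))
    summary.add("Dense", (spec.post_flatten_dense,), flat * spec.post_flatten_dense + spec.post_flatten_dense)
    return nn.Sequential(layers), summary


def build_fccnn(
    spec: FccnnSpec, rng: np.random.Generator | None = None
) -> tuple[FCCNN, ModelSummary]:
    """Assemble the full network (or a single-branch ablation) and its
    analytic layer summary."""
    rng = rng or np.random.default_rng(0)
    summary = ModelSummary()
    spectral = image = None
    concat = 0
    if spec.spectral_input_len is not None:
        spectral, s_sum = build_spectral_branch(spec, rng)
        summary.rows += s_sum.rows
        concat += spec.spectral_units[-1]
    if spec.image_channels > 0:
        image, i_sum = build_image_branch(spec, rng)
        summary.rows += i_sum.rows
        concat += spec.post_flatten_dense
    summary.add("Concatenate", (concat,), 0)
    summary.add("Dropout", (concat,), 0)
    head_dropout = nn.Dropout(spec.dropout_head, rng)
    head_dense = nn.Dense(concat, spec.n_classes, rng, relu=False)
    head_dense.W[...] = 0.0  # start from uniform class probabilities
    summary.add("Dense", (spec.n_classes,), concat * spec.n_classes + spec.n_classes)
    return FCCNN(spectral, image, head_dropout, head_dense, summary), summary


def count_parameters(network) -> ModelSummary:
    """Recount parameters from the network's actual arrays, layer by layer
    (the independent check on the analytic summary)."""
    summary = ModelSummary()

    def walk(part, prefix=""):
        if part is None:
            return
        if isinstance(part, nn.Sequential):
            for layer in part.layers:
                walk(layer, prefix)
            return
        summary.add(prefix + type(part).__name__, "-", part.param_count)

    if isinstance(network, FCCNN):
        walk(network.spectral, "spectral/")
        walk(network.image, "image/")
        walk(network.head_dropout, "head/")
        walk(network.head_dense, "head/")
    else:
        walk(network)
    return summary
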