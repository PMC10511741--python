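"""RANet: a compact custom CNN for two-class hand-thermogram classification.

The architecture is six blocks of (conv -> batch norm -> 2x2 max pool) with
conv filter counts 8, 16, 32, 64, 128, 256 and kernels alternating 1x1 / 3x3
(stride 1 throughout), followed by global average pooling and four fully
connected layers of 128, 64, 32 and 2 units, the last with softmax.  1x1
convolutions use 'same' padding and 3x3 convolutions 'valid' padding — the
unique assignment under which a 256x256x3 input traverses the published size
sequence 256 -> 126 -> 63 -> 29 -> 14 -> 5 (max pooling uses floor semantics
on odd sizes).

The module keeps two independent views of the model: a declarative
:class:`ArchitectureSpec` whose parameter counts are computed by closed-form
accounting (conv: kh*kw*cin*cout + cout; dense: nin*nout + nout; batch norm:
4 per channel, half of them non-trainable moving statistics), and the live
:mod:`thermonet.nn` network built from it.  The two must always agree.

For the full 256x256 model the account totals 369,042 parameters (368,034
trainable + 1,008 non-trainable).  Reduced-depth variants (``n_blocks`` < 6)
support smaller inputs such as 64x64, where the 3x3 valid convolutions would
otherwise exhaust the spatial extent; the FC stack is unchanged, so the third
fully connected layer always yields 32-dimensional deep features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "ParameterAccount",
    "TrainConfig",
    "build_ranet_spec",
    "propagate_shapes",
    "count_parameters",
    "build_network",
    "RANetClassifier",
    "train_ranet",
    "predict",
    "extract_features",
]

_KINDS = ("input", "conv2d", "batchnorm", "maxpool", "global_average_pool", "dense")


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    name: str
    out: int | None = None          # channels (conv) or units (dense)
    kernel: tuple[int, int] | None = None
    stride: int | None = None
    activation: str = "none"        # ReLU | SoftMax | none
    padding: str | None = None      # same | valid (conv only)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv2d", "dense") and (self.out is None or self.out <= 0):
            raise ValueError(f"{self.name}: positive out count required")
        if self.kind in ("conv2d", "maxpool"):
            if not self.kernel or min(self.kernel) <= 0 or (self.stride or 0) <= 0:
                raise ValueError(f"{self.name}: positive kernel and stride required")


@dataclass(frozen=True)
class ArchitectureSpec:
    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = (256, 256, 3)

    def to_json(self) -> str:
        return json.dumps(
            {"input_shape": self.input_shape, "layers": [asdict(l) for l in self.layers]},
            indent=2,
        )

    def find(self, name: str) -> int:
        for i, l in enumerate(self.layers):
            if l.name == name:
                return i
        raise KeyError(f"no layer named {name!r}")


@dataclass(frozen=True)
class ParameterAccount:
    per_layer: tuple[tuple[str, int], ...]
    total: int
    trainable: int
    non_trainable: int


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "SGD"
    learning_rate: float = 0.01
    batch_size: int = 16
    epochs: int = 50
    momentum: float = 0.0
    loss: str = "categorical_cross_entropy"
    seed: int = 0

    def validate(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


_FC_UNITS = (128, 64, 32)


def build_ranet_spec(input_size: int = 256, n_blocks: int = 6) -> ArchitectureSpec:
    """Declarative RANet architecture.

    Defaults give the full six-block 256x256 model; ``n_blocks`` < 6 truncates
    the conv stack (filters 8 * 2**i, kernels alternating 1x1/3x3) for smaller
    inputs while keeping the 128/64/32/2 fully connected head.
    """
    layers = [LayerSpec("input", "Input")]
    for i in range(n_blocks):
        k = 1 if i % 2 == 0 else 3
        layers.append(
            LayerSpec(
                "conv2d",
                f"Conv2D_{i + 1}",
                out=8 * 2**i,
                kernel=(k, k),
                stride=1,
                activation="ReLU",
                padding="same" if k == 1 else "valid",
            )
        )
        layers.append(LayerSpec("batchnorm", f"BN_{i + 1}"))
        layers.append(
            LayerSpec("maxpool", f"Maxpooling_{i + 1}", kernel=(2, 2), stride=2)
        )
    layers.append(LayerSpec("global_average_pool", "Global Average Pooling"))
    for j, units in enumerate(_FC_UNITS, start=1):
        layers.append(LayerSpec("dense", f"FC_{j}", out=units, activation="ReLU"))
    layers.append(LayerSpec("dense", "FC_4", out=2, activation="SoftMax"))
    return ArchitectureSpec(tuple(layers), (input_size, input_size, 3))


def propagate_shapes(spec: ArchitectureSpec) -> list[tuple[str, tuple]]:
    """Replay the shape of each stage; conv 'valid' shrinks by k-1, 'same'
    preserves, max pooling floors.  Raises if the spatial extent collapses."""
    h, w, c = spec.input_shape
    shapes = [("Input", (h, w, c))]
    flat = None
    for l in spec.layers[1:]:
        if l.kind == "conv2d":
            if l.padding == "valid":
                h, w = h - l.kernel[0] + 1, w - l.kernel[1] + 1
            if h < 1 or w < 1:
                raise ValueError(f"{l.name}: spatial size collapsed to {h}x{w}")
            c = l.out
            shapes.append((l.name, (h, w, c)))
        elif l.kind == "batchnorm":
            shapes.append((l.name, (h, w, c)))
        elif l.kind == "maxpool":
            h, w = h // l.stride, w // l.stride
            if h < 1 or w < 1:
                raise ValueError(f"{l.name}: spatial size collapsed to {h}x{w}")
            shapes.append((l.name, (h, w, c)))
        elif l.kind == "global_average_pool":
            flat = c
            shapes.append((l.name, (flat,)))
        elif l.kind == "dense":
            flat = l.out
            shapes.append((l.name, (flat,)))
    return shapes


def count_parameters(spec: ArchitectureSpec) -> ParameterAccount:
    """Closed-form parameter accounting, independent of the live network."""
    h, w, c = spec.input_shape
    per_layer = []
    trainable = non_trainable = 0
    channels = c
    for l in spec.layers[1:]:
        if l.kind == "conv2d":
            n = l.kernel[0] * l.kernel[1] * channels * l.out + l.out
            channels = l.out
            trainable += n
            per_layer.append((l.name, n))
        elif l.kind == "batchnorm":
            n = 4 * channels
            trainable += 2 * channels
            non_trainable += 2 * channels
            per_layer.append((l.name, n))
        elif l.kind == "dense":
            n = channels * l.out + l.out
            channels = l.out
            trainable += n
            per_layer.append((l.name, n))
        else:
            per_layer.append((l.name, 0))
    return ParameterAccount(
        per_layer=tuple(per_layer),
        total=trainable + non_trainable,
        trainable=trainable,
        non_trainable=non_trainable,
    )


def build_network(
    spec: ArchitectureSpec,
    rng: np.random.Generator,
    dtype=np.float32,
    bn_momentum: float = 0.99,
) -> nn.Network:
    """Instantiate the live network for a spec (softmax folded into the loss)."""
    propagate_shapes(spec)  # validates spatial feasibility
    layers: list[nn.Layer] = []
    channels = spec.input_shape[2]
    for l in spec.layers[1:]:
        if l.kind == "conv2d":
            layers.append(
                nn.Conv2D(channels, l.out, l.kernel, padding=l.padding or "valid",
                          rng=rng, dtype=dtype)
            )
            channels = l.out
            if l.activation == "ReLU":
                layers.append(nn.ReLU())
        elif l.kind == "batchnorm":
            layers.append(nn.BatchNorm(channels, momentum=bn_momentum, dtype=dtype))
        elif l.kind == "maxpool":
            layers.append(nn.MaxPool2())
        elif l.kind == "global_average_pool":
            layers.append(nn.GlobalAvgPool())
        elif l.kind == "dense":
            layers.append(nn.Dense(channels, l.out, rng=rng, dtype=dtype))
            channels = l.out
            if l.activation == "ReLU":
                layers.append(nn.ReLU())
    return nn.Network(layers)


class RANetClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style estimator wrapping the RANet CNN.

    Parameters mirror the published training recipe: SGD with learning rate
    0.01, batch size 16, categorical cross-entropy, 50 epochs, checkpointing
    on validation accuracy.

    ``X`` is an (n, H, W, 3) array of images in [0, 1]; ``y`` holds binary
    labels (0 = normal, 1 = RA, or the corresponding strings).
    """

    def __init__(
        self,
        input_size: int = 256,
        n_blocks: int = 6,
        learning_rate: float = 0.01,
        batch_size: int = 16,
        epochs: int = 50,
        optimizer: str = "SGD",
        momentum: float = 0.0,
        checkpoint: bool = True,
        bn_momentum: float = 0.99,
        seed: int = 0,
    ):
        self.input_size = input_size
        self.n_blocks = n_blocks
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.optimizer = optimizer
        self.momentum = momentum
        self.checkpoint = checkpoint
        self.bn_momentum = bn_momentum
        self.seed = seed

    def _validate_X(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1:] != (self.input_size, self.input_size, 3):
            raise ValueError(
                f"X must have shape (n, {self.input_size}, {self.input_size}, 3), "
                f"got {X.shape}"
            )
        return X

    def _encode_y(self, y):
        self.classes_, y_int = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("RANetClassifier is strictly two-class")
        return y_int

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._validate_X(X)
        if len(X) == 0:
            raise ValueError("empty training set")
        y_int = self._encode_y(y)
        self.spec_ = build_ranet_spec(self.input_size, self.n_blocks)
        rng = np.random.default_rng(self.seed)
        self.net_ = build_network(self.spec_, rng, bn_momentum=self.bn_momentum)
        self.loss_ = nn.SoftmaxCrossEntropy()
        if self.optimizer.upper() == "SGD":
            opt = nn.SGD(self.net_.params, lr=self.learning_rate, momentum=self.momentum)
        elif self.optimizer.lower() == "adam":
            opt = nn.Adam(self.net_.params, lr=self.learning_rate)
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if X_val is not None:
            X_val = self._validate_X(X_val)
            y_val = np.searchsorted(self.classes_, np.asarray(y_val))
        self.history_, self.best_epoch_ = nn.train_network(
            self.net_,
            self.loss_,
            opt,
            X,
            y_int,
            X_val,
            y_val,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.seed + 1,
            checkpoint=self.checkpoint,
        )
        self.parameter_account_ = count_parameters(self.spec_)
        return self

    def decision_logits(self, X):
        check_is_fitted(self, "net_")
        X = self._validate_X(X)
        return nn._batched_forward(self.net_, X, 64)

    def predict_proba(self, X):
        return self.loss_.predict_proba(self.decision_logits(X))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def extract_features(self, X, layer_name: str = "FC_3"):
        """Post-ReLU activations of a named dense layer (FC_3 -> n x 32)."""
        check_is_fitted(self, "net_")
        X = self._validate_X(X)
        spec_idx = self.spec_.find(layer_name)
        layer = self.spec_.layers[spec_idx]
        if layer.kind != "dense":
            raise KeyError(f"{layer_name!r} is not a dense layer")
        # locate the corresponding live Dense layer (they appear in order)
        dense_rank = sum(
            1 for l in self.spec_.layers[1:spec_idx] if l.kind == "dense"
        )
        live_idx = [
            i for i, l in enumerate(self.net_.layers) if isinstance(l, nn.Dense)
        ][dense_rank]
        if layer.activation == "ReLU":
            live_idx += 1  # include the ReLU that follows
        sub = nn.Network(self.net_.layers[: live_idx + 1])
        return nn._batched_forward(sub, X, 64)

    def save(self, path: str):
        check_is_fitted(self, "net_")
        arrays = {f"arr_{i}": a for i, a in enumerate(self.net_.get_state())}
        np.savez(path, **arrays)
        account = self.parameter_account_
        sidecar = {
            "architecture": json.loads(self.spec_.to_json()),
            "parameter_account": {
                "per_layer": list(map(list, account.per_layer)),
                "total": account.total,
                "trainable": account.trainable,
                "non_trainable": account.non_trainable,
            },
            "classes": [str(c) for c in self.classes_],
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def train_ranet(X_train, y_train, X_val=None, y_val=None,
                config: TrainConfig | None = None, **kwargs) -> RANetClassifier:
    config = config or TrainConfig()
    config.validate()
    clf = RANetClassifier(
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        epochs=config.epochs,
        optimizer=config.optimizer,
        momentum=config.momentum,
        seed=config.seed,
        **kwargs,
    )
    return clf.fit(X_train, y_train, X_val, y_val)


def predict(model: RANetClassifier, X):
    return model.predict_proba(X)


def extract_features(model: RANetClassifier, X, layer_name: str = "FC_3"):
    return model.extract_features(X, layer_name)
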