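"""The two skipping classifiers and the hyperparameter grid search.

* Dense network ("NN"): six layers — input, hidden 256/256/128/128 with
  ReLU and dropout 0.1 each, one sigmoid output unit.
* Convolutional network ("CNN"): one 1-D convolution with 64 filters
  (kernel size is the swept hyperparameter), max pooling of 2, a 50-unit
  ReLU dense layer, one sigmoid output unit.

Both are trained with Adam (lr 0.01, beta1 0.9, beta2 0.999, eps 1e-8,
no decay) on mean squared error — the published configuration, kept even
for binary classification.  The grid search replaces the original
automated sweep with a plain exhaustive Cartesian evaluation ranked by
validation loss.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from ..errors import DataError, SchemaMismatchError
from . import engine
from .engine import Adam, Conv1D, Dense, Dropout, Flatten, MaxPool1D, Network, ReLU, Sigmoid

#: Kernel sizes swept for the convolutional model.
CNN_KERNEL_SIZES = (2, 5, 7, 10, 15, 50, 75, 100, 150, 200)

LABEL_NEGATIVE, LABEL_POSITIVE = "WT", "delta14"


@dataclass(frozen=True)
class OptimizerConfig:
    algorithm: str = "adam"
    lr: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    decay: float = 0.0
    loss: str = "mean_squared_error"


@dataclass(frozen=True)
class DenseNetSpec:
    input_dim: int
    hidden: tuple[int, ...] = (256, 256, 128, 128)
    dropout: float = 0.1

    kind: str = "dense"


@dataclass(frozen=True)
class ConvNetSpec:
    input_dim: int
    kernel_size: int = 100
    filters: int = 64
    pool: int = 2
    dense: int = 50

    kind: str = "conv"

    def __post_init__(self) -> None:
        if self.kernel_size > self.input_dim:
            raise DataError(
                f"kernel size {self.kernel_size} exceeds input dimension {self.input_dim}"
            )


@dataclass
class TrainedModel:
    """Architecture spec + weights + training metadata."""

    spec: object
    network: Network
    feature_schema_hash: str
    training_log: dict
    seed: int

    @property
    def weights(self) -> list[np.ndarray]:
        return self.network.get_weights()


def build_network(spec, rng: np.random.Generator) -> Network:
    if isinstance(spec, DenseNetSpec):
        layers: list = []
        n_in = spec.input_dim
        for h in spec.hidden:
            layers += [Dense(n_in, h, rng), ReLU(), Dropout(spec.dropout)]
            n_in = h
        layers += [Dense(n_in, 1, rng), Sigmoid()]
        return Network(layers)
    if isinstance(spec, ConvNetSpec):
        conv_out = spec.input_dim - spec.kernel_size + 1
        flat = (conv_out // spec.pool) * spec.filters
        return Network(
            [
                Conv1D(spec.kernel_size, spec.filters, rng),
                ReLU(),
                MaxPool1D(spec.pool),
                Flatten(),
                Dense(flat, spec.dense, rng),
                ReLU(),
                Dense(spec.dense, 1, rng),
                Sigmoid(),
            ]
        )
    raise DataError(f"unknown spec type {type(spec).__name__}")


def _as_binary(labels) -> np.ndarray:
    """Map labels to {0, 1}: WT -> 0, delta14 -> 1; numeric passes through."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "ifb":
        y = arr.astype(float)
    else:
        table = {LABEL_NEGATIVE: 0.0, LABEL_POSITIVE: 1.0}
        try:
            y = np.array([table[str(v)] for v in arr], dtype=float)
        except KeyError as e:
            raise DataError(f"unknown class label {e.args[0]!r}") from None
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise DataError("labels must be binary (WT=0, delta14=1)")
    return y


def train_classifier(
    spec,
    features: np.ndarray,
    labels,
    opt: OptimizerConfig | None = None,
    epochs: int = 50,
    batch_size: int = 32,
    val_fraction: float = 0.2,
    seed: int = 0,
    patience: int = 10,
    feature_schema_hash: str = "",
) -> TrainedModel:
    """Train a dense or convolutional classifier; deterministic per seed."""
    X = np.asarray(features, dtype=np.float64)
    y = _as_binary(labels)[:, None]
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise DataError(f"feature matrix shape {X.shape} does not match input_dim {spec.input_dim}")
    if len(np.unique(y)) < 2:
        raise DataError("training labels contain a single class")
    opt = opt or OptimizerConfig()
    rng = np.random.default_rng(seed)
    net = build_network(spec, rng)
    optimizer = Adam(net.params(), opt.lr, opt.beta1, opt.beta2, opt.epsilon, opt.decay)
    log = engine.fit(
        net,
        X,
        y,
        optimizer=optimizer,
        epochs=epochs,
        batch_size=batch_size,
        val_fraction=val_fraction,
        patience=patience,
        rng=rng,
    )
    return TrainedModel(spec, net, feature_schema_hash, log, seed)


def predict(model: TrainedModel, features: np.ndarray, schema_hash: str | None = None) -> np.ndarray:
    """Sigmoid scores in [0, 1], one per row."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if schema_hash is not None and model.feature_schema_hash and schema_hash != model.feature_schema_hash:
        raise SchemaMismatchError(
            f"feature schema {schema_hash} != training schema {model.feature_schema_hash}"
        )
    if X.shape[1] != model.spec.input_dim:
        raise DataError(f"feature dimension {X.shape[1]} != model input {model.spec.input_dim}")
    return model.network.forward(X)[:, 0]


def classify(
    model: TrainedModel,
    features: np.ndarray,
    threshold: float = 0.5,
    schema_hash: str | None = None,
) -> np.ndarray:
    """Binary calls: score strictly above the threshold -> delta14."""
    scores = predict(model, features, schema_hash)
    return np.where(scores > threshold, LABEL_POSITIVE, LABEL_NEGATIVE)


def grid_search(
    spec_family: str,
    grid: dict[str, list],
    features: np.ndarray,
    labels,
    seed: int = 0,
    **train_kwargs,
) -> pd.DataFrame:
    """Exhaustive Cartesian sweep; rows ranked by final validation loss.

    ``spec_family`` is ``"dense"`` or ``"conv"``; grid keys are spec fields
    (e.g. ``kernel_size`` for conv, ``hidden``/``dropout`` for dense).
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise DataError("hyperparameter grid must be non-empty")
    X = np.asarray(features, dtype=np.float64)
    families = {"dense": DenseNetSpec, "conv": ConvNetSpec}
    if spec_family not in families:
        raise DataError(f"unknown spec family {spec_family!r}")
    keys = sorted(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        spec = families[spec_family](input_dim=X.shape[1], **params)
        tm = train_classifier(spec, X, labels, seed=seed, **train_kwargs)
        val = tm.training_log["val_loss"]
        rows.append({**params, "val_loss": min(val) if val else np.nan,
                     "epochs_run": tm.training_log["epochs_run"]})
    df = pd.DataFrame(rows).sort_values("val_loss", kind="stable").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# persistence: one .npz archive holding spec JSON + weights + schema hash
# ---------------------------------------------------------------------------

_SPEC_TYPES = {"dense": DenseNetSpec, "conv": ConvNetSpec}
BUNDLE_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    meta = {
        "version": BUNDLE_VERSION,
        "spec_kind": model.spec.kind,
        "spec": {k: v for k, v in asdict(model.spec).items() if k != "kind"},
        "feature_schema_hash": model.feature_schema_hash,
        "training_log": model.training_log,
        "seed": model.seed,
    }
    arrays = {f"w{i}": w for i, w in enumerate(model.network.get_weights())}
    if model.spec.kind == "sca":  # mask travels with the bundle
        arrays["mask"] = np.asarray(meta["spec"].pop("mask"))
    np.savez(path, meta=json.dumps(meta, default=_json_default), **arrays)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(type(o).__name__)


def load_model(path) -> TrainedModel:
    from .sca import SCASpec, build_sca_network  # local import avoids a cycle

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        weights = [z[f"w{i}"] for i in range(sum(1 for k in z.files if k.startswith("w")))]
        mask = z["mask"] if "mask" in z.files else None
    if meta["version"] != BUNDLE_VERSION:
        raise DataError(f"unsupported model bundle version {meta['version']}")
    kind = meta["spec_kind"]
    rng = np.random.default_rng(meta["seed"])
    if kind == "sca":
        spec = SCASpec(mask=mask, **meta["spec"])
        net = build_sca_network(spec, rng)
    else:
        spec_cls = _SPEC_TYPES[kind]
        spec_args = dict(meta["spec"])
        if "hidden" in spec_args:
            spec_args["hidden"] = tuple(spec_args["hidden"])
        spec = spec_cls(**spec_args)
        net = build_network(spec, rng)
    net.set_weights(weights)
    return TrainedModel(spec, net, meta["feature_schema_hash"], meta["training_log"], meta["seed"])
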