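"""Sparsely connected autoencoder with an exon-structured latent space.

Each latent node represents one exon of the scope; an input feature is
wired only to the latent node(s) of the exon(s) it belongs to (coverage
positions to their exon, k-mers to the exon(s) overlapped by their first
occurrence, junction-spanning k-mers to both flanking exons).  The decoder
mirrors the encoder through the transposed mask.  Masked weights are
exactly zero before, during, and after training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DataError
from . import engine
from .engine import Adam, Dense, Network, ReLU
from .models import OptimizerConfig, TrainedModel


@dataclass
class SCASpec:
    input_dim: int
    latent_dim: int
    mask: np.ndarray  # (input_dim, latent_dim) binary
    latent_ordinals: tuple[int, ...] = ()

    kind: str = "sca"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=float)
        if self.mask.shape != (self.input_dim, self.latent_dim):
            raise DataError(
                f"mask shape {self.mask.shape} != ({self.input_dim}, {self.latent_dim})"
            )
        if not np.isin(self.mask, (0.0, 1.0)).all():
            raise DataError("mask must be binary")
        uncovered = np.nonzero(self.mask.sum(axis=1) == 0)[0]
        if uncovered.size:
            raise DataError(
                f"every input feature must connect to >=1 latent node; offenders: "
                f"{uncovered[:20].tolist()}"
            )


def build_connectivity_mask(
    attribution: list[tuple[int, ...]],
    latent_ordinals: tuple[int, ...],
) -> np.ndarray:
    """Binary (n_features x n_latent) mask from per-feature exon attribution.

    ``latent_ordinals`` fixes the latent node order (one node per exon of
    the scope).  Features attributed to no known exon are reported as
    offenders.
    """
    col = {o: j for j, o in enumerate(latent_ordinals)}
    mask = np.zeros((len(attribution), len(latent_ordinals)))
    offenders = []
    for i, exons in enumerate(attribution):
        hit = False
        for o in exons:
            if o in col:
                mask[i, col[o]] = 1.0
                hit = True
        if not hit:
            offenders.append(i)
    if offenders:
        raise DataError(
            f"{len(offenders)} features attributable to no latent exon; offenders: "
            f"{offenders[:20]}"
        )
    return mask


def build_sca_network(spec: SCASpec, rng: np.random.Generator) -> Network:
    encoder = Dense(spec.input_dim, spec.latent_dim, rng, mask=spec.mask)
    decoder = Dense(spec.latent_dim, spec.input_dim, rng, mask=spec.mask.T)
    return Network([encoder, ReLU(), decoder])


def train_sca(
    spec: SCASpec,
    features: np.ndarray,
    opt: OptimizerConfig | None = None,
    epochs: int = 50,
    batch_size: int = 32,
    val_fraction: float = 0.1,
    seed: int = 0,
    patience: int = 10,
    feature_schema_hash: str = "",
) -> TrainedModel:
    """Train the autoencoder on reconstruction MSE (input = target)."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise DataError(f"feature matrix shape {X.shape} does not match input_dim {spec.input_dim}")
    opt = opt or OptimizerConfig()
    rng = np.random.default_rng(seed)
    net = build_sca_network(spec, rng)
    optimizer = Adam(net.params(), opt.lr, opt.beta1, opt.beta2, opt.epsilon, opt.decay)
    log = engine.fit(
        net,
        X,
        X,
        optimizer=optimizer,
        epochs=epochs,
        batch_size=batch_size,
        val_fraction=val_fraction,
        patience=patience,
        rng=rng,
    )
    return TrainedModel(spec, net, feature_schema_hash, log, seed)


def encode(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Project samples onto the exon latent space: (n_samples x n_exons)."""
    if not isinstance(model.spec, SCASpec):
        raise DataError("encode() requires a sparsely connected autoencoder model")
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[1] != model.spec.input_dim:
        raise DataError(f"feature dimension {X.shape[1]} != model input {model.spec.input_dim}")
    encoder, relu = model.network.layers[0], model.network.layers[1]
    return relu.forward(encoder.forward(X, train=False, rng=None), train=False, rng=None)


def masked_weights_are_zero(model: TrainedModel) -> bool:
    """Invariant check: every masked-out encoder/decoder weight is exactly 0."""
    enc, dec = model.network.layers[0], model.network.layers[2]
    return bool(
        np.all(enc.W.value[enc.mask == 0] == 0.0) and np.all(dec.W.value[dec.mask == 0] == 0.0)
    )


def n_trainable_encoder_weights(model: TrainedModel) -> int:
    enc = model.network.layers[0]
    return int(enc.mask.sum())
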