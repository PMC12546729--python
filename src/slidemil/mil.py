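"""Attention-based multiple-instance learning core.

A slide is a *bag* of instances (tiles, or their feature vectors) sharing
one label Y. The MIL assumption is Y = 0 iff every instance label is 0,
else Y = 1. The model encodes each instance to a D-vector, pools the bag
into a single D-vector with a permutation-invariant operator (softmax
attention by default, mean or max as ablation arms), and classifies the
pooled vector with a small dense head.

Attention scores are produced per instance by a D -> hidden(tanh) -> 1
network; softmax over the bag turns scores into weights that sum to one,
and the pooled vector is the weighted sum of instance features. The raw
(pre-softmax) score of an instance does not depend on the rest of the bag,
which is what makes dense heatmap scanning cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import Dense, Tanh, ReLU, Sequential, softmax, log_softmax

__all__ = [
    "Bag", "AttentionResult", "Prediction", "MILModelConfig",
    "bag_label_from_instances", "mean_pool", "max_pool",
    "IdentityEncoder", "TilePixelEncoder", "reduce_tile",
    "AttentionMILModel", "predict_slide",
]

POOLING_MODES = ("attention", "mean", "max")


@dataclass
class Bag:
    """N instances sharing one slide-level label.

    ``instances`` is an (N, ...) array: feature vectors (N, D) or image
    tiles (N, H, W, 3). ``instance_labels`` is synthetic ground truth only.
    """

    instances: np.ndarray
    bag_label: int
    slide_id: str = ""
    instance_labels: np.ndarray | None = None

    def __post_init__(self):
        if len(self.instances) < 1:
            raise ValueError("a bag needs at least one instance")
        if self.instance_labels is not None:
            expected = bag_label_from_instances(self.instance_labels)
            if expected != self.bag_label:
                raise ValueError(
                    "bag label must equal the OR of its instance labels"
                )


@dataclass
class AttentionResult:
    raw_scores: np.ndarray     # (N,) pre-softmax attention scores
    weights: np.ndarray        # (N,) softmax weights, sum to 1
    pooled: np.ndarray         # (D,)


@dataclass
class Prediction:
    probabilities: np.ndarray  # (2,) class probabilities, sum to 1
    predicted_label: int       # argmax; 1 = tumour
    attention: AttentionResult | None = None


@dataclass
class MILModelConfig:
    encoder_name: str = "identity"
    feature_dim: int = 1024
    attention_hidden: int = 32
    attention_layers: int = 1
    classifier_hidden: int = 128
    classifier_layers: int = 1
    pooling: str = "attention"
    n_classes: int = 2
    encoder_hidden: int = 64
    encoder_pool: int = 16  # tile block-mean reduction (pixel encoder only)

    def __post_init__(self):
        if self.pooling not in POOLING_MODES:
            raise ValueError(f"pooling must be one of {POOLING_MODES}")
        if min(self.feature_dim, self.attention_hidden, self.classifier_hidden) <= 0:
            raise ValueError("dimensions must be positive")
        if self.attention_layers not in (1, 2) or self.classifier_layers not in (1, 2):
            raise ValueError("layer counts must be 1 or 2")


def bag_label_from_instances(instance_labels) -> int:
    """Bag label under the MIL assumption: 0 iff all instance labels are 0."""
    labels = np.asarray(instance_labels)
    if labels.size == 0:
        raise ValueError("empty bag")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("instance labels must be binary")
    return int(labels.max())


def mean_pool(features: np.ndarray) -> np.ndarray:
    """Column-wise mean over instances."""
    return np.asarray(features, dtype=float).mean(axis=0)


def max_pool(features: np.ndarray) -> np.ndarray:
    """Column-wise max over instances (argmax, i.e. first index, wins ties)."""
    return np.asarray(features, dtype=float).max(axis=0)


def reduce_tile(tile: np.ndarray, pool: int = 16) -> np.ndarray:
    """Block-mean a (H, W, 3) tile to (pool, pool, 3) and flatten.

    This fixed reduction is the deterministic front end of the pixel
    encoder; it commutes with 90-degree rotations, flips and per-channel
    affine colour jitter, so augmentation may be applied on either side.
    """
    h, w, c = tile.shape
    bh, bw = h // pool, w // pool
    x = tile[: bh * pool, : bw * pool].astype(float)
    x = x.reshape(pool, bh, pool, bw, c).mean(axis=(1, 3))
    return x.ravel()


class IdentityEncoder:
    """Pass-through encoder for pre-extracted feature bags."""

    name = "identity"

    def __init__(self, feature_dim: int):
        self.feature_dim = feature_dim

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.feature_dim:
            raise ValueError(f"expected (N, {self.feature_dim}) features")
        return x

    def backward(self, d_features):  # no parameters
        return d_features

    params_and_grads = ()
    n_params = 0


class TilePixelEncoder:
    """Small trainable backbone: block-mean tile reduction + 2-layer MLP.

    Fulfils the encoder contract (tile -> D-vector, trained jointly with
    the pooling and classifier). Accepts either raw (N, H, W, 3) tile
    stacks or pre-reduced (N, pool*pool*3) vectors, since the reduction
    step is fixed and can be cached per slide.
    """

    name = "pixel_mlp"

    def __init__(self, feature_dim: int, rng: np.random.Generator,
                 hidden: int = 64, pool: int = 16):
        self.feature_dim = feature_dim
        self.pool = pool
        self.in_dim = pool * pool * 3
        self.net = Sequential(
            Dense(self.in_dim, hidden, rng), ReLU(),
            Dense(hidden, feature_dim, rng), ReLU(),
        )

    def reduce(self, tiles: np.ndarray) -> np.ndarray:
        return np.stack([reduce_tile(t, self.pool) for t in tiles])

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 4:
            x = self.reduce(x)
        if x.ndim != 2 or x.shape[1] != self.in_dim:
            raise ValueError(f"expected (N, {self.in_dim}) reduced tiles or (N, H, W, 3)")
        return self.net.forward(x)

    def backward(self, d_features):
        return self.net.backward(d_features)

    @property
    def params_and_grads(self):
        return self.net.params_and_grads

    @property
    def n_params(self):
        return self.net.n_params


def _make_encoder(config: MILModelConfig, rng: np.random.Generator):
    if config.encoder_name == "identity":
        return IdentityEncoder(config.feature_dim)
    if config.encoder_name == "pixel_mlp":
        return TilePixelEncoder(config.feature_dim, rng,
                                hidden=config.encoder_hidden,
                                pool=config.encoder_pool)
    raise ValueError(f"unknown encoder {config.encoder_name!r}")


class AttentionMILModel:
    """Encoder -> pooling -> classifier, with explicit backward pass."""

    def __init__(self, config: MILModelConfig, seed: int = 0,
                 encoder=None):
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoder = encoder if encoder is not None else _make_encoder(config, rng)
        D, H = config.feature_dim, config.attention_hidden
        att_layers = [Dense(D, H, rng), Tanh()]
        if config.attention_layers == 2:
            att_layers += [Dense(H, H, rng), Tanh()]
        att_layers += [Dense(H, 1, rng)]
        self.attention_net = Sequential(*att_layers)
        C = config.classifier_hidden
        clf_layers = [Dense(D, C, rng), ReLU()]
        if config.classifier_layers == 2:
            clf_layers += [Dense(C, C, rng), ReLU()]
        clf_layers += [Dense(C, config.n_classes, rng)]
        self.classifier = Sequential(*clf_layers)

    # ----- parameter plumbing -------------------------------------------
    @property
    def params_and_grads(self):
        out = list(self.encoder.params_and_grads)
        out += self.attention_net.params_and_grads
        out += self.classifier.params_and_grads
        return out

    @property
    def n_params(self):
        return (self.encoder.n_params + self.attention_net.n_params
                + self.classifier.n_params)

    # ----- forward pieces ------------------------------------------------
    def attention_pool(self, features: np.ndarray) -> AttentionResult:
        """Score, softmax-normalise and weighted-sum a bag of features."""
        F = np.asarray(features, dtype=float)
        if F.ndim != 2 or len(F) < 1:
            raise ValueError("features must be a non-empty (N, D) matrix")
        if not np.isfinite(F).all():
            raise ValueError("non-finite features")
        raw = self.attention_net.forward(F).ravel()
        w = softmax(raw)
        return AttentionResult(raw_scores=raw, weights=w, pooled=w @ F)

    def pool(self, features: np.ndarray):
        mode = self.config.pooling
        if mode == "attention":
            att = self.attention_pool(features)
            return att.pooled, att
        if mode == "mean":
            return mean_pool(features), None
        return max_pool(features), None

    def classify(self, pooled: np.ndarray) -> Prediction:
        if not np.isfinite(pooled).all():
            raise ValueError("non-finite pooled vector")
        logits = self.classifier.forward(pooled[None, :])[0]
        probs = softmax(logits)
        return Prediction(probabilities=probs, predicted_label=int(np.argmax(probs)))

    def predict(self, instances: np.ndarray) -> Prediction:
        """Full inference on one bag; attention attached when applicable."""
        F = self.encoder.forward(instances)
        pooled, att = self.pool(F)
        pred = self.classify(pooled)
        pred.attention = att
        return pred

    def attention_raw_scores(self, instances: np.ndarray) -> np.ndarray:
        """Per-instance pre-softmax attention scores (bag-independent)."""
        F = self.encoder.forward(instances)
        return self.attention_net.forward(F).ravel()

    # ----- training step -------------------------------------------------
    def loss_and_backward(self, instances: np.ndarray, label: int,
                          grad_scale: float = 1.0) -> float:
        """Cross-entropy on one bag; accumulates parameter gradients.

        grad_scale divides the contribution (1/batch for averaged batches).
        """
        F = self.encoder.forward(instances)
        N = len(F)
        mode = self.config.pooling
        if mode == "attention":
            raw = self.attention_net.forward(F).ravel()
            w = softmax(raw)
            pooled = w @ F
        elif mode == "mean":
            pooled = F.mean(axis=0)
        else:
            argmax = F.argmax(axis=0)
            pooled = F[argmax, np.arange(F.shape[1])]
        logits = self.classifier.forward(pooled[None, :])
        logp = log_softmax(logits[0])
        loss = -logp[label]

        dlogits = (np.exp(logp) - np.eye(self.config.n_classes)[label]) * grad_scale
        dpooled = self.classifier.backward(dlogits[None, :])[0]
        if mode == "attention":
            dw = F @ dpooled                       # (N,)
            draw = w * (dw - w @ dw)               # softmax Jacobian
            dF = np.outer(w, dpooled)
            dF += self.attention_net.backward(draw[:, None])
        elif mode == "mean":
            dF = np.broadcast_to(dpooled / N, F.shape).copy()
        else:
            dF = np.zeros_like(F)
            dF[argmax, np.arange(F.shape[1])] = dpooled
        self.encoder.backward(dF)
        return float(loss)

    def bag_loss(self, instances: np.ndarray, label: int) -> float:
        """Cross-entropy of one bag without touching gradients."""
        pred = self.predict(instances)
        logp = np.log(np.clip(pred.probabilities[label], 1e-12, None))
        return float(-logp)

    # ----- checkpointing --------------------------------------------------
    def save(self, path: str | Path):
        """Binary weight archive plus a JSON sidecar with the config."""
        path = Path(path)
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.params_and_grads)}
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "AttentionMILModel":
        path = Path(path)
        config = MILModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(config, seed=seed)
        with np.load(path.with_suffix(".npz")) as data:
            for i, (p, _) in enumerate(model.params_and_grads):
                p[...] = data[f"p{i}"]
        return model


def predict_slide(tiles: np.ndarray, model: AttentionMILModel,
                  bag_size: int, seed: int) -> Prediction:
    """Sample one bag of tiles from a slide and classify it.

    Sampling is uniform without replacement; when bag_size exceeds the
    number of available tiles, every tile is used before any is reused.
    """
    from .train import sample_bag_indices  # local import avoids a cycle

    n = len(tiles)
    if n == 0:
        raise ValueError("slide has no valid tiles")
    idx = sample_bag_indices(n, bag_size, np.random.default_rng(seed))
    return model.predict(np.asarray(tiles)[idx])
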