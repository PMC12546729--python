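"""Training protocol and experimental design for the MIL classifier.

One epoch samples one bag of N tiles from every training slide (uniform
without replacement; a bag larger than the slide cycles through all tiles
before reusing any), groups bags into batches, and takes one Adam step per
batch on the unweighted cross-entropy of the bag labels. Class imbalance
is addressed through metric choice only. Defaults follow the published
protocol: learning rate 1e-4, 60 epochs, and per-resolution (bag, batch)
sizes of (256, 4), (64, 12), (64, 12), (32, 24) for R = 0..3.

The experimental-design layer provides the stratified 90/10 slide split,
stratified k-fold cross-validation, repeated training with normal-theory
95% confidence intervals, randomized hyperparameter search (winner =
lowest mean validation loss, ties broken by fewer parameters), the
resolution sweep and the pooling/normalization ablations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .metrics import evaluate_scores
from .mil import AttentionMILModel, Bag, MILModelConfig
from .nn import Adam

__all__ = [
    "TABLE_BAG_BATCH", "TrainConfig", "SlideBagDataset", "SearchSpace",
    "split_train_test", "sample_bag_indices", "sample_bag", "train",
    "evaluate", "cross_validate", "repeated_training",
    "hyperparameter_search", "resolution_sweep", "ablation",
    "sampling_coverage",
]

# Optimal (bag size, batch size) per resolution level R.
TABLE_BAG_BATCH = {0: (256, 4), 1: (64, 12), 2: (64, 12), 3: (32, 24)}


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 60
    level: int = 1
    bag_size: int | None = None     # default: per-level optimum
    batch_size: int | None = None
    pooling: str = "attention"
    seed: int = 0
    normalization_enabled: bool = True

    def __post_init__(self):
        bag, batch = TABLE_BAG_BATCH[self.level]
        if self.bag_size is None:
            self.bag_size = bag
        if self.batch_size is None:
            self.batch_size = batch


@dataclass
class SlideBagDataset:
    """Per-slide instance pools: each entry is (instances (M, ...), label, id).

    ``instances`` may be feature vectors or (reduced) tile arrays; bags are
    sampled from the pool each epoch.
    """

    pools: list          # list of np.ndarray
    labels: np.ndarray   # (n_slides,)
    slide_ids: list

    def __len__(self):
        return len(self.pools)

    def subset(self, idx):
        idx = np.asarray(idx)
        return SlideBagDataset(
            pools=[self.pools[i] for i in idx],
            labels=self.labels[idx],
            slide_ids=[self.slide_ids[i] for i in idx],
        )

    @classmethod
    def from_feature_bags(cls, bags) -> "SlideBagDataset":
        """Adapt (features, instance_labels, bag_label) triples."""
        return cls(pools=[b[0] for b in bags],
                   labels=np.array([b[2] for b in bags]),
                   slide_ids=[f"bag_{i:04d}" for i in range(len(bags))])


def split_train_test(labels, test_fraction: float = 0.10, seed: int = 0):
    """Stratified slide-level split; returns (train_idx, test_idx)."""
    labels = np.asarray(labels)
    if len(labels) < 2 or len(np.unique(labels)) < 2:
        raise ValueError("need at least two slides and both classes present")
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed)
    for part in (train_idx, test_idx):
        if len(np.unique(labels[part])) < 2:
            raise ValueError("split produced an empty class")
    return np.sort(train_idx), np.sort(test_idx)


def sample_bag_indices(n_available: int, bag_size: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Uniform sampling without replacement, cycling once exhausted.

    When bag_size > n_available every tile appears floor or ceil of
    bag_size/n_available times (counts differ by at most one) and all tiles
    are used before any is reused.
    """
    if n_available < 1:
        raise ValueError("no tiles available to sample")
    reps, rem = divmod(bag_size, n_available)
    parts = [rng.permutation(n_available) for _ in range(reps)]
    if rem:
        parts.append(rng.permutation(n_available)[:rem])
    return np.concatenate(parts) if parts else np.empty(0, dtype=int)


def sample_bag(pool: np.ndarray, label: int, bag_size: int,
               rng: np.random.Generator, slide_id: str = "") -> Bag:
    idx = sample_bag_indices(len(pool), bag_size, rng)
    return Bag(instances=pool[idx], bag_label=int(label), slide_id=slide_id)


def _bag_rng(seed: int, epoch: int, slide_index: int) -> np.random.Generator:
    # per-(seed, epoch, slide) stream so bags differ across epochs but are
    # exactly reproducible
    return np.random.default_rng(np.random.SeedSequence([seed, epoch, slide_index]))


def evaluate(model: AttentionMILModel, dataset: SlideBagDataset,
             bag_size: int | None = None, seed: int = 0, transform=None):
    """P(tumour) per slide plus the metric report.

    By default the whole tile pool of each slide forms the evaluation bag;
    pass bag_size to mimic sampled inference. ``transform`` maps a pool to
    model input (e.g. channel standardization); augmentation never runs
    here.
    """
    scores = []
    for i, pool in enumerate(dataset.pools):
        inst = pool
        if bag_size is not None:
            inst = pool[sample_bag_indices(len(pool), bag_size, _bag_rng(seed, 0, i))]
        if transform is not None:
            inst = transform(inst)
        scores.append(model.predict(inst).probabilities[1])
    scores = np.asarray(scores)
    return scores, evaluate_scores(scores, dataset.labels)


def train(model: AttentionMILModel, train_set: SlideBagDataset,
          config: TrainConfig, val_set: SlideBagDataset | None = None,
          augment_fn=None, eval_transform=None):
    """Train in place; returns a per-epoch history dict.

    ``augment_fn(instances, rng) -> instances`` is applied to each sampled
    training bag (disabled for validation).
    """
    opt = Adam(model.params_and_grads, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = len(train_set)
    history = {"train_loss": [], "val_loss": [], "val_metrics": []}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            for i in batch:
                bag_rng = _bag_rng(config.seed, epoch, int(i))
                idx = sample_bag_indices(len(train_set.pools[i]),
                                         config.bag_size, bag_rng)
                inst = train_set.pools[i][idx]
                if augment_fn is not None:
                    inst = augment_fn(inst, bag_rng)
                elif eval_transform is not None:
                    inst = eval_transform(inst)
                batch_loss += model.loss_and_backward(
                    inst, int(train_set.labels[i]), grad_scale=1.0 / len(batch))
            opt.step()
            epoch_loss += batch_loss
        mean_loss = epoch_loss / n
        if not math.isfinite(mean_loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        history["train_loss"].append(mean_loss)
        if val_set is not None:
            scores, report = evaluate(model, val_set, transform=eval_transform)
            history["val_loss"].append(report.bce_loss)
            history["val_metrics"].append(report)
    return history


def _fit_one(train_set, val_set, config: TrainConfig,
             model_config: MILModelConfig, augment_fn=None, eval_transform=None):
    model = AttentionMILModel(
        replace(model_config, pooling=config.pooling), seed=config.seed)
    history = train(model, train_set, config, val_set=val_set,
                    augment_fn=augment_fn, eval_transform=eval_transform)
    return model, history


def cross_validate(dataset: SlideBagDataset, config: TrainConfig,
                   model_config: MILModelConfig, k: int = 5,
                   augment_fn=None):
    """Stratified k-fold CV at slide level; per-fold metrics + mean/sd."""
    labels = dataset.labels
    if min(np.bincount(labels, minlength=2)) < k:
        raise ValueError(f"need at least k={k} slides per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    fold_reports = []
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_config = replace(config, seed=config.seed + fold)
        _, history = _fit_one(dataset.subset(tr), dataset.subset(va),
                              fold_config, model_config, augment_fn)
        fold_reports.append(history["val_metrics"][-1])
    summary = {}
    for name in ("precision_macro", "recall_macro", "f1_macro", "auroc",
                 "mcc", "bce_loss"):
        vals = np.array([getattr(r, name) for r in fold_reports])
        summary[name] = {"mean": float(np.nanmean(vals)),
                         "sd": float(np.nanstd(vals, ddof=1)) if k > 1 else 0.0}
    return fold_reports, summary


def repeated_training(dataset: SlideBagDataset, test_set: SlideBagDataset,
                      config: TrainConfig, model_config: MILModelConfig,
                      n_runs: int = 100, val_fraction: float = 0.10,
                      augment_fn=None):
    """Re-split, re-initialize and re-train n_runs times; test each run.

    Returns per-metric mean and normal-theory 95% CI half-width
    (1.96 * sd / sqrt(n_runs)) over the fixed test set, Table-4 style.
    """
    if n_runs < 2:
        raise ValueError("repeated training needs n_runs >= 2")
    runs = []
    for run in range(n_runs):
        run_config = replace(config, seed=config.seed + 1000 * run)
        tr, va = split_train_test(dataset.labels, test_fraction=val_fraction,
                                  seed=run_config.seed)
        model, _ = _fit_one(dataset.subset(tr), None, run_config,
                            model_config, augment_fn)
        _, report = evaluate(model, test_set)
        runs.append(report)
    out = {}
    for name in ("bce_loss", "precision_macro", "recall_macro", "f1_macro",
                 "auroc", "mcc"):
        vals = np.array([getattr(r, name) for r in runs])
        out[name] = {"mean": float(np.nanmean(vals)),
                     "ci95_halfwidth": float(1.96 * np.nanstd(vals, ddof=1)
                                             / np.sqrt(n_runs))}
    return runs, out


@dataclass
class SearchSpace:
    levels: tuple = (0, 1, 2, 3)
    lr_bounds: tuple = (1e-5, 1e-1)          # log-uniform
    backbones: tuple = ("identity", "pixel_mlp")
    bag_sizes: tuple = (32, 64, 128, 256)
    batch_sizes: tuple = tuple(range(2, 25, 2))
    classifier_neurons: tuple = (64, 128)
    classifier_layers: tuple = (1, 2)
    attention_neurons: tuple = (32, 64, 128)
    attention_layers: tuple = (1, 2)
    epochs: tuple = (20, 60, 100)

    def sample(self, rng: np.random.Generator, feature_dim: int):
        lo, hi = np.log10(self.lr_bounds[0]), np.log10(self.lr_bounds[1])
        train_config = TrainConfig(
            learning_rate=float(10 ** rng.uniform(lo, hi)),
            epochs=int(rng.choice(self.epochs)),
            level=int(rng.choice(self.levels)),
            bag_size=int(rng.choice(self.bag_sizes)),
            batch_size=int(rng.choice(self.batch_sizes)),
        )
        model_config = MILModelConfig(
            encoder_name=str(rng.choice(self.backbones)),
            feature_dim=feature_dim,
            attention_hidden=int(rng.choice(self.attention_neurons)),
            attention_layers=int(rng.choice(self.attention_layers)),
            classifier_hidden=int(rng.choice(self.classifier_neurons)),
            classifier_layers=int(rng.choice(self.classifier_layers)),
        )
        return train_config, model_config


def hyperparameter_search(space: SearchSpace, budget: int,
                          dataset: SlideBagDataset, feature_dim: int,
                          k: int = 5, seed: int = 0, epochs_cap: int | None = None):
    """Randomized search scored by k-fold mean validation loss.

    Returns configs ranked best-first; equal losses favour the model with
    fewer parameters. ``epochs_cap`` optionally truncates sampled epoch
    counts (desk-scale runs).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    results = []
    for trial in range(budget):
        tc, mc = space.sample(rng, feature_dim)
        if epochs_cap is not None:
            tc = replace(tc, epochs=min(tc.epochs, epochs_cap))
        tc = replace(tc, seed=seed + trial)
        try:
            _, summary = cross_validate(dataset, tc, mc, k=k)
            loss = summary["bce_loss"]["mean"]
        except (FloatingPointError, ValueError):
            loss = float("inf")
        n_params = AttentionMILModel(mc, seed=0).n_params
        results.append({"train_config": tc, "model_config": mc,
                        "val_loss": loss, "n_params": n_params})
    results.sort(key=lambda r: (round(r["val_loss"], 6), r["n_params"]))
    return results


def resolution_sweep(datasets_by_level: dict, config: TrainConfig,
                     model_config: MILModelConfig, k: int = 5):
    """Cross-validate once per resolution level with its (bag, batch) optimum.

    ``datasets_by_level`` maps R -> SlideBagDataset preprocessed at that
    level. Returns a {R: summary} table shaped like the per-resolution
    comparison.
    """
    table = {}
    for level, dataset in sorted(datasets_by_level.items()):
        bag, batch = TABLE_BAG_BATCH[level]
        level_config = replace(config, level=level, bag_size=bag, batch_size=batch)
        _, summary = cross_validate(dataset, level_config, model_config, k=k)
        table[level] = summary
    return table


def ablation(train_set: SlideBagDataset, test_set: SlideBagDataset,
             config: TrainConfig, model_config: MILModelConfig,
             poolings=("attention", "mean", "max"), augment_fn=None):
    """Identical protocol per pooling arm; only the pooling differs.

    All arms share data, seed and schedule. Returns {pooling: MetricsReport}.
    """
    reports = {}
    for pooling in poolings:
        arm_config = replace(config, pooling=pooling)
        model, _ = _fit_one(train_set, None, arm_config, model_config, augment_fn)
        _, reports[pooling] = evaluate(model, test_set)
    return reports


def sampling_coverage(bag_size: int, n_tiles: float) -> float:
    """Fraction of a slide's tiles covered by one bag (e.g. 100/1e5 = 0.001)."""
    if n_tiles <= 0:
        raise ValueError("n_tiles must be positive")
    return min(bag_size / n_tiles, 1.0)
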