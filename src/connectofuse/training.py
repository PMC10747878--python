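"""Dataset splitting, the training loop, and model evaluation.

Training follows a fixed recipe: Adam (learning rate 1e-3, weight decay
0.05), batches of 64, 100 epochs, with the learning rate halved every 20
epochs; the data are split 8:2 into train and test once, at random.  There is
no validation split or early stopping — the epoch budget is fixed and the
per-epoch history is logged for inspection instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .graphs import build_graph, partial_correlation_matrix, pearson_matrix, vectorize_upper
from .metrics import MetricsReport, evaluate_predictions
from .network import Adam, MultimodalGraphClassifier, cross_entropy_loss, _softmax
from .phenotypes import PhenotypeSchema, encode_phenotypes
from .selection import FeatureMask

__all__ = [
    "TrainConfig",
    "GraphDataset",
    "split_dataset",
    "connectome_vectors",
    "build_dataset",
    "train",
    "evaluate",
]


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 0.05
    lr_step_size: int = 20
    lr_gamma: float = 0.5
    optimizer: str = "adam"
    split_ratio: tuple[float, float] = (0.8, 0.2)
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.lr_step_size) <= 0:
            raise ValueError("epochs, batch_size and lr_step_size must be positive")
        if self.learning_rate <= 0 or not 0 < self.lr_gamma <= 1:
            raise ValueError("invalid learning-rate settings")
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split_ratio must sum to 1")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the adam optimizer is supported")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_ratio"] = list(self.split_ratio)
        return d


@dataclass
class GraphDataset:
    """Batched model inputs for a set of subjects."""

    node_feats: np.ndarray  # B x R x R
    adjacency: np.ndarray  # B x R x R
    pheno: np.ndarray | None  # B x p
    labels: np.ndarray  # B
    subject_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "GraphDataset":
        idx = np.asarray(idx)
        return GraphDataset(
            node_feats=self.node_feats[idx],
            adjacency=self.adjacency[idx],
            pheno=None if self.pheno is None else self.pheno[idx],
            labels=self.labels[idx],
            subject_ids=[self.subject_ids[i] for i in idx] if self.subject_ids else [],
        )


def split_dataset(
    n_or_ids, ratio: tuple[float, float] = (0.8, 0.2), seed: int = 0,
    stratified: bool = False, labels=None,
):
    """Random train/test split; train size = round(ratio[0] * n).

    ``n_or_ids`` is either a subject count or a sequence of ids; returns
    (train_idx, test_idx) as index arrays (positions).  With ``stratified``
    the ratio is applied within each label class (``labels`` required).
    """
    if np.isscalar(n_or_ids):
        n = int(n_or_ids)
    else:
        n = len(n_or_ids)
    if n == 0:
        raise ValueError("empty input")
    rng = np.random.default_rng(seed)
    if stratified:
        if labels is None:
            raise ValueError("stratified split requires labels")
        labels = np.asarray(labels)
        train_parts, test_parts = [], []
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            if len(idx) < 2:
                raise ValueError(f"need >= 2 subjects per class, class {c} has {len(idx)}")
            perm = rng.permutation(idx)
            k = int(round(ratio[0] * len(idx)))
            train_parts.append(perm[:k])
            test_parts.append(perm[k:])
        return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))
    perm = rng.permutation(n)
    k = int(round(ratio[0] * n))
    return np.sort(perm[:k]), np.sort(perm[k:])


def connectome_vectors(timeseries: dict[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
    """Vectorized upper-triangle Pearson connectomes, one row per subject."""
    ids = sorted(timeseries)
    rows = [vectorize_upper(pearson_matrix(timeseries[s])) for s in ids]
    return ids, np.asarray(rows)


def build_dataset(
    timeseries: dict[str, np.ndarray],
    phenotypes: pd.DataFrame | None,
    labels: dict[str, int],
    mask: FeatureMask | None = None,
    schema: PhenotypeSchema | None = None,
    shrinkage: float | str = "auto",
    edge_rule: str = "complete",
    top_k: int = 10,
) -> GraphDataset:
    """Build per-subject graphs (+ encoded phenotypes) into a batched dataset.

    ``phenotypes`` must be indexed by subject id when given; the mask and
    schema are expected to have been fitted on training subjects only.
    """
    ids = sorted(timeseries)
    feats, adjs = [], []
    for s in ids:
        ts = timeseries[s]
        g = build_graph(
            pearson_matrix(ts),
            partial_correlation_matrix(ts, shrinkage=shrinkage),
            mask=mask,
            edge_rule=edge_rule,
            top_k=top_k,
        )
        feats.append(g.node_features)
        adjs.append(g.adjacency())
    pheno = None
    if phenotypes is not None and schema is not None:
        pheno = encode_phenotypes(phenotypes.loc[ids], schema)
    y = np.array([labels[s] for s in ids], dtype=int)
    return GraphDataset(
        node_feats=np.asarray(feats),
        adjacency=np.asarray(adjs),
        pheno=pheno,
        labels=y,
        subject_ids=ids,
    )


def train(
    model: MultimodalGraphClassifier, dataset: GraphDataset, config: TrainConfig
) -> pd.DataFrame:
    """Train in place; returns the per-epoch history (loss, accuracy, lr).

    Minibatches are reshuffled every epoch from the config seed, so the whole
    run is a pure function of (initial parameters, data, config).
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("empty training set")
    if len(np.unique(dataset.labels)) < 2:
        raise ValueError("training set must contain both classes")

    opt = Adam(
        model.params,
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
        no_decay=model.decay_exempt_params(),
    )
    rng = np.random.default_rng(config.seed)
    history = []
    for epoch in range(config.epochs):
        # step-wise learning-rate decay
        opt.lr = config.learning_rate * config.lr_gamma ** (epoch // config.lr_step_size)
        perm = rng.permutation(n)
        epoch_loss, n_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            batch = dataset.subset(idx)
            loss, grads = model.loss_and_grads(
                batch.node_feats, batch.adjacency, batch.pheno, batch.labels, training=True
            )
            opt.step(grads)
            epoch_loss += loss * len(idx)
            logits, _ = model.forward(batch.node_feats, batch.adjacency, batch.pheno, training=False)
            n_correct += int((logits.argmax(axis=1) == batch.labels).sum())
        history.append(
            {
                "epoch": epoch + 1,
                "loss": epoch_loss / n,
                "train_acc": n_correct / n,
                "lr": opt.lr,
            }
        )
    return pd.DataFrame(history)


def evaluate(model: MultimodalGraphClassifier, dataset: GraphDataset) -> MetricsReport:
    """Metric panel on a held-out set, in evaluation mode."""
    if len(dataset) == 0:
        raise ValueError("empty test set")
    probs = model.predict_proba(dataset.node_feats, dataset.adjacency, dataset.pheno)
    return evaluate_predictions(probs[:, 1], dataset.labels)
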