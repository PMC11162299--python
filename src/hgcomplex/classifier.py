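"""Complex embedding, negative sampling, and the feed-forward classifier.

A candidate complex (a set of proteins) is embedded as the column-wise
average of its members' latent node embeddings, giving a size-independent
vector of the latent dimension (100 by default). Gold-standard negatives
are random node sets whose sizes are resampled from the positive size
distribution, at a 5:1 negative:positive ratio. A four-layer feed-forward
network with batch normalization and dropout between layers, ending in a
sigmoid, is trained with binary cross-entropy to score candidate sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._optim import Adam
from .io import Complex, ComplexSet, InteractionNetwork

__all__ = [
    "EmbeddingTable",
    "ClassifierConfig",
    "ComplexDNN",
    "complex_embedding",
    "sample_negative_complexes",
    "train_classifier",
    "score_complex",
    "evaluate_classifier",
    "cross_validate_classifier",
    "save_classifier",
    "load_classifier",
]


class EmbeddingTable:
    """Protein id -> latent embedding lookup backed by a dense matrix."""

    def __init__(self, ids: list[str], matrix: np.ndarray):
        if len(ids) != matrix.shape[0]:
            raise ValueError("ids and matrix rows differ")
        self.ids = list(ids)
        self.matrix = np.asarray(matrix, dtype=float)
        self._index = {pid: i for i, pid in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, pid: str) -> bool:
        return pid in self._index

    def rows(self, members) -> np.ndarray:
        missing = [m for m in members if m not in self._index]
        if missing:
            raise KeyError(f"unknown protein id(s): {sorted(missing)}")
        return self.matrix[[self._index[m] for m in members]]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for pid, row in zip(self.ids, self.matrix):
                fh.write(pid + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EmbeddingTable":
        ids, rows = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(ids, np.asarray(rows))


def complex_embedding(z_table: EmbeddingTable, members) -> np.ndarray:
    """Column-wise average of the member embeddings (size-independent)."""
    rows = z_table.rows(sorted(members))
    return rows.mean(axis=0)


def sample_negative_complexes(
    positives: ComplexSet,
    network: InteractionNetwork,
    ratio: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> ComplexSet:
    """Random node sets emulating non-complexes.

    Emits round(ratio * |positives|) sets. Each set's size is drawn with
    replacement from the empirical size distribution of the positives (so
    the negative sizes follow the same power-law-like shape); members are
    drawn uniformly without replacement from the network nodes. A sampled
    set identical to any positive is rejected and redrawn.
    """
    if len(positives) == 0:
        raise ValueError("no positive complexes")
    sizes = np.asarray(positives.sizes)
    if sizes.max() > network.n_nodes:
        raise ValueError(
            f"largest positive ({sizes.max()}) exceeds network size "
            f"({network.n_nodes})"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    forbidden = set(positives.member_sets)
    nodes = np.asarray(network.nodes, dtype=object)
    n_out = int(round(ratio * len(positives)))
    out: list[Complex] = []
    while len(out) < n_out:
        size = int(rng.choice(sizes))
        members = frozenset(rng.choice(nodes, size=size, replace=False))
        if members in forbidden:
            continue
        out.append(Complex(members=members, score=None))
    return ComplexSet(out)


@dataclass
class ClassifierConfig:
    layer_sizes: tuple[int, ...] = (100, 64, 32, 16, 1)  # 4 weight layers
    dropout_rate: float = 0.1
    batch_norm: bool = True
    standardize: bool = True     # z-score inputs on training statistics
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 32
    negative_ratio: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least one weight layer")
        if self.layer_sizes[-1] != 1:
            raise ValueError("final layer must emit one logit")
        if self.negative_ratio <= 0:
            raise ValueError("negative_ratio must be positive")


class ComplexDNN:
    """Feed-forward scorer with batch norm + dropout between layers.

    Architecture for layer_sizes (d0, d1, ..., dk, 1): each hidden layer is
    linear -> batch norm -> ReLU -> dropout; the final layer is linear with
    a sigmoid read-out. Training uses minibatch Adam on binary cross-entropy;
    inference runs deterministically (dropout off, batch norm on running
    statistics).
    """

    _BN_EPS = 1e-5
    _BN_MOMENTUM = 0.9

    def __init__(self, config: ClassifierConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        sizes = config.layer_sizes
        self.params: dict[str, np.ndarray] = {}
        for layer, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            limit = np.sqrt(6.0 / (n_in + n_out))
            self.params[f"W{layer}"] = rng.uniform(-limit, limit, (n_in, n_out))
            self.params[f"b{layer}"] = np.zeros(n_out)
            if config.batch_norm and layer < len(sizes) - 2:
                self.params[f"gamma{layer}"] = np.ones(n_out)
                self.params[f"beta{layer}"] = np.zeros(n_out)
        self.running_mean = {
            layer: np.zeros(sizes[layer + 1])
            for layer in range(len(sizes) - 2)
        }
        self.running_var = {
            layer: np.ones(sizes[layer + 1]) for layer in range(len(sizes) - 2)
        }
        self._rng = rng
        self.loss_trace: list[float] = []
        # input standardization statistics, fit on the training set;
        # latent embeddings can have arbitrarily small scale, which makes
        # raw batch norm numerically pathological
        self.input_mean = np.zeros(sizes[0])
        self.input_std = np.ones(sizes[0])

    @property
    def n_hidden(self) -> int:
        return len(self.config.layer_sizes) - 2

    # ------------------------------------------------------------- inference

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass on running batch-norm statistics."""
        c = self.config
        h = np.asarray(X, dtype=float)
        if h.ndim == 1:
            h = h[None, :]
        if c.standardize:
            h = (h - self.input_mean) / self.input_std
        for layer in range(self.n_hidden):
            h = h @ self.params[f"W{layer}"] + self.params[f"b{layer}"]
            if c.batch_norm:
                xhat = (h - self.running_mean[layer]) / np.sqrt(
                    self.running_var[layer] + self._BN_EPS
                )
                h = self.params[f"gamma{layer}"] * xhat + self.params[f"beta{layer}"]
            h = np.maximum(h, 0.0)
        last = self.n_hidden
        logit = (h @ self.params[f"W{last}"] + self.params[f"b{last}"]).ravel()
        return 1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500)))

    # -------------------------------------------------------------- training

    def _batch_step(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> tuple[float, dict[str, np.ndarray]]:
        c = self.config
        n = X.shape[0]
        cache: list[dict] = []
        h = X
        for layer in range(self.n_hidden):
            lin = h @ self.params[f"W{layer}"] + self.params[f"b{layer}"]
            entry: dict = {"x_in": h, "lin": lin}
            if c.batch_norm:
                mean = lin.mean(axis=0)
                var = lin.var(axis=0)
                std = np.sqrt(var + self._BN_EPS)
                xhat = (lin - mean) / std
                bn = self.params[f"gamma{layer}"] * xhat + self.params[f"beta{layer}"]
                entry.update({"xhat": xhat, "std": std})
                m = self._BN_MOMENTUM
                self.running_mean[layer] = m * self.running_mean[layer] + (1 - m) * mean
                self.running_var[layer] = m * self.running_var[layer] + (1 - m) * var
            else:
                bn = lin
            act = np.maximum(bn, 0.0)
            entry["bn"] = bn
            if c.dropout_rate > 0:
                keep = 1.0 - c.dropout_rate
                mask = (rng.random(act.shape) < keep) / keep
                act = act * mask
                entry["mask"] = mask
            cache.append(entry)
            h = act
        last = self.n_hidden
        logit = (h @ self.params[f"W{last}"] + self.params[f"b{last}"]).ravel()
        p = 1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500)))
        pc = np.clip(p, 1e-12, 1 - 1e-12)
        loss = float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())

        grads: dict[str, np.ndarray] = {}
        glogit = (p - y)[:, None] / n
        grads[f"W{last}"] = h.T @ glogit
        grads[f"b{last}"] = glogit.sum(axis=0)
        gh = glogit @ self.params[f"W{last}"].T
        for layer in range(self.n_hidden - 1, -1, -1):
            entry = cache[layer]
            if "mask" in entry:
                gh = gh * entry["mask"]
            gbn = gh * (entry["bn"] > 0)
            if c.batch_norm:
                xhat, std = entry["xhat"], entry["std"]
                grads[f"gamma{layer}"] = (gbn * xhat).sum(axis=0)
                grads[f"beta{layer}"] = gbn.sum(axis=0)
                gxhat = gbn * self.params[f"gamma{layer}"]
                nb = gxhat.shape[0]
                glin = (
                    nb * gxhat
                    - gxhat.sum(axis=0)
                    - xhat * (gxhat * xhat).sum(axis=0)
                ) / (nb * std)
            else:
                glin = gbn
            grads[f"W{layer}"] = entry["x_in"].T @ glin
            grads[f"b{layer}"] = glin.sum(axis=0)
            gh = glin @ self.params[f"W{layer}"].T
        return loss, grads

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ComplexDNN":
        c = self.config
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if c.standardize:
            self.input_mean = X.mean(axis=0)
            self.input_std = X.std(axis=0) + 1e-8
            X = (X - self.input_mean) / self.input_std
        opt = Adam(self.params, lr=c.learning_rate)
        rng = self._rng
        n = X.shape[0]
        self.loss_trace = []
        for _ in range(c.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, c.batch_size):
                idx = order[start : start + c.batch_size]
                if len(idx) < 2:
                    continue  # batch norm needs >= 2 samples
                loss, grads = self._batch_step(X[idx], y[idx], rng)
                opt.step(grads)
                epoch_loss += loss * len(idx)
            self.loss_trace.append(epoch_loss / n)
        return self


def train_classifier(
    embeddings: EmbeddingTable,
    positives: ComplexSet,
    negatives: ComplexSet,
    config: ClassifierConfig | None = None,
) -> ComplexDNN:
    """Train the DNN on embedded positive and negative complexes."""
    if config is None:
        config = ClassifierConfig()
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("both classes need at least one example")
    X = np.vstack(
        [complex_embedding(embeddings, c.members) for c in positives]
        + [complex_embedding(embeddings, c.members) for c in negatives]
    )
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    if X.shape[1] != config.layer_sizes[0]:
        raise ValueError(
            f"embedding dim {X.shape[1]} != input layer {config.layer_sizes[0]}"
        )
    return ComplexDNN(config).fit(X, y)


def score_complex(
    classifier: ComplexDNN, embeddings: EmbeddingTable, members
) -> float:
    """Probability that the member set forms a complex (inference mode)."""
    vec = complex_embedding(embeddings, members)
    return float(classifier.predict_proba(vec)[0])


def _scores_for(classifier, embeddings, complexes: ComplexSet) -> np.ndarray:
    X = np.vstack(
        [complex_embedding(embeddings, c.members) for c in complexes]
    )
    return classifier.predict_proba(X)


def evaluate_classifier(
    classifier: ComplexDNN,
    embeddings: EmbeddingTable,
    positives: ComplexSet,
    network: InteractionNetwork,
    n_resamples: int = 30,
    seed: int = 0,
    negative_ratio: float = 5.0,
):
    """AUROC/AUPRC over repeated fresh negative draws (default 30).

    Returns a pandas DataFrame with one row per resample plus attrs
    ``auroc_mean/auroc_se/auprc_mean/auprc_se`` (SE = standard error).
    """
    import pandas as pd
    from sklearn.metrics import average_precision_score, roc_auc_score

    rng = np.random.default_rng(seed)
    pos_scores = _scores_for(classifier, embeddings, positives)
    rows = []
    for r in range(n_resamples):
        negatives = sample_negative_complexes(
            positives, network, ratio=negative_ratio, seed=rng
        )
        neg_scores = _scores_for(classifier, embeddings, negatives)
        y = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
        s = np.concatenate([pos_scores, neg_scores])
        rows.append(
            {
                "resample": r,
                "auroc": roc_auc_score(y, s),
                "auprc": average_precision_score(y, s),
            }
        )
    df = pd.DataFrame(rows)
    for metric in ("auroc", "auprc"):
        df.attrs[f"{metric}_mean"] = float(df[metric].mean())
        df.attrs[f"{metric}_se"] = float(
            df[metric].std(ddof=1) / np.sqrt(len(df))
        ) if len(df) > 1 else 0.0
    return df


def cross_validate_classifier(
    embeddings: EmbeddingTable,
    positives: ComplexSet,
    network: InteractionNetwork,
    config: ClassifierConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
):
    """K-fold cross-validation (default 5) with fresh negatives per fold."""
    import warnings

    import pandas as pd
    from sklearn.metrics import average_precision_score, roc_auc_score
    from sklearn.model_selection import KFold

    if config is None:
        config = ClassifierConfig()
    rng = np.random.default_rng(seed)
    negatives = sample_negative_complexes(
        positives, network, ratio=config.negative_ratio, seed=rng
    )
    X = np.vstack(
        [complex_embedding_table_rows(embeddings, c) for c in positives]
        + [complex_embedding_table_rows(embeddings, c) for c in negatives]
    )
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(kf.split(X)):
        if len(np.unique(y[test_idx])) < 2:
            warnings.warn(f"fold {fold} has a single class; skipped")
            continue
        model = ComplexDNN(config).fit(X[train_idx], y[train_idx])
        s = model.predict_proba(X[test_idx])
        rows.append(
            {
                "fold": fold,
                "auroc": roc_auc_score(y[test_idx], s),
                "auprc": average_precision_score(y[test_idx], s),
            }
        )
    return pd.DataFrame(rows)


def complex_embedding_table_rows(embeddings: EmbeddingTable, c: Complex) -> np.ndarray:
    return complex_embedding(embeddings, c.members)


def save_classifier(model: ComplexDNN, path: str | Path) -> None:
    path = Path(path)
    arrays = dict(model.params)
    for layer in range(model.n_hidden):
        arrays[f"rm{layer}"] = model.running_mean[layer]
        arrays[f"rv{layer}"] = model.running_var[layer]
    arrays["input_mean"] = model.input_mean
    arrays["input_std"] = model.input_std
    np.savez(path.with_suffix(".npz"), **arrays)
    cfg = asdict(model.config)
    cfg["layer_sizes"] = list(cfg["layer_sizes"])
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_classifier(path: str | Path) -> ComplexDNN:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg["layer_sizes"] = tuple(cfg["layer_sizes"])
    model = ComplexDNN(ClassifierConfig(**cfg))
    with np.load(path.with_suffix(".npz")) as data:
        model.params = {
            k: data[k]
            for k in data.files
            if not k.startswith(("rm", "rv", "input_"))
        }
        for layer in range(model.n_hidden):
            model.running_mean[layer] = data[f"rm{layer}"]
            model.running_var[layer] = data[f"rv{layer}"]
        model.input_mean = data["input_mean"]
        model.input_std = data["input_std"]
    return model
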