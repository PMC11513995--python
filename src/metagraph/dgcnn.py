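"""Deep graph convolutional regressor for per-sample SOC prediction.

The architecture follows a fixed 10-stage listing: four single-head graph
attention stages widening the 2-bit node features 2->32->32->32->128, a
weighted graph convolution stage 128->128, a max-pooling readout collapsing
the node dimension to one 128-vector per graph, a second 128->128 transform
applied to the pooled representation, then dense layers 128->32->1.
Rectified-linear nonlinearities sit between stages.

Attention stages consume connectivity only; the graph convolution stage
consumes edge weights through symmetric weighted-degree normalisation
(self-loops of weight one are added to both operators).  Training uses Adam
with L1 loss, learning rate 0.001, weight decay 0.1, 100 epochs, minibatches
of 32 shuffled graphs, an 85/15 train/test split at random state 40 and
5-fold cross-validation on the training portion.

Targets are z-scored on the training portion before optimisation and
predictions unscaled afterwards; with a zero-initialised output bias an
untrained model therefore predicts the training mean exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import sparse, stats
from sklearn.model_selection import KFold, train_test_split

from . import autodiff as ad
from .autodiff import Tensor
from .graphs import SampleGraph

__all__ = [
    "ModelConfig",
    "EvalReport",
    "Metrics",
    "TrainedRegressor",
    "split_data",
    "train",
    "evaluate",
    "null_model_mae",
]

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture and training protocol (the printed preset by default)."""

    attention_widths: tuple[int, ...] = (2, 32, 32, 32, 128)
    conv_width: int = 128
    dense_widths: tuple[int, ...] = (128, 32, 1)
    heads: int = 1
    epochs: int = 100
    learning_rate: float = 0.001
    weight_decay: float = 0.1
    folds: int = 5
    split_fraction: float = 0.85
    split_seed: int = 40
    batch_size: int = 32
    loss: str = "l1"  # l1 | l2
    activation: str = "relu"  # relu | leaky_relu
    negative_slope: float = 0.2  # attention score nonlinearity
    standardize_targets: bool = True
    init_seed: int = 0

    def validate(self) -> None:
        if self.heads != 1:
            raise ValueError("only single-head attention is supported")
        if self.loss not in ("l1", "l2"):
            raise ValueError("loss must be 'l1' or 'l2'")
        if self.activation not in ("relu", "leaky_relu"):
            raise ValueError("activation must be 'relu' or 'leaky_relu'")
        if self.attention_widths[-1] != self.conv_width != self.dense_widths[0]:
            raise ValueError("attention output, conv width and first dense width must agree")
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must be in (0, 1)")


@dataclass
class EvalReport:
    """All error fields in g kg^-1; Pearson r dimensionless."""

    train_mae: float
    test_mae: float
    cv_mean_mae: float
    cv_sd_mae: float
    rmse: float
    pearson_r: float


@dataclass
class Metrics:
    mae: float
    rmse: float
    pearson_r: float  # NaN when the truth has zero variance


# --------------------------------------------------------------------------
# graph preparation and batching


class _Prepared:
    """Message-passing arrays for one graph: doubled edges plus self-loops."""

    __slots__ = ("x", "src", "dst", "gcn_norm", "edge_logw", "n")

    def __init__(self, graph: SampleGraph):
        n = graph.n_nodes
        if n == 0:
            raise ValueError(f"graph {graph.sample_id!r} has no nodes")
        e = graph.edges
        w = graph.weights
        src = np.concatenate([e[:, 0], e[:, 1], np.arange(n)])
        dst = np.concatenate([e[:, 1], e[:, 0], np.arange(n)])
        msg_w = np.concatenate([w, w, np.ones(n)])
        # Degrees use |w| so that signed edge weights (environment features
        # such as sub-zero temperatures) cannot produce near-zero or negative
        # degrees; the self-loop keeps every degree >= 1, so |norm| <= 1 and
        # the sign of the weight survives in the message.
        deg = np.zeros(n)
        np.add.at(deg, dst, np.abs(msg_w))
        deg = np.maximum(deg, 1.0)
        self.x = graph.node_features.astype(np.float64)
        self.src = src
        self.dst = dst
        self.gcn_norm = msg_w / np.sqrt(deg[src] * deg[dst])
        # signed log-compressed weight fed to the attention score, so the
        # attention stages see edge weights on a bounded scale
        self.edge_logw = np.sign(msg_w) * np.log1p(np.abs(msg_w))
        self.n = n


class _Batch:
    __slots__ = (
        "x",
        "src",
        "dst",
        "gcn_norm",
        "edge_logw",
        "node_graph",
        "n_nodes",
        "n_graphs",
        "scat_src",
        "scat_dst",
    )

    def __init__(self, prepared: list[_Prepared]):
        offsets = np.cumsum([0] + [p.n for p in prepared])
        self.x = np.vstack([p.x for p in prepared])
        self.src = np.concatenate([p.src + o for p, o in zip(prepared, offsets)])
        self.dst = np.concatenate([p.dst + o for p, o in zip(prepared, offsets)])
        self.gcn_norm = np.concatenate([p.gcn_norm for p in prepared])
        self.edge_logw = np.concatenate([p.edge_logw for p in prepared])
        self.node_graph = np.concatenate([np.full(p.n, i) for i, p in enumerate(prepared)])
        self.n_nodes = int(offsets[-1])
        self.n_graphs = len(prepared)
        ne = len(self.src)
        ones = np.ones(ne)
        cols = np.arange(ne)
        # scatter matrices: one sparse matmul replaces np.add.at in gradients
        self.scat_src = sparse.csr_matrix((ones, (self.src, cols)), shape=(self.n_nodes, ne))
        self.scat_dst = sparse.csr_matrix((ones, (self.dst, cols)), shape=(self.n_nodes, ne))


# --------------------------------------------------------------------------
# parameters and forward pass


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    p: dict[str, Tensor] = {}
    widths = config.attention_widths
    for k in range(len(widths) - 1):
        fi, fo = widths[k], widths[k + 1]
        p[f"gat{k}_w"] = Tensor(_glorot(rng, fi, fo, (fi, fo)), requires_grad=True)
        p[f"gat{k}_a_src"] = Tensor(_glorot(rng, fo, 1, (fo, 1)), requires_grad=True)
        p[f"gat{k}_a_dst"] = Tensor(_glorot(rng, fo, 1, (fo, 1)), requires_grad=True)
        p[f"gat{k}_a_w"] = Tensor(_glorot(rng, 1, 1, (1,)), requires_grad=True)
        p[f"gat{k}_b"] = Tensor(np.zeros(fo), requires_grad=True)
    c = config.conv_width
    p["gcn_w"] = Tensor(_glorot(rng, c, c, (c, c)), requires_grad=True)
    p["gcn_b"] = Tensor(np.zeros(c), requires_grad=True)
    p["post_w"] = Tensor(_glorot(rng, c, c, (c, c)), requires_grad=True)
    p["post_b"] = Tensor(np.zeros(c), requires_grad=True)
    d = config.dense_widths
    p["dense1_w"] = Tensor(_glorot(rng, d[0], d[1], (d[0], d[1])), requires_grad=True)
    p["dense1_b"] = Tensor(np.zeros(d[1]), requires_grad=True)
    p["dense2_w"] = Tensor(_glorot(rng, d[1], d[2], (d[1], d[2])), requires_grad=True)
    p["dense2_b"] = Tensor(np.zeros(d[2]), requires_grad=True)  # zero output bias
    return p


def _act(config: ModelConfig, t: Tensor) -> Tensor:
    if config.activation == "relu":
        return ad.relu(t)
    return ad.leaky_relu(t, 0.01)


def _gat_layer(p: dict, k: int, h: Tensor, batch: _Batch, config: ModelConfig) -> Tensor:
    hw = ad.matmul(h, p[f"gat{k}_w"])
    s_src = ad.matmul(hw, p[f"gat{k}_a_src"])  # (N, 1)
    s_dst = ad.matmul(hw, p[f"gat{k}_a_dst"])
    scores = ad.reshape(
        ad.add(ad.gather(s_src, batch.src), ad.gather(s_dst, batch.dst)), (len(batch.src),)
    )
    # attention also reads the edge weight (signed log scale)
    scores = ad.add(scores, ad.mul(Tensor(batch.edge_logw), p[f"gat{k}_a_w"]))
    scores = ad.leaky_relu(scores, config.negative_slope)
    alpha = ad.segment_softmax(scores, batch.dst, batch.n_nodes)
    msg = ad.mul(ad.gather(hw, batch.src, batch.scat_src), ad.reshape(alpha, (-1, 1)))
    out = ad.segment_sum(msg, batch.dst, batch.n_nodes, batch.scat_dst)
    return ad.add(out, p[f"gat{k}_b"])


def _gcn_layer(p: dict, h: Tensor, batch: _Batch) -> Tensor:
    hw = ad.matmul(h, p["gcn_w"])
    norm = Tensor(batch.gcn_norm.reshape(-1, 1))
    msg = ad.mul(ad.gather(hw, batch.src, batch.scat_src), norm)
    out = ad.segment_sum(msg, batch.dst, batch.n_nodes, batch.scat_dst)
    return ad.add(out, p["gcn_b"])


def forward(params: dict[str, Tensor], batch: _Batch, config: ModelConfig) -> Tensor:
    """Standardised-scale predictions, shape (n_graphs,)."""
    h = Tensor(batch.x)
    for k in range(len(config.attention_widths) - 1):
        h = _act(config, _gat_layer(params, k, h, batch, config))
    h = _act(config, _gcn_layer(params, h, batch))
    pooled = ad.segment_max(h, batch.node_graph, batch.n_graphs)
    h = _act(config, ad.add(ad.matmul(pooled, params["post_w"]), params["post_b"]))
    h = _act(config, ad.add(ad.matmul(h, params["dense1_w"]), params["dense1_b"]))
    out = ad.add(ad.matmul(h, params["dense2_w"]), params["dense2_b"])
    return ad.reshape(out, (batch.n_graphs,))


# --------------------------------------------------------------------------
# optimiser


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            # decoupled weight decay: shrink is lr*wd*w per step, so the
            # regulariser cannot swamp the loss signal inside the adaptive step
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


# --------------------------------------------------------------------------
# model object


@dataclass
class TrainedRegressor:
    """Fitted parameters plus the target scaling learned on the training set."""

    params: dict[str, Tensor]
    config: ModelConfig
    y_mean: float
    y_std: float
    history: list[float] = field(default_factory=list)  # per-epoch mean loss

    def predict(self, graphs: list[SampleGraph], chunk: int = 256) -> np.ndarray:
        """Deterministic SOC predictions in g kg^-1 (no stochastic layers)."""
        prepared = [_Prepared(g) for g in graphs]
        return self.predict_prepared(prepared, chunk=chunk)

    def predict_prepared(self, prepared: list["_Prepared"], chunk: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(prepared), chunk):
            batch = _Batch(prepared[i : i + chunk])
            out.append(forward(self.params, batch, self.config).data)
        raw = np.concatenate(out) if out else np.array([])
        return raw * self.y_std + self.y_mean

    def predict_one(self, graph: SampleGraph) -> float:
        return float(self.predict([graph])[0])

    def save(self, path: str | Path) -> None:
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "history": self.history,
        }
        arrays = {k: t.data for k, t in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedRegressor":
        with np.load(path) as npz:
            meta = json.loads(npz["__meta__"].tobytes().decode())
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            cfg = meta["config"]
            for key in ("attention_widths", "dense_widths"):
                if key in cfg and isinstance(cfg[key], list):
                    cfg[key] = tuple(cfg[key])
            params = {
                k: Tensor(npz[k], requires_grad=True) for k in npz.files if k != "__meta__"
            }
        return cls(
            params=params,
            config=ModelConfig(**cfg),
            y_mean=meta["y_mean"],
            y_std=meta["y_std"],
            history=meta["history"],
        )


# --------------------------------------------------------------------------
# protocol: split, fit, cross-validate, evaluate


def split_data(sample_ids: list, fraction: float = 0.85, seed: int = 40) -> tuple[list, list]:
    """Deterministic train/test partition: |train| = floor(fraction * n)."""
    n = len(sample_ids)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError(f"fraction {fraction} leaves an empty partition for n={n}")
    train_ids, test_ids = train_test_split(
        list(sample_ids), train_size=n_train, random_state=seed, shuffle=True
    )
    return train_ids, test_ids


def _fit(
    prepared: list[_Prepared],
    labels: np.ndarray,
    config: ModelConfig,
    seed: int,
) -> TrainedRegressor:
    rng = np.random.default_rng(seed)
    params = init_params(config, rng)
    if config.standardize_targets:
        y_mean = float(labels.mean())
        y_std = float(labels.std()) or 1.0
    else:
        y_mean, y_std = 0.0, 1.0
    y = (labels - y_mean) / y_std
    opt = _Adam(params, config.learning_rate, config.weight_decay)
    loss_fn = ad.mean_abs_error if config.loss == "l1" else ad.mean_square_error
    history = []
    n = len(prepared)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            batch = _Batch([prepared[j] for j in idx])
            opt.zero_grad()
            pred = forward(params, batch, config)
            loss = loss_fn(pred, y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history.append(epoch_loss / n)
    return TrainedRegressor(params=params, config=config, y_mean=y_mean, y_std=y_std, history=history)


def _metrics(pred: np.ndarray, truth: np.ndarray) -> Metrics:
    mae = float(np.mean(np.abs(pred - truth)))
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    if len(truth) < 2 or np.std(truth) == 0 or np.std(pred) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(pred, truth).statistic)
    return Metrics(mae=mae, rmse=rmse, pearson_r=r)


def evaluate(model: TrainedRegressor, graphs: list[SampleGraph]) -> Metrics:
    truth = np.array([g.label for g in graphs])
    pred = model.predict(graphs)
    return _metrics(pred, truth)


def null_model_mae(train_labels: np.ndarray, eval_labels: np.ndarray) -> float:
    """MAE of always predicting the training mean."""
    return float(np.mean(np.abs(np.asarray(eval_labels) - np.mean(train_labels))))


def train(
    graphs: list[SampleGraph], config: ModelConfig | None = None
) -> tuple[TrainedRegressor, EvalReport]:
    """Full protocol: split, 5-fold CV on the training portion, final fit.

    The held-out test partition is touched only for the final report.
    """
    config = config or ModelConfig()
    config.validate()
    n = len(graphs)
    if n < config.folds:
        raise ValueError(f"need at least {config.folds} graphs, got {n}")
    idx = np.arange(n)
    train_idx, test_idx = split_data(list(idx), config.split_fraction, config.split_seed)
    train_idx, test_idx = np.array(train_idx), np.array(test_idx)
    if len(train_idx) < 2 * config.folds:
        raise ValueError(f"training portion too small for {config.folds}-fold CV")
    prepared = [_Prepared(g) for g in graphs]
    labels = np.array([g.label for g in graphs])

    kf = KFold(n_splits=config.folds, shuffle=True, random_state=config.split_seed)
    fold_maes = []
    for fold, (tr, va) in enumerate(kf.split(train_idx)):
        sub_tr, sub_va = train_idx[tr], train_idx[va]
        model = _fit([prepared[j] for j in sub_tr], labels[sub_tr], config, seed=config.init_seed + fold + 1)
        pred = model.predict_prepared([prepared[j] for j in sub_va])
        fold_maes.append(float(np.mean(np.abs(pred - labels[sub_va]))))

    final = _fit([prepared[j] for j in train_idx], labels[train_idx], config, seed=config.init_seed)
    train_metrics = _metrics(final.predict_prepared([prepared[j] for j in train_idx]), labels[train_idx])
    test_metrics = _metrics(final.predict_prepared([prepared[j] for j in test_idx]), labels[test_idx])
    report = EvalReport(
        train_mae=train_metrics.mae,
        test_mae=test_metrics.mae,
        cv_mean_mae=float(np.mean(fold_maes)),
        cv_sd_mae=float(np.std(fold_maes)),
        rmse=test_metrics.rmse,
        pearson_r=test_metrics.pearson_r,
    )
    return final, report
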