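"""Graph-attention prediction of community degradation phenotypes.

A multi-head graph attention network (GAT) consumes the heterogeneous
metabolic subgraph induced by a candidate community (member strains plus
their enzyme and metabolite neighbors), with node features built from the
spline/Node2Vec encoding. Three attention layers (heads concatenated in the
first two, averaged in the last), ELU activations, batch normalization and
global attention pooling feed an MLP head with a sigmoid output, so the
predicted per-pollutant degradation efficiencies always lie in [0, 1]^3.

Training minimizes L = MSE + lambda1 * L2(weights) + lambda2 * L_stability,
where the stability term penalizes the squared deviation between the
community prediction and predictions on its leave-one-member-out subgraphs
(zero for single-strain samples). Optimization is Adam with single-cycle
cosine-annealed learning rate and early stopping on a validation plateau.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .autodiff import Tensor, concat, softmax
from .network import MetabolicGraph

__all__ = [
    "PredictorConfig",
    "CommunitySample",
    "GATPredictor",
    "CVMetrics",
    "build_model",
    "build_sample",
    "build_dataset",
    "predict",
    "loss",
    "train",
    "loocv",
]


@dataclass
class PredictorConfig:
    """Architecture and optimization hyperparameters.

    Defaults follow the full-scale configuration: 3 GAT layers of 8 heads
    with dims [662, 256, 128, 64] (662 = 534 spline + 128 embedding
    features), MLP head [64, 32, 16, 3], sigmoid output, dropout 0.3, batch
    norm, Adam at lr 1e-3 with cosine annealing, lambda1 = 1e-3 (L2),
    lambda2 = 1e-2 (stability). All dims are configurable; reduced widths
    are appropriate for desk-scale experiments.
    """

    input_dim: int = 662
    gat_layers: int = 3
    heads_per_layer: int = 8
    layer_dims: tuple = (256, 128, 64)  # GAT output dims per layer
    mlp_dims: tuple = (64, 32, 16, 3)
    dropout: float = 0.3
    batch_norm: bool = True
    learning_rate: float = 0.001
    lambda1: float = 0.001
    lambda2: float = 0.01
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_dims) != self.gat_layers:
            raise ValueError("layer_dims must list one output dim per GAT layer")
        if self.mlp_dims[0] != self.layer_dims[-1]:
            raise ValueError("MLP input dim must equal the last GAT layer dim")
        if self.mlp_dims[-1] != 3:
            raise ValueError("output dimension must be 3 (one efficiency per pollutant)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if any(d <= 0 for d in (self.input_dim, *self.layer_dims, *self.mlp_dims)):
            raise ValueError("all dims must be positive")
        for li, d in enumerate(self.layer_dims):
            if li < self.gat_layers - 1 and d % self.heads_per_layer != 0:
                raise ValueError(
                    "concatenating layers need output dims divisible by heads_per_layer"
                )


@dataclass
class CommunitySample:
    """One (community subgraph, label) training or prediction instance."""

    members: tuple[str, ...]
    nodes: tuple[str, ...]
    features: np.ndarray  # (n_nodes, input_dim)
    adj: np.ndarray  # (n_nodes, n_nodes) with self-loops
    label: np.ndarray | None = None  # (3,)


@dataclass(frozen=True)
class CVMetrics:
    """Pooled cross-validation metrics over held-out predictions."""

    r2: float
    rmse: float
    spearman_rho: float
    spearman_p: float = float("nan")
    degenerate: bool = False


# ---------------------------------------------------------------------------
# sample construction


def build_sample(
    mg: MetabolicGraph,
    members,
    feature_map: dict,
    label=None,
) -> CommunitySample:
    """Induced community subgraph: members + enzyme neighbors + their metabolites."""
    members = tuple(sorted(members))
    g = mg.graph
    for m in members:
        if m not in g:
            raise KeyError(f"strain {m} not in graph")
    enzymes = set()
    for m in members:
        enzymes |= {v for v in g.neighbors(m) if g.nodes[v].get("ntype") == "enzyme"}
    mets = set()
    for e in enzymes:
        mets |= {v for v in g.neighbors(e) if g.nodes[v].get("ntype") == "metabolite"}
    nodes = tuple(list(members) + sorted(enzymes) + sorted(mets))
    missing = [v for v in nodes if v not in feature_map]
    if missing:
        raise KeyError(f"missing feature vectors for nodes: {missing[:5]}")
    feats = np.vstack([feature_map[v] for v in nodes])
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    adj = np.eye(n)
    for u, v in g.subgraph(nodes).edges():
        adj[pos[u], pos[v]] = adj[pos[v], pos[u]] = 1.0
    lab = None if label is None else np.asarray(label, dtype=float)
    return CommunitySample(members=members, nodes=nodes, features=feats, adj=adj, label=lab)


def build_dataset(
    mg: MetabolicGraph, feature_map: dict, labels: pd.DataFrame
) -> list[CommunitySample]:
    """One single-strain sample per labelled strain (rows of ``labels``)."""
    return [
        build_sample(mg, [s], feature_map, label=labels.loc[s].to_numpy())
        for s in labels.index
    ]


def _batch(samples: list[CommunitySample]):
    """Pad samples to a common node count; returns (X, adj, node_mask, Y)."""
    B = len(samples)
    S = max(s.features.shape[0] for s in samples)
    F = samples[0].features.shape[1]
    X = np.zeros((B, S, F))
    A = np.zeros((B, S, S))
    M = np.zeros((B, S))
    Y = np.zeros((B, 3))
    for i, s in enumerate(samples):
        n = s.features.shape[0]
        X[i, :n] = s.features
        A[i, :n, :n] = s.adj
        M[i, :n] = 1.0
        if s.label is not None:
            Y[i] = s.label
    return X, A, M, Y


# ---------------------------------------------------------------------------
# the model


class GATPredictor:
    """Multi-head GAT + global attention pooling + sigmoid MLP head."""

    def __init__(self, config: PredictorConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self.bn_running: dict[str, np.ndarray] = {}
        self.training = False
        self._rng = np.random.default_rng(config.seed)
        self._init_params()

    # parameter initialization: Glorot for weights, zeros for biases
    def _glorot(self, shape) -> Tensor:
        fan_in, fan_out = shape[0], shape[-1]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(self._rng.uniform(-limit, limit, size=shape), requires_grad=True)

    def _zeros(self, shape) -> Tensor:
        return Tensor(np.zeros(shape), requires_grad=True)

    def _init_params(self) -> None:
        cfg = self.config
        dims = [cfg.input_dim, *cfg.layer_dims]
        for li in range(cfg.gat_layers):
            d_in, d_out = dims[li], dims[li + 1]
            concat_heads = li < cfg.gat_layers - 1
            dh = d_out // cfg.heads_per_layer if concat_heads else d_out
            for h in range(cfg.heads_per_layer):
                self.params[f"gat{li}_W{h}"] = self._glorot((d_in, dh))
                self.params[f"gat{li}_asrc{h}"] = self._glorot((dh, 1))
                self.params[f"gat{li}_adst{h}"] = self._glorot((dh, 1))
            self.params[f"gat{li}_b"] = self._zeros((d_out,))
            if cfg.batch_norm:
                self.params[f"bn{li}_gamma"] = Tensor(np.ones(d_out), requires_grad=True)
                self.params[f"bn{li}_beta"] = self._zeros((d_out,))
                self.bn_running[f"bn{li}_mean"] = np.zeros(d_out)
                self.bn_running[f"bn{li}_var"] = np.ones(d_out)
        d_pool = cfg.layer_dims[-1]
        self.params["pool_gate_W"] = self._glorot((d_pool, 1))
        self.params["pool_gate_b"] = self._zeros((1,))
        for mi in range(len(cfg.mlp_dims) - 1):
            self.params[f"mlp{mi}_W"] = self._glorot((cfg.mlp_dims[mi], cfg.mlp_dims[mi + 1]))
            self.params[f"mlp{mi}_b"] = self._zeros((cfg.mlp_dims[mi + 1],))

    # -- forward -------------------------------------------------------------
    def _gat_layer(self, li: int, h: Tensor, adj: np.ndarray, node_mask: np.ndarray) -> Tensor:
        cfg = self.config
        concat_heads = li < cfg.gat_layers - 1
        heads = []
        for hi in range(cfg.heads_per_layer):
            W = self.params[f"gat{li}_W{hi}"]
            wh = h @ W  # (B, S, dh)
            src = wh @ self.params[f"gat{li}_asrc{hi}"]  # (B, S, 1)
            dst = wh @ self.params[f"gat{li}_adst{hi}"]  # (B, S, 1)
            e = (src + dst.transpose_last()).leaky_relu(cfg.leaky_slope)  # (B, S, S)
            att = softmax(e, mask=adj, axis=-1)
            heads.append(att @ wh)
        out = concat(heads, axis=-1) if concat_heads else _mean_tensors(heads)
        out = out + self.params[f"gat{li}_b"]
        out = out.elu()
        if cfg.batch_norm:
            out = self._batch_norm(li, out, node_mask)
        if self.training and cfg.dropout > 0:
            keep = (self._rng.random(out.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            out = out * keep
        return out

    def _batch_norm(self, li: int, x: Tensor, node_mask: np.ndarray) -> Tensor:
        eps = 1e-5
        mask = node_mask[..., None]  # (B, S, 1)
        if self.training:
            n_valid = mask.sum()
            mean = _masked_mean(x, mask, n_valid)
            centered = (x - mean) * mask
            var = _masked_mean(centered * centered, mask, n_valid)
            m = 0.9
            self.bn_running[f"bn{li}_mean"] = (
                m * self.bn_running[f"bn{li}_mean"] + (1 - m) * mean.data
            )
            self.bn_running[f"bn{li}_var"] = (
                m * self.bn_running[f"bn{li}_var"] + (1 - m) * var.data
            )
        else:
            mean = Tensor(self.bn_running[f"bn{li}_mean"])
            var = Tensor(self.bn_running[f"bn{li}_var"])
        norm = (x - mean) * (var + eps).pow(-0.5)
        out = norm * self.params[f"bn{li}_gamma"] + self.params[f"bn{li}_beta"]
        return out * mask  # keep padded rows at zero

    def forward(self, X: np.ndarray, adj: np.ndarray, node_mask: np.ndarray) -> Tensor:
        """Batched forward pass -> (B, 3) sigmoid outputs."""
        h = Tensor(X)
        for li in range(self.config.gat_layers):
            h = self._gat_layer(li, h, adj, node_mask)
        # global attention pooling over valid nodes
        gate = h @ self.params["pool_gate_W"] + self.params["pool_gate_b"]  # (B, S, 1)
        att = softmax(gate.transpose_last(), mask=node_mask[:, None, :], axis=-1)  # (B,1,S)
        pooled = (att @ h).sum(axis=1)  # (B, d)
        out = pooled
        n_mlp = len(self.config.mlp_dims) - 1
        for mi in range(n_mlp):
            out = out @ self.params[f"mlp{mi}_W"] + self.params[f"mlp{mi}_b"]
            if mi < n_mlp - 1:
                out = out.elu()
        return out.sigmoid()

    def weight_l2(self) -> Tensor:
        """Sum of squared weight-matrix entries (biases and BN excluded)."""
        total = Tensor(0.0)
        for name, p in self.params.items():
            if "_W" in name or "asrc" in name or "adst" in name:
                total = total + (p * p).sum()
        return total

    # -- persistence -----------------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "params": {k: v.data.tolist() for k, v in self.params.items()},
            "bn_running": {k: v.tolist() for k, v in self.bn_running.items()},
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.state_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "GATPredictor":
        with open(path) as fh:
            state = json.load(fh)
        cfg = state["config"]
        cfg["layer_dims"] = tuple(cfg["layer_dims"])
        cfg["mlp_dims"] = tuple(cfg["mlp_dims"])
        model = cls(PredictorConfig(**cfg))
        for k, v in state["params"].items():
            model.params[k] = Tensor(np.array(v), requires_grad=True)
        for k, v in state["bn_running"].items():
            model.bn_running[k] = np.array(v)
        return model


def _mean_tensors(tensors: list[Tensor]) -> Tensor:
    out = tensors[0]
    for t in tensors[1:]:
        out = out + t
    return out * (1.0 / len(tensors))


def _masked_mean(x: Tensor, mask: np.ndarray, n_valid: float) -> Tensor:
    return (x * mask).sum(axis=0).sum(axis=0) * (1.0 / n_valid)


def build_model(config: PredictorConfig | None = None) -> GATPredictor:
    """Construct a seeded predictor; same seed + config -> identical weights."""
    return GATPredictor(config or PredictorConfig())


# ---------------------------------------------------------------------------
# prediction / loss / training


def predict(model: GATPredictor, sample: CommunitySample) -> np.ndarray:
    """Predicted (lignin, atrazine, pfas) efficiencies in [0, 1]^3."""
    if sample.features.shape[1] != model.config.input_dim:
        raise ValueError(
            f"sample features have dim {sample.features.shape[1]}, "
            f"model expects {model.config.input_dim}"
        )
    model.training = False
    X, A, M, _ = _batch([sample])
    return model.forward(X, A, M).data[0]


def loss(
    pred: Tensor,
    target: np.ndarray,
    model: GATPredictor | None = None,
    aux_preds: Tensor | None = None,
    lambda1: float | None = None,
    lambda2: float | None = None,
) -> Tensor:
    """Composite loss: MSE + lambda1 * L2(weights) + lambda2 * stability.

    ``aux_preds`` holds predictions on leave-one-member-out subcommunities
    (any leading shape ending in 3); the stability term is their mean squared
    deviation from ``pred``. With lambda1 = lambda2 = 0 this is plain MSE.
    """
    if np.any(~np.isfinite(pred.data)) or np.any(~np.isfinite(np.asarray(target, dtype=float))):
        raise FloatingPointError("loss received non-finite predictions or targets")
    l1 = model.config.lambda1 if (lambda1 is None and model is not None) else (lambda1 or 0.0)
    l2 = model.config.lambda2 if (lambda2 is None and model is not None) else (lambda2 or 0.0)
    diff = pred - Tensor(np.asarray(target, dtype=float))
    total = (diff * diff).mean()
    if l1 > 0 and model is not None:
        total = total + l1 * model.weight_l2()
    if l2 > 0 and aux_preds is not None and aux_preds.data.size > 0:
        dev = aux_preds - _broadcast_pred(pred, aux_preds)
        total = total + l2 * (dev * dev).mean()
    return total


def _broadcast_pred(pred: Tensor, aux: Tensor) -> Tensor:
    if pred.shape == aux.shape:
        return pred
    reps = int(np.prod(aux.shape[:-1]) // max(np.prod(pred.shape[:-1]), 1))
    return concat([pred] * reps, axis=0) if reps > 1 else pred


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def train(
    model: GATPredictor,
    dataset: list[CommunitySample],
    epochs: int = 200,
    seed: int | None = None,
    val_fraction: float = 0.0,
    patience: int = 20,
    verbose: bool = False,
) -> dict:
    """Fit the predictor by full-batch Adam with cosine-annealed lr.

    With ``val_fraction > 0`` a random split is monitored and training stops
    once the validation loss has not improved for ``patience`` epochs
    (plateau early stopping), restoring the best parameters. Returns
    ``{"loss_trace": [...], "val_trace": [...], "stopped_epoch": int}``.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    if any(s.label is None for s in dataset):
        raise ValueError("all training samples need labels")
    rng = np.random.default_rng(model.config.seed if seed is None else seed)
    idx = rng.permutation(len(dataset))
    n_val = int(round(val_fraction * len(dataset)))
    val = [dataset[i] for i in idx[:n_val]]
    tr = [dataset[i] for i in idx[n_val:]]
    if not tr:
        raise ValueError("validation split left no training samples")
    Xt, At, Mt, Yt = _batch(tr)
    if val:
        Xv, Av, Mv, Yv = _batch(val)

    opt = _Adam(model.params, model.config.learning_rate)
    trace, val_trace = [], []
    best_val, best_state, since_best = np.inf, None, 0
    stopped = epochs
    for ep in range(epochs):
        lr = 0.5 * model.config.learning_rate * (1.0 + np.cos(np.pi * ep / max(epochs, 1)))
        model.training = True
        opt.zero_grad()
        pred = model.forward(Xt, At, Mt)
        L = loss(pred, Yt, model=model)
        L.backward()
        opt.step(lr=lr)
        trace.append(L.item())
        if val:
            model.training = False
            vp = model.forward(Xv, Av, Mv)
            vl = float(((vp.data - Yv) ** 2).mean())
            val_trace.append(vl)
            if vl < best_val - 1e-6:
                best_val, since_best = vl, 0
                best_state = {k: p.data.copy() for k, p in model.params.items()}
            else:
                since_best += 1
                if since_best >= patience:
                    stopped = ep + 1
                    break
        if verbose and ep % 20 == 0:
            print(f"epoch {ep}: loss {trace[-1]:.5f}")
    if best_state is not None:
        for k, p in model.params.items():
            p.data = best_state[k]
    model.training = False
    return {"loss_trace": trace, "val_trace": val_trace, "stopped_epoch": stopped}


# ---------------------------------------------------------------------------
# evaluation


def loocv(
    dataset: list[CommunitySample],
    config: PredictorConfig,
    epochs: int = 150,
    seed: int = 0,
) -> CVMetrics:
    """Leave-one-out cross-validation: one model fit per held-out sample.

    Metrics are pooled over the held-out predictions (flattened across the 3
    outputs): R^2 = 1 - SS_res/SS_tot, RMSE, and Spearman rho. A degenerate
    SS_tot = 0 (constant labels) reports R^2 = 0 with ``degenerate=True``.
    """
    if len(dataset) < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    preds = np.zeros((len(dataset), 3))
    for i in range(len(dataset)):
        cfg = PredictorConfig(**{**asdict(config), "seed": config.seed + i})
        model = GATPredictor(cfg)
        train_set = [s for j, s in enumerate(dataset) if j != i]
        train(model, train_set, epochs=epochs, seed=seed + i)
        preds[i] = predict(model, dataset[i])
    y = np.vstack([s.label for s in dataset])
    return cv_metrics(y, preds)


def cv_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> CVMetrics:
    yt, yp = np.ravel(y_true), np.ravel(y_pred)
    ss_res = float(((yt - yp) ** 2).sum())
    ss_tot = float(((yt - yt.mean()) ** 2).sum())
    degenerate = ss_tot == 0.0
    r2 = 0.0 if degenerate else 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(((yt - yp) ** 2).mean()))
    if degenerate or np.allclose(yp, yp[0]):
        rho, p = 0.0, float("nan")
    else:
        rho, p = _scipy_stats.spearmanr(yt, yp)
    return CVMetrics(
        r2=float(r2),
        rmse=rmse,
        spearman_rho=float(rho),
        spearman_p=float(p),
        degenerate=degenerate,
    )
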