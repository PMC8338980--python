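"""Graph isomorphism network for subject-graph classification.

The layer rule is the standard GIN aggregate-combine step on the shared
weighted adjacency A:

    h_v^(k) = MLP_k( (1 + eps_k) * h_v^(k-1) + sum_u A_vu * h_u^(k-1) )

followed by sum-pooling of node features into a per-layer graph feature,
concatenation of all K layer features into the graph embedding, and a linear
classifier with a sigmoid output. eps_k is a learnable per-layer scalar
(initialized at 0); each MLP is two affine maps with an elementwise
activation (ReLU by default) and optional batch normalization after each
affine map. Aggregation uses the signed edge weights as stored in the edge
matrix and is evaluated through a sparse matrix product, so the cost of a
layer is linear in the number of retained edges.

Everything — forward, loss, parameter gradients, and the input gradients the
attention plots need — is implemented directly on numpy arrays; batching over
subjects is free because all subjects share one adjacency.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import expit

from .errors import InvalidSpecError, VocabularyError
from .graphs import EdgeMatrix, NodeVocabulary, SubjectGraph, SubjectGraphSet

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass
class GinConfig:
    n_layers: int = 5
    hidden_dim: int = 64
    input_dim: int = 6
    eps_learnable: bool = True
    activation: str = "relu"  # "relu" | "identity"
    dropout: float = 0.0
    batch_norm: bool = False

    def __post_init__(self):
        if self.n_layers < 1:
            raise InvalidSpecError("n_layers must be >= 1")
        if self.hidden_dim < 1 or self.input_dim < 1:
            raise InvalidSpecError("layer widths must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise InvalidSpecError("dropout must be in [0, 1)")
        if self.activation not in ("relu", "identity"):
            raise InvalidSpecError("activation must be 'relu' or 'identity'")

    @property
    def layer_dims(self) -> list[int]:
        return [self.input_dim] + [self.hidden_dim] * self.n_layers

    @property
    def embedding_dim(self) -> int:
        return self.hidden_dim * self.n_layers

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 256
    epochs: int = 200
    seed: int = 0


@dataclass
class GraphEmbedding:
    """Per-layer sum-pooled graph features and their concatenation."""

    per_layer: list[np.ndarray]  # K arrays of shape (B, C_k)
    concatenated: np.ndarray  # (B, sum_k C_k)


@dataclass
class PredictionScore:
    """Raw (pre-sigmoid) score and the sigmoid score in (0, 1)."""

    raw: np.ndarray
    sigmoid: np.ndarray


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(x, 0.0) if kind == "relu" else x


def _act_grad(pre: np.ndarray, kind: str) -> np.ndarray:
    return (pre > 0).astype(float) if kind == "relu" else np.ones_like(pre)


class GinModel:
    """Trained or freshly initialized GIN parameters bound to a vocabulary."""

    def __init__(
        self,
        config: GinConfig,
        vocab: NodeVocabulary,
        seed: int = 0,
        edge_hash: str = "",
    ):
        self.config = config
        self.vocab = vocab
        self.seed = seed
        self.edge_hash = edge_hash
        rng = np.random.default_rng(seed)
        dims = config.layer_dims
        self.params: dict[str, np.ndarray] = {}
        self.bn_state: dict[str, np.ndarray] = {}
        for k in range(config.n_layers):
            c_in, c_out = dims[k], dims[k + 1]
            self.params[f"eps_{k}"] = np.zeros(())
            self.params[f"W1_{k}"] = rng.normal(0, np.sqrt(2.0 / c_in), (c_in, c_out))
            self.params[f"b1_{k}"] = np.zeros(c_out)
            self.params[f"W2_{k}"] = rng.normal(0, np.sqrt(2.0 / c_out), (c_out, c_out))
            self.params[f"b2_{k}"] = np.zeros(c_out)
            if config.batch_norm:
                for j in (1, 2):
                    self.params[f"g{j}_{k}"] = np.ones(c_out)
                    self.params[f"beta{j}_{k}"] = np.zeros(c_out)
                    self.bn_state[f"mean{j}_{k}"] = np.zeros(c_out)
                    self.bn_state[f"var{j}_{k}"] = np.ones(c_out)
        self.params["w_out"] = rng.normal(0, 0.01, config.embedding_dim)
        self.params["b_out"] = np.zeros(())

    # -- identity construction used by analytic tests ----------------------
    def set_identity_mlps(self, classifier_weights=None, classifier_bias=0.0) -> "GinModel":
        """Make every MLP the identity map (requires hidden_dim == input_dim)."""
        c = self.config
        if c.hidden_dim != c.input_dim:
            raise InvalidSpecError("identity MLPs require hidden_dim == input_dim")
        eye = np.eye(c.input_dim)
        for k in range(c.n_layers):
            self.params[f"W1_{k}"] = eye.copy()
            self.params[f"W2_{k}"] = eye.copy()
            self.params[f"b1_{k}"] = np.zeros(c.input_dim)
            self.params[f"b2_{k}"] = np.zeros(c.input_dim)
            self.params[f"eps_{k}"] = np.zeros(())
        if classifier_weights is not None:
            self.params["w_out"] = np.asarray(classifier_weights, dtype=float)
        self.params["b_out"] = np.asarray(classifier_bias, dtype=float)
        return self

    # -- forward / backward -------------------------------------------------
    def _adjacency(self, edges: EdgeMatrix) -> sp.csr_matrix:
        if tuple(edges.names) != tuple(self.vocab.names):
            raise VocabularyError("graph vocabulary does not match model vocabulary")
        return sp.csr_matrix(edges.weights)

    @staticmethod
    def _agg(A: sp.csr_matrix, H: np.ndarray) -> np.ndarray:
        """A @ H along the node axis for H of shape (B, N, C): O(edges * B * C)."""
        B, N, C = H.shape
        out = A @ H.transpose(1, 0, 2).reshape(N, B * C)
        return np.asarray(out).reshape(N, B, C).transpose(1, 0, 2)

    def _forward(self, H0: np.ndarray, A: sp.csr_matrix, train: bool, rng=None):
        cfg = self.config
        p = self.params
        cache: dict = {"H": [H0], "Z": [], "pre": [], "post": [], "mask": []}
        H = H0
        for k in range(cfg.n_layers):
            Z = (1.0 + p[f"eps_{k}"]) * H + self._agg(A, H)
            B, N, C = Z.shape
            X = Z.reshape(B * N, C)
            layer_pre, layer_post, layer_mask = [], [], []
            cur = X
            for j in (1, 2):
                pre = cur @ p[f"W{j}_{k}"] + p[f"b{j}_{k}"]
                bn_cache = None
                if cfg.batch_norm:
                    pre, bn_cache = self._bn_forward(pre, j, k, train)
                post = _act(pre, cfg.activation)
                mask = None
                if train and cfg.dropout > 0.0:
                    mask = (rng.random(post.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
                    post = post * mask
                layer_pre.append((pre, bn_cache))
                layer_post.append(post)
                layer_mask.append(mask)
                cur = post
            H = cur.reshape(B, N, -1)
            cache["Z"].append(X)
            cache["pre"].append(layer_pre)
            cache["post"].append(layer_post)
            cache["mask"].append(layer_mask)
            cache["H"].append(H)
        per_layer = [cache["H"][k + 1].sum(axis=1) for k in range(cfg.n_layers)]
        G = np.concatenate(per_layer, axis=1)
        y = G @ p["w_out"] + p["b_out"]
        cache["per_layer"] = per_layer
        cache["G"] = G
        return y, cache

    def _bn_forward(self, x, j, k, train):
        g, beta = self.params[f"g{j}_{k}"], self.params[f"beta{j}_{k}"]
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.bn_state[f"mean{j}_{k}"] = (
                _BN_MOMENTUM * self.bn_state[f"mean{j}_{k}"] + (1 - _BN_MOMENTUM) * mu
            )
            self.bn_state[f"var{j}_{k}"] = (
                _BN_MOMENTUM * self.bn_state[f"var{j}_{k}"] + (1 - _BN_MOMENTUM) * var
            )
        else:
            mu = self.bn_state[f"mean{j}_{k}"]
            var = self.bn_state[f"var{j}_{k}"]
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu) * inv
        return g * xhat + beta, (xhat, inv, g, train)

    @staticmethod
    def _bn_backward(dout, bn_cache):
        xhat, inv, g, train = bn_cache
        dg = (dout * xhat).sum(axis=0)
        dbeta = dout.sum(axis=0)
        if train:
            m = dout.shape[0]
            dx = (g * inv / m) * (
                m * dout - dout.sum(axis=0) - xhat * (dout * xhat).sum(axis=0)
            )
        else:
            dx = dout * g * inv
        return dx, dg, dbeta

    def _backward(self, cache, dy: np.ndarray, A: sp.csr_matrix):
        """Gradients of sum(dy * y) w.r.t. parameters and the input features."""
        cfg = self.config
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        G = cache["G"]
        grads["w_out"] = G.T @ dy
        grads["b_out"] = np.asarray(dy.sum())
        dG = np.outer(dy, p["w_out"])
        dims = np.cumsum([0] + [cfg.hidden_dim] * cfg.n_layers)
        dg_layers = [dG[:, dims[k] : dims[k + 1]] for k in range(cfg.n_layers)]

        AT = A.T.tocsr()
        dH = None
        for k in range(cfg.n_layers - 1, -1, -1):
            B, N, _ = cache["H"][k + 1].shape
            pooled = np.repeat(dg_layers[k][:, None, :], N, axis=1)
            dH = pooled if dH is None else dH + pooled
            dcur = dH.reshape(B * N, -1)
            for j in (2, 1):
                pre, bn_cache = cache["pre"][k][j - 1]
                mask = cache["mask"][k][j - 1]
                if mask is not None:
                    dcur = dcur * mask
                dpre = dcur * _act_grad(pre, cfg.activation)
                if cfg.batch_norm:
                    dpre, dgj, dbj = self._bn_backward(dpre, bn_cache)
                    grads[f"g{j}_{k}"] += dgj
                    grads[f"beta{j}_{k}"] += dbj
                inp = cache["Z"][k] if j == 1 else cache["post"][k][0]
                grads[f"W{j}_{k}"] += inp.T @ dpre
                grads[f"b{j}_{k}"] += dpre.sum(axis=0)
                dcur = dpre @ p[f"W{j}_{k}"].T
            dZ = dcur.reshape(B, N, -1)
            H_prev = cache["H"][k]
            grads[f"eps_{k}"] = np.asarray((dZ * H_prev).sum())
            dH = (1.0 + p[f"eps_{k}"]) * dZ + self._agg(AT, dZ)
        return grads, dH

    # -- public API ----------------------------------------------------------
    def forward(self, graphs: SubjectGraphSet | SubjectGraph):
        """Embed and score subject graphs; returns (GraphEmbedding, PredictionScore)."""
        single = isinstance(graphs, SubjectGraph)
        feats = graphs.features[None] if single else graphs.features
        if feats.shape[1] != len(self.vocab.names) or feats.shape[2] != self.config.input_dim:
            raise VocabularyError(
                f"feature matrix {feats.shape[1:]} does not match model "
                f"({len(self.vocab.names)}, {self.config.input_dim})"
            )
        A = self._adjacency(graphs.edges)
        y, cache = self._forward(feats, A, train=False)
        emb = GraphEmbedding(per_layer=cache["per_layer"], concatenated=cache["G"])
        if single:
            y = y[0:1]
        return emb, PredictionScore(raw=y, sigmoid=expit(y))

    def predict(self, graphs: SubjectGraphSet) -> np.ndarray:
        return self.forward(graphs)[1].sigmoid

    def layer_node_features(self, graphs: SubjectGraphSet) -> list[np.ndarray]:
        """Per-layer node features H^(k), k = 1..K, each of shape (B, N, C_k)."""
        A = self._adjacency(graphs.edges)
        _, cache = self._forward(graphs.features, A, train=False)
        return cache["H"][1:]

    def input_gradient(self, graphs: SubjectGraphSet | SubjectGraph) -> np.ndarray:
        """d(raw score)/d(input feature slot) for every subject: (B, N, 6).

        The gradient is taken with respect to the pre-sigmoid output; batch
        elements are independent, so one backward pass yields each subject's
        own gradient.
        """
        single = isinstance(graphs, SubjectGraph)
        feats = graphs.features[None] if single else graphs.features
        A = self._adjacency(graphs.edges)
        y, cache = self._forward(feats, A, train=False)
        _, dH0 = self._backward(cache, np.ones_like(y), A)
        return dH0[0] if single else dH0

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"param::{k}": v for k, v in self.params.items()}
        arrays.update({f"bn::{k}": v for k, v in self.bn_state.items()})
        np.savez(path, **arrays)
        meta = {
            "config": self.config.to_dict(),
            "vocab": self.vocab.to_dict(),
            "vocab_hash": self.vocab.content_hash(),
            "edge_hash": self.edge_hash,
            "seed": self.seed,
        }
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path) -> "GinModel":
        with open(str(path) + ".meta.json") as fh:
            meta = json.load(fh)
        vocab = NodeVocabulary.from_dict(meta["vocab"])
        if vocab.content_hash() != meta["vocab_hash"]:
            raise VocabularyError("vocabulary hash mismatch in saved model")
        model = cls(GinConfig(**meta["config"]), vocab, seed=meta["seed"], edge_hash=meta["edge_hash"])
        with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as data:
            for key in data.files:
                kind, name = key.split("::", 1)
                (model.params if kind == "param" else model.bn_state)[name] = data[key]
        return model

    def copy_params(self) -> dict:
        return copy.deepcopy(self.params)


def bce_loss(scores, labels) -> float:
    """Mean binary cross-entropy of sigmoid scores; scores clipped to [1e-7, 1-1e-7]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    p = np.clip(scores, 1e-7, 1.0 - 1e-7)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def forward(model: GinModel, graph):
    """Functional alias for :meth:`GinModel.forward`."""
    return model.forward(graph)


def input_gradient(model: GinModel, graph) -> np.ndarray:
    """Functional alias for :meth:`GinModel.input_gradient`."""
    return model.input_gradient(graph)


# ---------------------------------------------------------------------------
# Training with checkpoint selection
# ---------------------------------------------------------------------------


@dataclass
class CheckpointRule:
    """Keep the minimum-validation-loss epoch among epochs with both
    validation sensitivity and specificity above the floor (default 0.80),
    judged at the given decision threshold on the sigmoid score."""

    min_sensitivity: float = 0.80
    min_specificity: float = 0.80
    threshold: float = 0.5


@dataclass
class TrainLog:
    trace: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    constraint_met: bool = False


def select_checkpoint(trace, rule: CheckpointRule):
    """Pick the epoch index per the checkpoint rule from (loss, sens, spec) triples.

    Falls back to the overall minimal-loss epoch (with a warning) when no
    epoch satisfies the sensitivity/specificity constraint; NaN sensitivity
    or specificity counts as a constraint failure.
    """
    losses, ok = [], []
    for rec in trace:
        loss, sens, spec = rec if not isinstance(rec, dict) else (
            rec["loss"],
            rec["sensitivity"],
            rec["specificity"],
        )
        losses.append(loss)
        ok.append(
            np.isfinite(sens)
            and np.isfinite(spec)
            and sens > rule.min_sensitivity
            and spec > rule.min_specificity
        )
    losses = np.asarray(losses, dtype=float)
    if any(ok):
        idx_ok = np.flatnonzero(ok)
        return int(idx_ok[np.argmin(losses[idx_ok])]), True
    warnings.warn(
        "no epoch satisfied the sensitivity/specificity constraint; "
        "returning the minimal-validation-loss checkpoint"
    )
    return int(np.argmin(losses)), False


def _sens_spec(scores: np.ndarray, labels: np.ndarray, threshold: float):
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    sens = float(np.mean(pred[pos])) if pos.any() else float("nan")
    spec = float(np.mean(~pred[neg])) if neg.any() else float("nan")
    return sens, spec


def train_gin(
    train_set: SubjectGraphSet,
    val_set: SubjectGraphSet,
    config: GinConfig,
    train_config: TrainConfig,
    rule: CheckpointRule | None = None,
) -> tuple[GinModel, TrainLog]:
    """Train with Adam on binary cross-entropy and select the checkpoint.

    All randomness (initialization, batching, dropout) flows from
    ``train_config.seed``; two runs with identical inputs and seed produce
    identical validation-loss trajectories.
    """
    rule = rule or CheckpointRule()
    if train_set.labels is None or val_set.labels is None:
        raise ValueError("train and validation sets must carry labels")
    if len(np.unique(train_set.labels)) < 2:
        raise ValueError("training partition contains a single class")
    model = GinModel(config, train_set.vocab, seed=train_config.seed,
                     edge_hash=train_set.edges.content_hash())
    A = model._adjacency(train_set.edges)
    rng = np.random.default_rng(train_config.seed + 1)

    trainable = [k for k in model.params if config.eps_learnable or not k.startswith("eps_")]
    m_state = {k: np.zeros_like(model.params[k]) for k in trainable}
    v_state = {k: np.zeros_like(model.params[k]) for k in trainable}
    beta1, beta2, adam_eps, t = 0.9, 0.999, 1e-8, 0

    log = TrainLog()
    best_params, best_bn = None, None
    n = len(train_set)
    labels = train_set.labels.astype(float)
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            H0 = train_set.features[idx]
            y, cache = model._forward(H0, A, train=True, rng=rng)
            dy = (expit(y) - labels[idx]) / len(idx)
            grads, _ = model._backward(cache, dy, A)
            t += 1
            for k in trainable:
                g = grads[k]
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
                mhat = m_state[k] / (1 - beta1**t)
                vhat = v_state[k] / (1 - beta2**t)
                model.params[k] = model.params[k] - train_config.lr * mhat / (
                    np.sqrt(vhat) + adam_eps
                )
        val_scores = model.predict(val_set)
        val_loss = bce_loss(val_scores, val_set.labels)
        sens, spec = _sens_spec(val_scores, val_set.labels, rule.threshold)
        log.trace.append({"epoch": epoch, "loss": val_loss, "sensitivity": sens,
                          "specificity": spec})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idx_best, met = select_checkpoint(log.trace, rule)
        if idx_best == epoch:
            best_params = model.copy_params()
            best_bn = copy.deepcopy(model.bn_state)
            log.best_epoch = epoch
            log.constraint_met = met
    if not log.constraint_met:
        warnings.warn(
            "checkpoint constraint (validation sensitivity/specificity > "
            f"{rule.min_sensitivity:.0%}/{rule.min_specificity:.0%}) never satisfied; "
            f"kept minimal-loss epoch {log.best_epoch}"
        )
    model.params = best_params
    model.bn_state = best_bn
    return model, log
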