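"""Multi-task graph-attention classifier of peptide receptor activity.

Architecture: a shared encoder of four GATv2-style attention layers (6 heads,
96-dimensional hidden representations, ReLU, batch-norm, dropout 0.2,
identity residual connections after layers 2 and 4), a Set2Set readout with
three processing steps (192-dim output), a 192->96 representation layer, and
three task-specific heads (96->48->24->1) producing one logit per receptor
(GCGR, GLP1R, GIPR).  Per-sample loss is focal loss (alpha = 0.25,
gamma = 2.0); per-task weights combine the receptors, with missing labels
masked out.

Everything runs on the package's numpy autodiff core (:mod:`._autodiff`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import _autodiff as ad
from ._autodiff import Parameter, Tensor
from .graphrep import NormStats, PeptideGraph

RECEPTORS = ("GCGR", "GLP1R", "GIPR")


@dataclass
class ModelConfig:
    n_layers: int = 4
    n_heads: int = 6
    hidden_dim: int = 96
    dropout: float = 0.2
    set2set_steps: int = 3
    repr_dim: int = 96
    head_hidden: tuple[int, ...] = (48, 24)
    receptors: tuple[str, ...] = RECEPTORS
    in_dim: int = 7
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    task_weight: float = 0.5

    def __post_init__(self):
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError(
                f"hidden_dim {self.hidden_dim} not divisible by n_heads {self.n_heads}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout {self.dropout} outside [0, 1)")
        if self.n_layers < 1 or self.set2set_steps < 1:
            raise ValueError("n_layers and set2set_steps must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["head_hidden"] = list(self.head_hidden)
        d["receptors"] = list(self.receptors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["head_hidden"] = tuple(d.get("head_hidden", (48, 24)))
        d["receptors"] = tuple(d.get("receptors", RECEPTORS))
        return cls(**d)


# ---------------------------------------------------------------------------
# layers


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class BatchNorm1d:
    """Batch normalization over the row (node or graph) dimension."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training and x.shape[0] > 1:
            mu = ad.tmean(x, axis=0, keepdims=True)
            var = ad.tmean((x - mu) ** 2, axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            inv = (var + self.eps) ** -0.5
            return (x - mu) * inv * self.gamma + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - Tensor(self.running_mean)) * Tensor(inv) * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]

    def state(self) -> dict:
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class Dropout:
    def __init__(self, p: float):
        self.p = p

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        if not training or self.p <= 0.0:
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class GATv2Conv:
    """One multi-head GATv2 attention layer on a node graph with self-loops."""

    def __init__(self, n_in: int, n_out: int, heads: int, rng: np.random.Generator,
                 negative_slope: float = 0.2):
        if n_out % heads != 0:
            raise ValueError("output dim must be divisible by heads")
        self.heads = heads
        self.d_head = n_out // heads
        self.n_out = n_out
        self.negative_slope = negative_slope
        scale = np.sqrt(2.0 / n_in)
        self.Wl = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.Wr = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.att = Parameter(rng.normal(0.0, np.sqrt(2.0 / self.d_head),
                                        size=(1, heads, self.d_head)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor, edges: np.ndarray, n_nodes: int) -> Tensor:
        loops = np.arange(n_nodes, dtype=np.int64)
        src = np.concatenate([edges[0], loops])
        tgt = np.concatenate([edges[1], loops])
        gl = ad.reshape(x @ self.Wl, (n_nodes, self.heads, self.d_head))
        gr = ad.reshape(x @ self.Wr, (n_nodes, self.heads, self.d_head))
        hs = ad.gather_rows(gr, src)           # source (message) features
        ht = ad.gather_rows(gl, tgt)           # target features
        m = ad.leaky_relu(hs + ht, self.negative_slope)
        scores = ad.tsum(m * self.att, axis=2)  # (E, heads)
        alpha = ad.segment_softmax(scores, tgt, n_nodes)
        msg = hs * ad.reshape(alpha, (len(src), self.heads, 1))
        out = ad.segment_sum(msg, tgt, n_nodes)
        return ad.reshape(out, (n_nodes, self.n_out)) + self.bias

    def parameters(self):
        return [self.Wl, self.Wr, self.att, self.bias]


class Set2Set:
    """Iterative attention readout producing a 2*dim graph embedding."""

    def __init__(self, dim: int, steps: int, rng: np.random.Generator):
        self.dim = dim
        self.steps = steps
        scale = np.sqrt(1.0 / (2 * dim))
        self.Wx = Parameter(rng.normal(0.0, scale, size=(2 * dim, 4 * dim)))
        self.Wh = Parameter(rng.normal(0.0, scale, size=(dim, 4 * dim)))
        self.b = Parameter(np.zeros(4 * dim))

    def __call__(self, x: Tensor, batch_idx: np.ndarray, n_graphs: int) -> Tensor:
        d = self.dim
        q = Tensor(np.zeros((n_graphs, d)))
        c = Tensor(np.zeros((n_graphs, d)))
        q_star = Tensor(np.zeros((n_graphs, 2 * d)))
        for _ in range(self.steps):
            gates = q_star @ self.Wx + q @ self.Wh + self.b
            i = ad.sigmoid(ad.narrow(gates, 1, 0, d))
            f = ad.sigmoid(ad.narrow(gates, 1, d, d))
            g = ad.tanh(ad.narrow(gates, 1, 2 * d, d))
            o = ad.sigmoid(ad.narrow(gates, 1, 3 * d, d))
            c = f * c + i * g
            q = o * ad.tanh(c)
            e = ad.tsum(x * ad.gather_rows(q, batch_idx), axis=1)  # (N,)
            a = ad.segment_softmax(e, batch_idx, n_graphs)
            r = ad.segment_sum(x * ad.reshape(a, (-1, 1)), batch_idx, n_graphs)
            q_star = ad.concat([q, r], axis=1)
        return q_star

    def parameters(self):
        return [self.Wx, self.Wh, self.b]


class MLPHead:
    """Three-layer fully connected task head ending in one logit."""

    def __init__(self, n_in: int, hidden: Sequence[int], dropout: float,
                 rng: np.random.Generator):
        self.linears: list[Linear] = []
        self.bns: list[BatchNorm1d] = []
        prev = n_in
        for h in hidden:
            self.linears.append(Linear(prev, h, rng))
            self.bns.append(BatchNorm1d(h))
            prev = h
        self.out = Linear(prev, 1, rng)
        self.drop = Dropout(dropout)
        self.frozen = False  # freezes batch-norm stats and dropout

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        training = training and not self.frozen
        for lin, bn in zip(self.linears, self.bns):
            x = self.drop(bn(ad.relu(lin(x)), training), training, rng)
        return self.out(x)

    def parameters(self):
        ps = []
        for lin in self.linears:
            ps += lin.parameters()
        for bn in self.bns:
            ps += bn.parameters()
        return ps + self.out.parameters()

    def batchnorms(self):
        return list(self.bns)


# ---------------------------------------------------------------------------
# batching


@dataclass
class GraphBatch:
    node_features: np.ndarray  # (N, 7)
    edges: np.ndarray          # (2, E) with node offsets applied
    batch_idx: np.ndarray      # (N,)
    n_graphs: int


def make_batch(graphs: Sequence[PeptideGraph]) -> GraphBatch:
    feats, edges, batch_idx = [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        feats.append(g.node_features)
        edges.append(g.edges + offset)
        batch_idx.append(np.full(g.length, gi, dtype=np.int64))
        offset += g.length
    return GraphBatch(
        node_features=np.concatenate(feats, axis=0),
        edges=np.concatenate(edges, axis=1) if edges else np.zeros((2, 0), np.int64),
        batch_idx=np.concatenate(batch_idx),
        n_graphs=len(graphs),
    )


# ---------------------------------------------------------------------------
# model


class GATNet:
    """The shared-encoder, multi-head peptide activity classifier."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        c = config
        self.convs = [GATv2Conv(c.in_dim if i == 0 else c.hidden_dim,
                                c.hidden_dim, c.n_heads, rng)
                      for i in range(c.n_layers)]
        self.conv_bns = [BatchNorm1d(c.hidden_dim) for _ in range(c.n_layers)]
        self.drop = Dropout(c.dropout)
        self.set2set = Set2Set(c.hidden_dim, c.set2set_steps, rng)
        self.proj = Linear(2 * c.hidden_dim, c.repr_dim, rng)
        self.proj_bn = BatchNorm1d(c.repr_dim)
        self.heads = {r: MLPHead(c.repr_dim, c.head_hidden, c.dropout, rng)
                      for r in c.receptors}
        self.training = True
        self.encoder_frozen = False

    # -- modes ------------------------------------------------------------
    def train(self):
        self.training = True
        return self

    def eval(self):
        self.training = False
        return self

    def freeze_encoder(self, frozen: bool = True):
        """Freeze encoder weights, batch-norm statistics and dropout."""
        self.encoder_frozen = frozen
        return self

    def set_trainable_heads(self, receptors: Sequence[str]):
        """Freeze batch-norm/dropout of every head not in ``receptors``."""
        for r, head in self.heads.items():
            head.frozen = r not in receptors
        return self

    # -- parameter groups --------------------------------------------------
    def encoder_parameters(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for conv in self.convs:
            ps += conv.parameters()
        for bn in self.conv_bns:
            ps += bn.parameters()
        ps += self.set2set.parameters()
        ps += self.proj.parameters()
        ps += self.proj_bn.parameters()
        return ps

    def head_parameters(self, receptor: str) -> list[Parameter]:
        return self.heads[receptor].parameters()

    def parameters(self) -> list[Parameter]:
        ps = self.encoder_parameters()
        for r in self.config.receptors:
            ps += self.head_parameters(r)
        return ps

    # -- forward ------------------------------------------------------------
    def forward(self, batch: GraphBatch) -> Tensor:
        """Logits (n_graphs, n_receptors)."""
        enc_training = self.training and not self.encoder_frozen
        n = batch.node_features.shape[0]
        x = Tensor(batch.node_features)
        for i, (conv, bn) in enumerate(zip(self.convs, self.conv_bns)):
            x_in = x
            h = conv(x, batch.edges, n)
            h = ad.relu(h)
            h = bn(h, enc_training)
            h = self.drop(h, enc_training, self._dropout_rng)
            # identity residual after every second layer
            if i % 2 == 1 and h.shape == x_in.shape:
                h = h + x_in
            x = h
        pooled = self.set2set(x, batch.batch_idx, batch.n_graphs)
        rep = self.proj(pooled)
        rep = ad.relu(rep)
        rep = self.proj_bn(rep, enc_training)
        rep = self.drop(rep, enc_training, self._dropout_rng)
        logits = [self.heads[r](rep, self.training, self._dropout_rng)
                  for r in self.config.receptors]
        return ad.concat(logits, axis=1)

    def predict_proba(self, graphs: Sequence[PeptideGraph]) -> np.ndarray:
        """Deterministic evaluation-mode probabilities, shape (B, n_receptors)."""
        was_training = self.training
        self.eval()
        try:
            with ad.no_grad():
                logits = self.forward(make_batch(graphs))
                probs = 1.0 / (1.0 + np.exp(-logits.data))
        finally:
            self.training = was_training
        eps = 1e-6
        return np.clip(probs, eps, 1 - eps)

    # -- state --------------------------------------------------------------
    def _named_state(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, conv in enumerate(self.convs):
            for name, p in zip(("Wl", "Wr", "att", "bias"), conv.parameters()):
                out[f"conv{i}.{name}"] = p.data
        for i, bn in enumerate(self.conv_bns):
            out[f"conv_bn{i}.gamma"] = bn.gamma.data
            out[f"conv_bn{i}.beta"] = bn.beta.data
            out[f"conv_bn{i}.running_mean"] = bn.running_mean
            out[f"conv_bn{i}.running_var"] = bn.running_var
        for name, p in zip(("Wx", "Wh", "b"), self.set2set.parameters()):
            out[f"set2set.{name}"] = p.data
        out["proj.W"], out["proj.b"] = self.proj.W.data, self.proj.b.data
        out["proj_bn.gamma"] = self.proj_bn.gamma.data
        out["proj_bn.beta"] = self.proj_bn.beta.data
        out["proj_bn.running_mean"] = self.proj_bn.running_mean
        out["proj_bn.running_var"] = self.proj_bn.running_var
        for r in self.config.receptors:
            head = self.heads[r]
            for j, lin in enumerate(head.linears):
                out[f"head.{r}.lin{j}.W"] = lin.W.data
                out[f"head.{r}.lin{j}.b"] = lin.b.data
            for j, bn in enumerate(head.bns):
                out[f"head.{r}.bn{j}.gamma"] = bn.gamma.data
                out[f"head.{r}.bn{j}.beta"] = bn.beta.data
                out[f"head.{r}.bn{j}.running_mean"] = bn.running_mean
                out[f"head.{r}.bn{j}.running_var"] = bn.running_var
            out[f"head.{r}.out.W"] = head.out.W.data
            out[f"head.{r}.out.b"] = head.out.b.data
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._named_state().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        current = self._named_state()
        if set(current) != set(state):
            raise ValueError("state dict keys do not match model architecture")
        for k, v in current.items():
            v[...] = state[k]
        return self


def init_model(config: ModelConfig, seed: int = 0) -> GATNet:
    """Deterministically initialize a model from a config and seed."""
    return GATNet(config, seed=seed)


# ---------------------------------------------------------------------------
# losses


def focal_loss(p, y, alpha: float = 0.25, gamma: float = 2.0):
    """Focal loss -alpha_t (1 - p_t)^gamma log(p_t).

    ``p`` may be a float, numpy array, or autodiff Tensor of probabilities in
    (0, 1); ``y`` holds binary labels.  With gamma = 0 and alpha = 0.5 this
    reduces to 0.5 x binary cross-entropy.
    """
    is_tensor = isinstance(p, Tensor)
    p_data = p.data if is_tensor else np.asarray(p, dtype=np.float64)
    if np.any(p_data <= 0.0) or np.any(p_data >= 1.0):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    pt_ = p if is_tensor else Tensor(p_data)
    y = np.asarray(y, dtype=np.float64)
    yt = Tensor(y)
    p_t = pt_ * yt + (1.0 - pt_) * (1.0 - y)
    alpha_t = alpha * y + (1.0 - alpha) * (1.0 - y)
    loss = -Tensor(alpha_t) * (1.0 - p_t) ** gamma * ad.log(p_t)
    if is_tensor:
        return loss
    out = loss.data
    return float(out) if out.ndim == 0 else out


def multitask_loss(
    probs: Tensor,
    labels: np.ndarray,
    mask: np.ndarray,
    weights: Sequence[float],
    alpha: float = 0.25,
    gamma: float = 2.0,
) -> Tensor:
    """Weighted sum over receptors of the masked mean focal loss.

    ``labels`` (B, R) with arbitrary fill at masked positions; ``mask`` (B, R)
    True where a label exists.  Receptors without any unmasked sample (or with
    weight 0) contribute nothing.
    """
    labels = np.where(mask, labels, 0.0).astype(np.float64)
    per_sample = focal_loss(probs, labels, alpha=alpha, gamma=gamma)
    total = Tensor(0.0)
    for r in range(labels.shape[1]):
        w = float(weights[r])
        n_r = int(mask[:, r].sum())
        if w == 0.0 or n_r == 0:
            continue
        col_mask = (mask[:, r] / n_r).reshape(-1, 1)
        col = ad.narrow(per_sample, 1, r, 1)
        total = total + w * ad.tsum(col * Tensor(col_mask))
    return total


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(path: str | Path, model: GATNet, stats: NormStats) -> None:
    """Write config JSON, weights and normalization stats to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": model.config.to_dict(),
        "seed": model.seed,
        "norm_stats": stats.to_dict(),
        "stats_fingerprint": stats.fingerprint(),
    }
    (path / "config.json").write_text(json.dumps(meta, indent=2))
    np.savez(path / "weights.npz", **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[GATNet, NormStats]:
    path = Path(path)
    meta = json.loads((path / "config.json").read_text())
    model = GATNet(ModelConfig.from_dict(meta["config"]), seed=meta.get("seed", 0))
    with np.load(path / "weights.npz") as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    stats = NormStats.from_dict(meta["norm_stats"])
    if stats.fingerprint() != meta["stats_fingerprint"]:
        raise ValueError(f"checkpoint {path}: normalization stats fingerprint mismatch")
    model.eval()
    return model, stats
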