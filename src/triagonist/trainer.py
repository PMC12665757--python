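"""Three-stage transfer learning, stratified cross-validation and evaluation.

Training protocol: stage 1 fits the shared encoder plus the GCGR/GLP1R heads
on every record carrying a label for either receptor (80 epochs, lr 1e-3);
stage 2 freezes the encoder (weights, batch-norm statistics and dropout) and
trains only the GIPR head on GIPR-labelled records (100 epochs, lr 1e-3);
stage 3 unfreezes everything for unified fine-tuning at lr 1e-4 (60 epochs).
Each stage early-stops on validation loss with patience 15 and restores the
best weights seen; Adam with global-norm gradient clipping at 1.0 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from . import _autodiff as ad
from . import design_scoring
from .gatnet import (
    GATNet,
    GraphBatch,
    ModelConfig,
    make_batch,
    multitask_loss,
)
from .graphrep import NormStats, build_graph, fit_norm_stats
from .seqio import RECEPTORS, ActivityRecord, TokenSeq

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    stage1_epochs: int = 80
    stage2_epochs: int = 100
    stage3_epochs: int = 60
    lr_stage12: float = 1e-3
    lr_stage3: float = 1e-4
    patience: int = 15
    #: epochs per stage before early-stopping bookkeeping engages; the focal
    #: objective has a trivial predict-the-prior optimum at initialization
    #: that validation loss must transiently leave while features form
    warmup_epochs: int = 8
    grad_clip_norm: float = 1.0
    batch_size: int = 32
    k_folds: int = 5
    inner_split: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if min(self.stage1_epochs, self.stage2_epochs, self.stage3_epochs) <= 0:
            raise ValueError("stage epochs must be positive")
        if not 0.0 < self.inner_split < 1.0:
            raise ValueError("inner_split must be in (0, 1)")


# ---------------------------------------------------------------------------
# stratification


def make_strat_key(record: ActivityRecord, receptors: Sequence[str] = RECEPTORS) -> str:
    """Activity-state key like ``"1|0|m"`` over (GCGR, GLP1R, GIPR)."""
    parts = []
    for r in receptors:
        lab = record.label.get(r)
        parts.append("m" if lab is None else str(int(lab)))
    return "|".join(parts)


def stratified_kfold(
    records: Sequence[ActivityRecord], k: int = 5, seed: int = 0
) -> list[list[int]]:
    """Partition record indices into k folds balanced by activity-state key.

    Within each key, indices are shuffled and dealt round-robin starting at
    the currently smallest fold, so per-key counts differ by at most one
    across folds and keys rarer than k still spread out.
    """
    n = len(records)
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    by_key: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_key.setdefault(make_strat_key(rec), []).append(i)
    folds: list[list[int]] = [[] for _ in range(k)]
    for key in sorted(by_key):
        idx = by_key[key]
        rng.shuffle(idx)
        start = int(np.argmin([len(f) for f in folds]))
        for j, i in enumerate(idx):
            folds[(start + j) % k].append(i)
    return folds


def stratified_split(
    records: Sequence[ActivityRecord], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[int], list[int]]:
    """Stratified train/validation split using the same activity-state keys."""
    rng = np.random.default_rng(seed)
    by_key: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_key.setdefault(make_strat_key(rec), []).append(i)
    train_idx, val_idx = [], []
    for key in sorted(by_key):
        idx = by_key[key]
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1 if len(idx) > 1 else 1), len(idx))
        train_idx.extend(idx[:n_train])
        val_idx.extend(idx[n_train:])
    if not val_idx:  # tiny datasets: steal one record for validation
        val_idx.append(train_idx.pop())
    return sorted(train_idx), sorted(val_idx)


# ---------------------------------------------------------------------------
# label matrices


def label_matrix(
    records: Sequence[ActivityRecord], receptors: Sequence[str] = RECEPTORS
) -> tuple[np.ndarray, np.ndarray]:
    """(labels, mask) arrays of shape (n, R); masked entries are False."""
    n = len(records)
    labels = np.zeros((n, len(receptors)))
    mask = np.zeros((n, len(receptors)), dtype=bool)
    for i, rec in enumerate(records):
        for j, r in enumerate(receptors):
            lab = rec.label.get(r)
            if lab is not None:
                labels[i, j] = lab
                mask[i, j] = True
    return labels, mask


# ---------------------------------------------------------------------------
# staged training


@dataclass
class TrainResult:
    model: GATNet
    stats: NormStats
    history: list[dict] = field(default_factory=list)


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _dataset_loss(model: GATNet, batch: GraphBatch, labels, mask, weights,
                  alpha: float, gamma: float) -> float:
    was_training = model.training
    model.eval()
    try:
        with ad.no_grad():
            logits = model.forward(batch)
            probs = ad.Tensor(np.clip(1 / (1 + np.exp(-logits.data)), 1e-6, 1 - 1e-6))
            loss = multitask_loss(probs, labels, mask, weights, alpha, gamma)
    finally:
        model.training = was_training
    return float(loss.data)


def _run_stage(
    model: GATNet,
    params,
    graphs: list,
    labels: np.ndarray,
    mask: np.ndarray,
    val_batch: GraphBatch,
    val_labels: np.ndarray,
    val_mask: np.ndarray,
    weights: Sequence[float],
    epochs: int,
    lr: float,
    config: TrainConfig,
    rng: np.random.Generator,
    stage_name: str,
) -> list[dict]:
    """One training stage with early stopping; restores best-val-loss weights."""
    c = model.config
    opt = ad.Adam(params, lr=lr)
    best_val = np.inf
    best_state = model.state_dict()
    patience_left = config.patience
    history = []
    n = len(graphs)
    for epoch in range(epochs):
        model.train()
        epoch_loss, n_batches = 0.0, 0
        for idx in _epoch_batches(n, config.batch_size, rng):
            batch = make_batch([graphs[i] for i in idx])
            opt.zero_grad()
            logits = model.forward(batch)
            probs = ad.clip(ad.sigmoid(logits), 1e-6, 1 - 1e-6)
            loss = multitask_loss(probs, labels[idx], mask[idx], weights,
                                  c.focal_alpha, c.focal_gamma)
            loss.backward()
            ad.clip_grad_norm(params, config.grad_clip_norm)
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val_loss = _dataset_loss(model, val_batch, val_labels, val_mask, weights,
                                 c.focal_alpha, c.focal_gamma)
        history.append({"stage": stage_name, "epoch": epoch,
                        "train_loss": epoch_loss / max(n_batches, 1),
                        "val_loss": val_loss})
        if epoch < config.warmup_epochs:
            best_val = val_loss
            best_state = model.state_dict()
            continue
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state_dict()
            patience_left = config.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                log.info("%s: early stop at epoch %d (best val %.5f)",
                         stage_name, epoch, best_val)
                break
    model.load_state_dict(best_state)
    return history


def run_transfer_learning(
    train_records: Sequence[ActivityRecord],
    val_records: Sequence[ActivityRecord],
    config: Optional[TrainConfig] = None,
    model_config: Optional[ModelConfig] = None,
    stats: Optional[NormStats] = None,
    seed: Optional[int] = None,
) -> TrainResult:
    """Train a model with the three-stage transfer-learning protocol."""
    config = config or TrainConfig()
    model_config = model_config or ModelConfig()
    seed = config.seed if seed is None else seed
    if stats is None:
        stats = fit_norm_stats(train_records)
    rng = np.random.default_rng(seed)
    model = GATNet(model_config, seed=seed)

    receptors = model_config.receptors
    graphs = [build_graph(rec.seq, stats) for rec in train_records]
    labels, mask = label_matrix(train_records, receptors)
    val_batch = make_batch([build_graph(rec.seq, stats) for rec in val_records])
    val_labels, val_mask = label_matrix(val_records, receptors)

    r_index = {r: i for i, r in enumerate(receptors)}
    i_gipr = r_index.get("GIPR")
    gcgr_glp1 = [i for r, i in r_index.items() if r in ("GCGR", "GLP1R")]
    history: list[dict] = []

    # stage 1: encoder + GCGR/GLP1R heads on records with either label
    s1_idx = [i for i in range(len(train_records))
              if any(mask[i, j] for j in gcgr_glp1)]
    w1 = [0.0] * len(receptors)
    for j in gcgr_glp1:
        w1[j] = model_config.task_weight
    s1_params = model.encoder_parameters()
    for r in ("GCGR", "GLP1R"):
        if r in r_index:
            s1_params += model.head_parameters(r)
    if s1_idx:
        history += _run_stage(
            model, s1_params, [graphs[i] for i in s1_idx],
            labels[s1_idx], mask[s1_idx], val_batch, val_labels, val_mask,
            w1, config.stage1_epochs, config.lr_stage12, config, rng, "stage1")

    # stage 2: frozen encoder, GIPR head only
    if i_gipr is not None:
        s2_idx = [i for i in range(len(train_records)) if mask[i, i_gipr]]
        if s2_idx:
            w2 = [0.0] * len(receptors)
            w2[i_gipr] = 1.0
            model.freeze_encoder(True)
            model.set_trainable_heads(["GIPR"])
            history += _run_stage(
                model, model.head_parameters("GIPR"), [graphs[i] for i in s2_idx],
                labels[s2_idx], mask[s2_idx], val_batch, val_labels, val_mask,
                w2, config.stage2_epochs, config.lr_stage12, config, rng, "stage2")
            model.freeze_encoder(False)
            model.set_trainable_heads(receptors)
        else:
            log.warning("no GIPR-labelled training records; stage 2 skipped")

    # stage 3: unified fine-tuning at reduced learning rate
    s3_idx = [i for i in range(len(train_records)) if mask[i].any()]
    w3 = [model_config.task_weight] * len(receptors)
    history += _run_stage(
        model, model.parameters(), [graphs[i] for i in s3_idx],
        labels[s3_idx], mask[s3_idx], val_batch, val_labels, val_mask,
        w3, config.stage3_epochs, config.lr_stage3, config, rng, "stage3")

    model.eval()
    return TrainResult(model=model, stats=stats, history=history)


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class ReceptorMetrics:
    auc_roc: Optional[float]
    auc_pr: Optional[float]
    f1: float
    precision: float
    recall: float
    balanced_accuracy: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(
    probabilities: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    receptors: Sequence[str] = RECEPTORS,
    threshold: float = 0.5,
) -> dict[str, ReceptorMetrics]:
    """Per-receptor classification metrics over unmasked samples.

    AUCs are reported as None when only one class is present.
    """
    out = {}
    for j, r in enumerate(receptors):
        m = mask[:, j]
        y = labels[m, j].astype(int)
        p = probabilities[m, j]
        if len(y) == 0:
            out[r] = ReceptorMetrics(None, None, 0.0, 0.0, 0.0, 0.0, 0)
            continue
        pred = (p >= threshold).astype(int)
        two_class = len(np.unique(y)) == 2
        out[r] = ReceptorMetrics(
            auc_roc=float(roc_auc_score(y, p)) if two_class else None,
            auc_pr=float(average_precision_score(y, p)) if two_class else None,
            f1=float(f1_score(y, pred, zero_division=0)),
            precision=float(precision_score(y, pred, zero_division=0)),
            recall=float(recall_score(y, pred, zero_division=0)),
            balanced_accuracy=float(balanced_accuracy_score(y, pred)),
            n=int(len(y)),
        )
    return out


# ---------------------------------------------------------------------------
# ensembles


class EnsemblePredictor:
    """Averages probability outputs across fold models sharing one NormStats."""

    def __init__(self, members: Sequence[tuple[GATNet, NormStats]]):
        if not members:
            raise ValueError("ensemble needs at least one model")
        fps = {stats.fingerprint() for _, stats in members}
        if len(fps) != 1:
            raise ValueError("ensemble members use different normalization stats")
        self.models = [m for m, _ in members]
        self.stats = members[0][1]
        self.receptors = self.models[0].config.receptors

    def predict_proba(self, seqs: Sequence[TokenSeq]) -> np.ndarray:
        graphs = [build_graph(s, self.stats) for s in seqs]
        probs = np.mean([m.predict_proba(graphs) for m in self.models], axis=0)
        return probs


def ensemble_predict(
    members: Sequence[tuple[GATNet, NormStats]], seqs: Sequence[TokenSeq]
) -> np.ndarray:
    """Arithmetic mean of the member models' probabilities for each receptor."""
    return EnsemblePredictor(members).predict_proba(seqs)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CrossValResult:
    fold_metrics: list[dict[str, ReceptorMetrics]]
    members: list[tuple[GATNet, NormStats]]
    folds: list[list[int]]

    def mean_metric(self, receptor: str, metric: str = "auc_roc") -> float:
        vals = [getattr(fm[receptor], metric) for fm in self.fold_metrics]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else float("nan")

    def summary(self) -> dict:
        out = {}
        receptors = self.fold_metrics[0].keys()
        for r in receptors:
            out[r] = {}
            for metric in ("auc_roc", "auc_pr", "f1", "precision", "recall",
                           "balanced_accuracy"):
                vals = [getattr(fm[r], metric) for fm in self.fold_metrics]
                vals = [v for v in vals if v is not None]
                out[r][metric] = {
                    "mean": float(np.mean(vals)) if vals else None,
                    "std": float(np.std(vals)) if vals else None,
                }
        return out


def cross_validate(
    records: Sequence[ActivityRecord],
    config: Optional[TrainConfig] = None,
    model_config: Optional[ModelConfig] = None,
) -> CrossValResult:
    """Stratified k-fold cross-validation with the three-stage protocol.

    A single NormStats fitted on the full dataset is shared by fold models so
    they can act as one ensemble afterwards.
    """
    config = config or TrainConfig()
    model_config = model_config or ModelConfig()
    folds = stratified_kfold(records, k=config.k_folds, seed=config.seed)
    stats = fit_norm_stats(records)
    fold_metrics, members = [], []
    for f, test_idx in enumerate(folds):
        test_set = set(test_idx)
        pool = [records[i] for i in range(len(records)) if i not in test_set]
        tr_idx, va_idx = stratified_split(pool, config.inner_split,
                                          seed=config.seed + 1000 + f)
        result = run_transfer_learning(
            [pool[i] for i in tr_idx], [pool[i] for i in va_idx],
            config=config, model_config=model_config, stats=stats,
            seed=config.seed + f,
        )
        test_records = [records[i] for i in test_idx]
        graphs = [build_graph(rec.seq, stats) for rec in test_records]
        probs = result.model.predict_proba(graphs)
        labels, mask = label_matrix(test_records, model_config.receptors)
        fold_metrics.append(evaluate(probs, labels, mask, model_config.receptors))
        members.append((result.model, stats))
        log.info("fold %d done", f)
    return CrossValResult(fold_metrics=fold_metrics, members=members, folds=folds)


# ---------------------------------------------------------------------------
# similarity-based validation filtering


def similarity_filter(
    validation_records: Sequence[ActivityRecord],
    training_records: Sequence[ActivityRecord],
    threshold: float = 0.8,
) -> tuple[list[ActivityRecord], list[ActivityRecord], dict[str, float]]:
    """Split validation records by similarity to the training set.

    Exact sequence matches (similarity 1.0) are dropped entirely; the novel
    subset keeps records with maximum similarity <= ``threshold``.  Returns
    (novel subset, full set without exact matches, per-record max similarity).
    """
    if not validation_records or not training_records:
        raise ValueError("both record sets must be non-empty")
    train_seqs = [rec.seq for rec in training_records]
    max_sims: dict[str, float] = {}
    full, novel = [], []
    for rec in validation_records:
        ms = design_scoring.max_similarity(rec.seq, train_seqs)
        max_sims[rec.id] = ms
        if ms >= 1.0:
            continue
        full.append(rec)
        if ms <= threshold:
            novel.append(rec)
    if not novel:
        log.warning("no validation sequences below %.0f%% similarity", 100 * threshold)
    return novel, full, max_sims
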