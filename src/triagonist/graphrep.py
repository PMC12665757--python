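"""Residue-graph representation of peptides.

A peptide of L tokens becomes a chain graph with L nodes and bidirectional
backbone edges between sequential residues.  Each node carries a
7-dimensional feature vector:

0. Kyte-Doolittle hydrophobicity (z-scored over training residues)
1. side-chain net charge at physiological pH (z-scored)
2. residue molecular weight (z-scored)
3. D-amino-acid indicator (0/1)
4. lipidation indicator (0/1)
5. sin(pi * pos / L) positional encoding (pos 0-based)
6. cos(pi * pos / L) positional encoding

Normalization statistics are fitted once on the training set (pooled over all
residues) and frozen for prediction.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from . import physchem
from .seqio import ActivityRecord, TokenSeq, is_d_residue, is_lipidated

N_FEATURES = 7


@dataclass(frozen=True)
class NormStats:
    """Per-channel mean/std for the three physicochemical node features."""

    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    def fingerprint(self) -> str:
        payload = json.dumps([self.mean, self.std], sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {"mean": list(self.mean), "std": list(self.std)}

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(mean=tuple(d["mean"]), std=tuple(d["std"]))


@dataclass(frozen=True)
class PeptideGraph:
    """Chain graph of one peptide: L x 7 node features + directed edge list."""

    node_features: np.ndarray  # (L, 7) float64
    edges: np.ndarray          # (2, 2(L-1)) int64, row 0 = source, row 1 = target
    length: int

    def to_json(self, stats: Optional[NormStats] = None) -> str:
        return json.dumps({
            "nodes": self.node_features.tolist(),
            "edges": self.edges.tolist(),
            "stats_fingerprint": stats.fingerprint() if stats else None,
        })


def _raw_channels(token: str) -> tuple[float, float, float]:
    return (
        physchem.token_kd(token),
        physchem.token_charge_ph7(token),
        physchem.token_mass(token),
    )


def fit_norm_stats(records: Iterable[ActivityRecord] | Sequence[TokenSeq]) -> NormStats:
    """Fit per-channel mean/std over every residue of the training set.

    Degenerate channels (zero variance) fall back to std 1.0.
    """
    rows = []
    for item in records:
        seq = item.seq if isinstance(item, ActivityRecord) else item
        for t in seq:
            rows.append(_raw_channels(t))
    if not rows:
        raise ValueError("cannot fit normalization statistics on an empty dataset")
    arr = np.asarray(rows, dtype=np.float64)
    mean = arr.mean(axis=0)
    std = arr.std(axis=0)
    std = np.where(std > 1e-12, std, 1.0)
    return NormStats(mean=tuple(mean.tolist()), std=tuple(std.tolist()))


def residue_features(token: str, pos: int, length: int, stats: NormStats) -> np.ndarray:
    """7-vector of node features for one residue token at 0-based position."""
    if not 0 <= pos < length:
        raise ValueError(f"position {pos} outside [0, {length})")
    raw = np.asarray(_raw_channels(token))
    z = (raw - np.asarray(stats.mean)) / np.asarray(stats.std)
    angle = math.pi * pos / length
    return np.array([
        z[0], z[1], z[2],
        1.0 if is_d_residue(token) else 0.0,
        1.0 if is_lipidated(token) else 0.0,
        math.sin(angle), math.cos(angle),
    ])


def build_graph(seq: TokenSeq, stats: NormStats) -> PeptideGraph:
    """Build the chain graph for one peptide (node order = token order)."""
    L = len(seq)
    feats = np.empty((L, N_FEATURES), dtype=np.float64)
    raw = np.asarray([_raw_channels(t) for t in seq])
    feats[:, 0:3] = (raw - np.asarray(stats.mean)) / np.asarray(stats.std)
    feats[:, 3] = [1.0 if is_d_residue(t) else 0.0 for t in seq]
    feats[:, 4] = [1.0 if is_lipidated(t) else 0.0 for t in seq]
    pos = np.arange(L)
    feats[:, 5] = np.sin(np.pi * pos / L)
    feats[:, 6] = np.cos(np.pi * pos / L)
    if L > 1:
        fwd = np.stack([pos[:-1], pos[1:]])
        edges = np.concatenate([fwd, fwd[::-1]], axis=1).astype(np.int64)
    else:
        edges = np.zeros((2, 0), dtype=np.int64)
    if not np.all(np.isfinite(feats)):
        raise ValueError(f"non-finite node features for sequence {seq.text!r}")
    return PeptideGraph(node_features=feats, edges=edges, length=L)


def build_graphs(seqs: Sequence[TokenSeq], stats: NormStats) -> list[PeptideGraph]:
    return [build_graph(s, stats) for s in seqs]
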