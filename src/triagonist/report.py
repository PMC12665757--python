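"""Candidate characterization reports and summary statistics.

A report row holds, per designed candidate: the sequence, predicted
per-receptor activities, the highest similarity to any training sequence
(with the best-match ID), and the physicochemical profile (molecular weight,
pI, instability index, GRAVY, estimated logP, estimated PSA).  A bundled
reference panel of 20 designed candidates with published predicted
activities and properties ships with the package as a golden fixture and
demo input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import design_scoring, physchem
from .seqio import RECEPTORS, ActivityRecord, TokenSeq, tokenize

REPORT_COLUMNS = [
    "sequence", "GCGR_activity", "GLP1R_activity", "GIPR_activity",
    "highest_similarity", "best_match_id", "mol_weight", "isoelectric",
    "instability_index", "gravy", "estimated_logP", "estimated_PSA",
]


@dataclass
class CandidateReport:
    sequence: str
    activities: dict[str, Optional[float]]
    highest_similarity: Optional[float]
    best_match_id: Optional[str]
    mol_weight: float
    isoelectric: float
    instability_index: float
    gravy: float
    estimated_logP: float
    estimated_PSA: float

    def to_row(self) -> dict:
        row = {"sequence": self.sequence}
        for r in RECEPTORS:
            row[f"{r}_activity"] = self.activities.get(r)
        row.update({
            "highest_similarity": self.highest_similarity,
            "best_match_id": self.best_match_id,
            "mol_weight": self.mol_weight,
            "isoelectric": self.isoelectric,
            "instability_index": self.instability_index,
            "gravy": self.gravy,
            "estimated_logP": self.estimated_logP,
            "estimated_PSA": self.estimated_PSA,
        })
        return row


def build_report(
    candidates: Sequence[TokenSeq],
    predictor=None,
    training_records: Sequence[ActivityRecord] = (),
) -> list[CandidateReport]:
    """One report row per candidate, sorted by descending mean predicted activity.

    Without a predictor the activity columns stay empty; without training
    records the similarity columns stay empty.
    """
    probs = predictor.predict_proba(list(candidates)) if predictor else None
    rows = []
    for i, seq in enumerate(candidates):
        profile = physchem.compute_properties(seq)
        activities: dict[str, Optional[float]] = {r: None for r in RECEPTORS}
        if probs is not None:
            activities = {r: float(probs[i, j]) for j, r in enumerate(RECEPTORS)}
        best_sim, best_id = None, None
        if training_records:
            for rec in training_records:
                s = design_scoring.similarity(seq, rec.seq)
                if best_sim is None or s > best_sim:
                    best_sim, best_id = s, rec.id
        rows.append(CandidateReport(
            sequence=seq.text,
            activities=activities,
            highest_similarity=best_sim,
            best_match_id=best_id,
            mol_weight=profile.mol_weight,
            isoelectric=profile.isoelectric,
            instability_index=profile.instability_index,
            gravy=profile.gravy,
            estimated_logP=profile.est_logP,
            estimated_PSA=profile.est_psa,
        ))
    if probs is not None:
        rows.sort(key=lambda r: -float(np.mean([v for v in r.activities.values()
                                                if v is not None])))
    return rows


def report_to_dataframe(report: Sequence[CandidateReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in report], columns=REPORT_COLUMNS)


def summarize_report(
    report: Sequence[CandidateReport],
    motifs: Sequence[str] = ("EGTF",),
) -> dict:
    """Mean/sd summary of lengths, properties and activities plus motif counts."""
    if not report:
        raise ValueError("cannot summarize an empty report")
    seqs = [tokenize(r.sequence) for r in report]
    lengths = np.array([len(s) for s in seqs], dtype=float)

    def mean_sd(values):
        vals = np.array([v for v in values if v is not None], dtype=float)
        if len(vals) == 0:
            return {"mean": None, "sd": None}
        return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}

    summary = {
        "n_candidates": len(report),
        "length": {**mean_sd(lengths), "min": int(lengths.min()),
                   "max": int(lengths.max())},
        "properties": {
            key: mean_sd(getattr(r, key) for r in report)
            for key in ("mol_weight", "isoelectric", "instability_index",
                        "gravy", "estimated_logP", "estimated_PSA")
        },
        "activities": {
            r: mean_sd(row.activities.get(r) for row in report)
            for r in RECEPTORS
        },
        "similarity": mean_sd(r.highest_similarity for r in report),
        "motif_counts": {
            m: design_scoring.count_motif_occurrences(seqs, m) for m in motifs
        },
    }
    return summary


def write_report(report: Sequence[CandidateReport], path: str | Path) -> None:
    """Write the report CSV plus a full-precision JSON twin next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = report_to_dataframe(report)
    df.to_csv(path, index=False, float_format="%.6g")
    path.with_suffix(".json").write_text(
        json.dumps([asdict(r) for r in report], indent=2))


def reference_candidates() -> pd.DataFrame:
    """The packaged 20-candidate reference panel (sequences + printed values)."""
    with resources.as_file(
        resources.files("triagonist.data") / "reference_candidates.csv"
    ) as p:
        return pd.read_csv(p)


def reference_candidate_seqs() -> list[TokenSeq]:
    return [tokenize(s) for s in reference_candidates()["sequence"]]
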