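"""Scoring components for evolutionary peptide design.

Covers token-level sequence similarity (normalized Levenshtein), novelty
against a training set, position-anchored motif preservation, the weighted
biological-plausibility score

    B = 0.3 C + 0.35 M + 0.2 P + 0.15 A   (candidates require B >= 0.3)

with C = chemical constraints (net charge window, hydrophobic patches,
compositional dominance), M = motif preservation, P = proteolytic stability
(trypsin/chymotrypsin cleavage-site density) and A = amino-acid composition
similarity to the native hormones, plus population diversity tracking.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import yaml

from . import physchem
from .seqio import STANDARD_AA, TokenSeq, read_fasta

#: Standard physicochemical substitution classes used for conservative credit.
CONSERVATIVE_GROUPS = (
    frozenset("AVLIM"), frozenset("FWY"), frozenset("ST"), frozenset("DE"),
    frozenset("KRH"), frozenset("NQ"), frozenset("G"), frozenset("P"),
    frozenset("C"),
)

_GROUP_OF = {aa: g for g in CONSERVATIVE_GROUPS for aa in g}


def same_conservative_group(a: str, b: str) -> bool:
    return _GROUP_OF.get(a) is _GROUP_OF.get(b) and a in _GROUP_OF


# ---------------------------------------------------------------------------
# similarity / novelty

_TOKEN_CODES: dict[str, str] = {}


def _encode(seq: TokenSeq) -> str:
    """Map tokens to single private-use-area characters so NSAA compare atomically."""
    out = []
    for t in seq:
        code = _TOKEN_CODES.get(t)
        if code is None:
            code = chr(0xE000 + len(_TOKEN_CODES))
            _TOKEN_CODES[t] = code
        out.append(code)
    return "".join(out)


def levenshtein_tokens(a: TokenSeq, b: TokenSeq) -> int:
    """Token-level Levenshtein distance (NSAA tokens are atomic symbols)."""
    return edlib.align(_encode(a), _encode(b), task="distance")["editDistance"]


def similarity(a: TokenSeq, b: TokenSeq) -> float:
    """Normalized similarity: 1 - levenshtein / max(|a|, |b|); in [0, 1]."""
    return 1.0 - levenshtein_tokens(a, b) / max(len(a), len(b))


def max_similarity(seq: TokenSeq, references: Sequence[TokenSeq]) -> float:
    if not references:
        raise ValueError("reference set is empty")
    return max(similarity(seq, r) for r in references)


def novelty_score(
    seq: TokenSeq,
    training_set: Sequence[TokenSeq],
    penalty_threshold: float = 0.8,
    penalty: float = 0.2,
) -> float:
    """N = 1 - max similarity, with an extra penalty above 80% similarity."""
    ms = max_similarity(seq, training_set)
    n = 1.0 - ms
    if ms > penalty_threshold:
        n = max(0.0, n - penalty)
    return n


def diversity_score(
    seq: TokenSeq,
    population_sample: Sequence[TokenSeq],
    max_sample: int = 20,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Mean dissimilarity of ``seq`` to up to ``max_sample`` population members."""
    sample = list(population_sample)
    if not sample:
        raise ValueError("population sample is empty")
    if len(sample) > max_sample:
        if rng is not None:
            idx = rng.choice(len(sample), size=max_sample, replace=False)
            sample = [sample[i] for i in idx]
        else:
            sample = sample[:max_sample]
    return float(np.mean([1.0 - similarity(seq, other) for other in sample]))


# ---------------------------------------------------------------------------
# motifs


@dataclass(frozen=True)
class MotifSpec:
    """Expected residues anchored at positions of a native hormone frame.

    ``frame`` is ``"n"`` (1-based from the N-terminus) or ``"c"`` (1-based
    from the C-terminus, 1 = last residue).  Up to ``wildcard`` mismatches are
    forgiven; a same-class substitution earns ``conservative_credit``.
    """

    name: str
    positions: tuple[tuple[int, str], ...]  # sorted (position, residue)
    frame: str = "n"
    wildcard: int = 1
    conservative_credit: float = 0.5

    def __post_init__(self):
        if self.frame not in ("n", "c"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if not 0.0 <= self.conservative_credit <= 1.0:
            raise ValueError("conservative_credit must be in [0, 1]")

    def anchor_indices(self, length: int) -> list[tuple[int, str]]:
        """0-based sequence indices of the anchors that fall inside ``length``."""
        out = []
        for pos, res in self.positions:
            idx = pos - 1 if self.frame == "n" else length - pos
            if 0 <= idx < length:
                out.append((idx, res))
        return out


def load_motifs(path: Optional[str | Path] = None) -> list[MotifSpec]:
    """Load motif specs from YAML (defaults to the packaged motif table)."""
    if path is None:
        with resources.as_file(resources.files("triagonist.data") / "motifs.yaml") as p:
            text = Path(p).read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    motifs = []
    for m in raw["motifs"]:
        positions = tuple(sorted((int(k), str(v)) for k, v in m["positions"].items()))
        motifs.append(MotifSpec(
            name=m["name"],
            positions=positions,
            frame=m.get("frame", "n"),
            wildcard=int(m.get("wildcard", 1)),
            conservative_credit=float(m.get("conservative_credit", 0.5)),
        ))
    return motifs


_PACKAGED_MOTIFS: Optional[list[MotifSpec]] = None


def default_motifs() -> list[MotifSpec]:
    global _PACKAGED_MOTIFS
    if _PACKAGED_MOTIFS is None:
        _PACKAGED_MOTIFS = load_motifs()
    return _PACKAGED_MOTIFS


def single_motif_score(seq: TokenSeq, motif: MotifSpec) -> float:
    """Fraction of anchored positions matched, after wildcard forgiveness."""
    letters = seq.base_letters()
    credits = []
    n_total = len(motif.positions)
    inside = motif.anchor_indices(len(seq))
    # anchors beyond the sequence end count as plain mismatches
    credits.extend([0.0] * (n_total - len(inside)))
    for idx, expected in inside:
        actual = letters[idx]
        if actual == expected:
            credits.append(1.0)
        elif same_conservative_group(actual, expected):
            credits.append(motif.conservative_credit)
        else:
            credits.append(0.0)
    credits.sort()
    forgiven = 0
    for _ in range(motif.wildcard):
        if credits and credits[0] < 1.0:
            credits.pop(0)
            forgiven += 1
    kept = n_total - forgiven
    if kept <= 0:
        return 1.0
    return sum(credits) / kept


def motif_score(seq: TokenSeq, motif_specs: Optional[Sequence[MotifSpec]] = None) -> float:
    """Mean preservation score over the motif set."""
    specs = default_motifs() if motif_specs is None else list(motif_specs)
    if not specs:
        return 1.0
    return float(np.mean([single_motif_score(seq, m) for m in specs]))


def count_motif_occurrences(seqs: Iterable[TokenSeq], motif: str) -> int:
    """Number of sequences whose base-letter string contains ``motif`` contiguously."""
    if len(motif) < 2:
        raise ValueError("motif must have length >= 2")
    return sum(1 for s in seqs if motif in s.base_letters())


# ---------------------------------------------------------------------------
# native hormone references

_NATIVES: Optional[dict[str, TokenSeq]] = None


def native_hormones() -> dict[str, TokenSeq]:
    """The packaged native references: glucagon, GLP-1(7-36), GIP(1-42)."""
    global _NATIVES
    if _NATIVES is None:
        with resources.as_file(
            resources.files("triagonist.data") / "native_hormones.fasta"
        ) as p:
            _NATIVES = dict(read_fasta(p))
    return _NATIVES


def _composition(letters: str) -> np.ndarray:
    order = sorted(STANDARD_AA)
    counts = np.array([letters.count(a) for a in order], dtype=np.float64)
    return counts / max(counts.sum(), 1.0)


_NATIVE_COMPOSITION: Optional[np.ndarray] = None


def native_composition() -> np.ndarray:
    """Mean residue-frequency vector of the three native hormones."""
    global _NATIVE_COMPOSITION
    if _NATIVE_COMPOSITION is None:
        comps = [_composition(s.base_letters()) for s in native_hormones().values()]
        _NATIVE_COMPOSITION = np.mean(comps, axis=0)
    return _NATIVE_COMPOSITION


# ---------------------------------------------------------------------------
# plausibility components


def chemical_constraint_score(seq: TokenSeq) -> float:
    """Mean of three rule passes: charge window, hydrophobic patch, dominance.

    Rules: net charge at pH 7 in [-6, +2]; longest hydrophobic run <= 5
    (hydrophobic = positive Kyte-Doolittle value); no residue exceeding 30%
    of the composition.
    """
    charge_ok = -6.0 <= physchem.net_charge(seq, 7.0) <= 2.0
    run, longest = 0, 0
    for t in seq:
        if physchem.token_kd(t) > 0:
            run += 1
            longest = max(longest, run)
        else:
            run = 0
    patch_ok = longest <= 5
    letters = seq.base_letters()
    dominance_ok = max(letters.count(a) for a in set(letters)) <= 0.3 * len(letters)
    return float(np.mean([charge_ok, patch_ok, dominance_ok]))


def proteolytic_stability_score(seq: TokenSeq) -> float:
    """P = 1 - cleavage sites / (L - 1).

    Trypsin cleaves after K/R, chymotrypsin after F/Y/W, both blocked by a
    following proline.
    """
    letters = seq.base_letters()
    if len(letters) < 2:
        return 1.0
    sites = 0
    for i in range(len(letters) - 1):
        if letters[i] in "KRFYW" and letters[i + 1] != "P":
            sites += 1
    return 1.0 - sites / (len(letters) - 1)


def composition_score(seq: TokenSeq) -> float:
    """A = 1 - total-variation distance to the mean native hormone composition."""
    p = _composition(seq.base_letters())
    q = native_composition()
    return 1.0 - 0.5 * float(np.abs(p - q).sum())


@dataclass(frozen=True)
class PlausibilityResult:
    """The four biological-plausibility components and their weighted total."""

    c_chem: float
    m_motif: float
    p_stab: float
    a_comp: float
    b_total: float
    pass_flag: bool


PLAUSIBILITY_WEIGHTS = (0.3, 0.35, 0.2, 0.15)
PLAUSIBILITY_THRESHOLD = 0.3


def plausibility(
    seq: TokenSeq,
    motif_specs: Optional[Sequence[MotifSpec]] = None,
    threshold: float = PLAUSIBILITY_THRESHOLD,
) -> PlausibilityResult:
    """Weighted plausibility B = 0.3 C + 0.35 M + 0.2 P + 0.15 A; pass if B >= 0.3."""
    c = chemical_constraint_score(seq)
    m = motif_score(seq, motif_specs)
    p = proteolytic_stability_score(seq)
    a = composition_score(seq)
    wc, wm, wp, wa = PLAUSIBILITY_WEIGHTS
    b = wc * c + wm * m + wp * p + wa * a
    return PlausibilityResult(c, m, p, a, b, b >= threshold)
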