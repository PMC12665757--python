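"""Peptide sequence and activity-table I/O.

Sequences are handled as :class:`TokenSeq` objects: ordered lists of residue
tokens where each token is either one of the 20 standard amino-acid letters or
a bracketed non-standard amino-acid (NSAA) token such as ``[dS]`` (D-serine)
or ``[K (yE-C16)]`` (a lipidated lysine).  The first letter inside a bracket
(after an optional lower-case ``d`` marking a D-enantiomer) names the base
residue; the remainder of the bracket payload is preserved verbatim.

Activity tables are CSV files with columns ``id``, ``sequence`` and one
``EC50_<receptor>`` column per receptor (values in pM, blank = not measured).
Binary high-affinity labels are derived from EC50 with a 1000 pM threshold.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

log = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

RECEPTORS = ("GCGR", "GLP1R", "GIPR")

#: EC50 threshold (pM) separating the high-affinity positive class.
DEFAULT_EC50_THRESHOLD_PM = 1000.0

MISSING = None


class SequenceParseError(ValueError):
    """Raised when a raw sequence string cannot be tokenized."""


@dataclass(frozen=True)
class TokenSeq:
    """An ordered, immutable list of residue tokens."""

    tokens: tuple[str, ...]

    def __post_init__(self):
        if len(self.tokens) == 0:
            raise SequenceParseError("empty sequence")
        for i, t in enumerate(self.tokens):
            if len(t) == 1:
                if t not in STANDARD_AA:
                    raise SequenceParseError(f"illegal residue letter {t!r} at token {i}")
            else:
                if not (t.startswith("[") and t.endswith("]")):
                    raise SequenceParseError(f"malformed token {t!r} at token {i}")
                base_residue(t)  # validates the base letter

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def __getitem__(self, i):
        return self.tokens[i]

    @property
    def text(self) -> str:
        return detokenize(self)

    def base_letters(self) -> str:
        """The sequence with every NSAA collapsed to its base residue letter."""
        return "".join(base_residue(t) for t in self.tokens)


def base_residue(token: str) -> str:
    """Base residue letter of a token (``[dS]`` → ``S``, ``A`` → ``A``)."""
    if len(token) == 1:
        if token not in STANDARD_AA:
            raise SequenceParseError(f"illegal residue letter {token!r}")
        return token
    inner = token[1:-1].strip()
    if inner[:1] == "d" and len(inner) >= 2 and inner[1].upper() in STANDARD_AA:
        return inner[1].upper()
    for ch in inner:
        if ch.upper() in STANDARD_AA and ch.isalpha():
            return ch.upper()
    raise SequenceParseError(f"no valid base residue in NSAA token {token!r}")


def is_d_residue(token: str) -> bool:
    """True for bracketed D-enantiomer tokens like ``[dA]``."""
    if len(token) == 1:
        return False
    inner = token[1:-1].strip()
    return inner[:1] == "d" and len(inner) >= 2 and inner[1].upper() in STANDARD_AA


def is_lipidated(token: str) -> bool:
    """True for bracket tokens whose payload carries an acyl-chain code (C12, C16, C20DA...)."""
    if len(token) == 1:
        return False
    import re

    return re.search(r"C\d{2}", token) is not None


def tokenize(raw: str) -> TokenSeq:
    """Parse a raw sequence string into a :class:`TokenSeq`.

    Whitespace outside brackets is ignored; bracket payloads are preserved
    verbatim.  A standard letter immediately preceding ``[(`` is folded into
    the bracket token (``K [(yE-C16)]`` and ``[K (yE-C16)]`` parse identically).
    """
    if not raw or not raw.strip():
        raise SequenceParseError("empty sequence string")
    tokens: list[str] = []
    i, n = 0, len(raw)
    while i < n:
        ch = raw[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "[":
            j = raw.find("]", i)
            if j < 0:
                raise SequenceParseError(f"unbalanced '[' at position {i}")
            tokens.append(raw[i : j + 1])
            i = j + 1
        elif ch == "]":
            raise SequenceParseError(f"unbalanced ']' at position {i}")
        elif ch.upper() in STANDARD_AA and ch.isupper():
            # fold "K [(payload)]" into "[K (payload)]"
            k = i + 1
            while k < n and raw[k].isspace():
                k += 1
            if k < n and raw[k] == "[" and k + 1 < n and raw[k + 1] == "(":
                j = raw.find("]", k)
                if j < 0:
                    raise SequenceParseError(f"unbalanced '[' at position {k}")
                tokens.append(f"[{ch} {raw[k + 1 : j]}]")
                i = j + 1
            else:
                tokens.append(ch)
                i += 1
        else:
            raise SequenceParseError(f"illegal character {ch!r} at position {i}")
    return TokenSeq(tuple(tokens))


def detokenize(seq: TokenSeq) -> str:
    """Inverse of :func:`tokenize`: concatenation of the tokens."""
    return "".join(seq.tokens)


def label_from_ec50(
    ec50_pm: Optional[float],
    threshold_pm: float = DEFAULT_EC50_THRESHOLD_PM,
    strict: bool = True,
) -> Optional[int]:
    """Binary high-affinity label from an EC50 in pM.

    ``strict=True`` labels EC50 < threshold as positive and EC50 >= threshold
    as negative (the evaluation convention); ``strict=False`` uses <=.
    Missing EC50 propagates as ``None``.
    """
    if ec50_pm is None:
        return None
    if ec50_pm < 0:
        raise ValueError(f"negative EC50: {ec50_pm}")
    if strict:
        return 1 if ec50_pm < threshold_pm else 0
    return 1 if ec50_pm <= threshold_pm else 0


@dataclass
class ActivityRecord:
    """One peptide with per-receptor EC50 values (pM) and derived labels."""

    id: str
    seq: TokenSeq
    ec50: dict[str, Optional[float]] = field(default_factory=dict)
    label: dict[str, Optional[int]] = field(default_factory=dict)
    c_term_amidated: bool = False

    @classmethod
    def from_ec50(
        cls,
        id: str,
        seq: TokenSeq,
        ec50: dict[str, Optional[float]],
        threshold_pm: float = DEFAULT_EC50_THRESHOLD_PM,
        strict: bool = True,
        c_term_amidated: bool = False,
    ) -> "ActivityRecord":
        labels = {r: label_from_ec50(v, threshold_pm, strict) for r, v in ec50.items()}
        return cls(id=id, seq=seq, ec50=dict(ec50), label=labels,
                   c_term_amidated=c_term_amidated)


def read_activity_table(
    path: str | Path,
    receptors: Sequence[str] = RECEPTORS,
    threshold_pm: float = DEFAULT_EC50_THRESHOLD_PM,
    strict: bool = True,
) -> list[ActivityRecord]:
    """Read an activity CSV into validated records with derived labels."""
    path = Path(path)
    records: list[ActivityRecord] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "sequence"} | {f"EC50_{r}" for r in receptors}
        missing_cols = required - set(reader.fieldnames or [])
        if missing_cols:
            raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
        for rownum, row in enumerate(reader, start=2):
            rid = row["id"].strip()
            if rid in seen:
                raise ValueError(f"{path}: duplicate id {rid!r} at row {rownum}")
            seen.add(rid)
            try:
                seq = tokenize(row["sequence"])
            except SequenceParseError as e:
                raise SequenceParseError(f"{path} row {rownum} (id {rid!r}): {e}") from e
            ec50 = {}
            for r in receptors:
                cell = (row.get(f"EC50_{r}") or "").strip()
                ec50[r] = float(cell) if cell else None
            records.append(
                ActivityRecord.from_ec50(rid, seq, ec50, threshold_pm, strict)
            )
    for r in receptors:
        n = sum(rec.label.get(r) is not None for rec in records)
        pos = sum(rec.label.get(r) == 1 for rec in records)
        log.info("%s: %d labelled records (%d positive)", r, n, pos)
    return records


def write_activity_table(
    records: Iterable[ActivityRecord],
    path: str | Path,
    receptors: Sequence[str] = RECEPTORS,
) -> None:
    """Write records back to the activity CSV schema (blank = missing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "sequence"] + [f"EC50_{r}" for r in receptors])
        for rec in records:
            row = [rec.id, rec.seq.text]
            for r in receptors:
                v = rec.ec50.get(r)
                row.append("" if v is None else repr(float(v)))
            writer.writerow(row)


def read_fasta(path: str | Path) -> list[tuple[str, TokenSeq]]:
    """Read a FASTA file; NSAA bracket tokens may appear inline on sequence lines."""
    path = Path(path)
    entries: list[tuple[str, TokenSeq]] = []
    name, chunks = None, []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    entries.append((name, tokenize("".join(chunks))))
                name, chunks = line[1:].split()[0], []
            elif line.strip():
                chunks.append(line)
    if name is not None:
        entries.append((name, tokenize("".join(chunks))))
    return entries


def write_fasta(entries: Iterable[tuple[str, TokenSeq]], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq.text}\n")
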