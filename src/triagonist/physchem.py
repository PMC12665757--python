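"""Sequence-level physicochemical profiling of peptide candidates.

Molecular weight, isoelectric point (Bjellqvist pKa set, charge-balance
bisection), Guruprasad instability index and Kyte-Doolittle GRAVY follow the
ProtParam conventions via Biopython's ``ProteinAnalysis``.  Two deliberately
simple sequence-only estimates complete the profile:

* ``estimated_logP`` — length-normalised Kyte-Doolittle hydrophobicity,
  identical to GRAVY under the default parameterization;
* ``estimated_psa`` — 50 Å² per polar residue, with the polar set
  {S, T, N, Q, D, E, H, K, R}.

Non-standard residues (bracketed tokens) inherit their base residue's values
unless an override table supplies explicit mass/hydropathy/charge/polarity
contributions.  A small, user-extensible override CSV ships with the package;
its lipid-chain mass increments are chemistry-derived estimates.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .seqio import TokenSeq, base_residue

#: Residues counted as polar for the PSA estimate (50 Å² each).
POLAR_RESIDUES = frozenset("STNQDEHKR")

PSA_PER_POLAR_RESIDUE = 50.0

#: Side-chain formal charges at physiological pH used for graph node features
#: and the chemical-constraint score (His carries a small partial charge).
SIDECHAIN_CHARGE_PH7 = {
    "D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1,
}


@dataclass(frozen=True)
class ResidueOverride:
    """Explicit property contributions for one NSAA token pattern."""

    token_pattern: str
    delta_mass_da: float = 0.0
    kd_value: Optional[float] = None
    charge: Optional[float] = None
    polar_flag: Optional[bool] = None


class OverrideTable:
    """NSAA token → property overrides; exact match first, then regex fullmatch."""

    def __init__(self, overrides: list[ResidueOverride] = ()):  # type: ignore[assignment]
        self._exact = {o.token_pattern: o for o in overrides}
        self._patterns = []
        for o in overrides:
            try:
                self._patterns.append((re.compile(o.token_pattern), o))
            except re.error:
                pass  # plain literal pattern; exact lookup covers it

    def lookup(self, token: str) -> Optional[ResidueOverride]:
        if token in self._exact:
            return self._exact[token]
        for pat, o in self._patterns:
            try:
                if pat.fullmatch(token):
                    return o
            except re.error:  # pragma: no cover - defensive
                continue
        return None

    @classmethod
    def from_csv(cls, path: str | Path) -> "OverrideTable":
        rows = []
        with Path(path).open(newline="") as fh:
            for row in csv.DictReader(fh):
                rows.append(ResidueOverride(
                    token_pattern=row["token_pattern"],
                    delta_mass_da=float(row["delta_mass_Da"] or 0.0),
                    kd_value=float(row["kd_value"]) if row.get("kd_value") else None,
                    charge=float(row["charge"]) if row.get("charge") else None,
                    polar_flag=(row["polar_flag"].strip() in ("1", "true", "True"))
                    if row.get("polar_flag") else None,
                ))
        return cls(rows)

    @classmethod
    def packaged(cls) -> "OverrideTable":
        with resources.as_file(
            resources.files("triagonist.data") / "nsaa_overrides.csv"
        ) as p:
            return cls.from_csv(p)


_DEFAULT_OVERRIDES: Optional[OverrideTable] = None


def default_overrides() -> OverrideTable:
    global _DEFAULT_OVERRIDES
    if _DEFAULT_OVERRIDES is None:
        _DEFAULT_OVERRIDES = OverrideTable.packaged()
    return _DEFAULT_OVERRIDES


@dataclass(frozen=True)
class PropertyProfile:
    """The per-candidate physicochemical profile."""

    mol_weight: float          # Da
    isoelectric: float         # pH units
    instability_index: float   # dimensionless; > 40 suggests in-vitro instability
    gravy: float               # dimensionless, in [-4.5, 4.5]
    est_logP: float            # dimensionless (== gravy by default)
    est_psa: float             # Å², non-negative multiple of 50
    net_charge_ph7: float      # elementary charges


def token_kd(token: str, overrides: Optional[OverrideTable] = None) -> float:
    """Kyte-Doolittle hydropathy of one token (NSAA → base residue unless overridden)."""
    ov = (overrides or default_overrides()).lookup(token) if len(token) > 1 else None
    if ov is not None and ov.kd_value is not None:
        return ov.kd_value
    return KYTE_DOOLITTLE[base_residue(token)]


def token_charge_ph7(token: str, overrides: Optional[OverrideTable] = None) -> float:
    """Side-chain formal charge at physiological pH for one token."""
    ov = (overrides or default_overrides()).lookup(token) if len(token) > 1 else None
    if ov is not None and ov.charge is not None:
        return ov.charge
    return SIDECHAIN_CHARGE_PH7.get(base_residue(token), 0.0)


def token_mass(token: str, overrides: Optional[OverrideTable] = None) -> float:
    """Average residue mass (Da, water excluded) of one token."""
    base = base_residue(token)
    mass = ProteinAnalysis(base).molecular_weight() - 18.0153
    if len(token) > 1:
        ov = (overrides or default_overrides()).lookup(token)
        if ov is not None:
            mass += ov.delta_mass_da
    return mass


def gravy(seq: TokenSeq, overrides: Optional[OverrideTable] = None) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per token."""
    return sum(token_kd(t, overrides) for t in seq) / len(seq)


def estimated_logP(seq: TokenSeq, overrides: Optional[OverrideTable] = None) -> float:
    """Length-normalised hydrophobicity lipophilicity estimate (== GRAVY)."""
    return gravy(seq, overrides)


def estimated_psa(seq: TokenSeq, overrides: Optional[OverrideTable] = None) -> float:
    """Polar surface area estimate: 50 Å² per polar residue."""
    ovt = overrides or default_overrides()
    n_polar = 0
    for t in seq:
        ov = ovt.lookup(t) if len(t) > 1 else None
        if ov is not None and ov.polar_flag is not None:
            n_polar += int(ov.polar_flag)
        else:
            n_polar += int(base_residue(t) in POLAR_RESIDUES)
    return n_polar * PSA_PER_POLAR_RESIDUE


def molecular_weight(seq: TokenSeq, overrides: Optional[OverrideTable] = None) -> float:
    """Average molecular weight in Da of the linear, unmodified peptide."""
    base = seq.base_letters()
    mw = ProteinAnalysis(base).molecular_weight()
    ovt = overrides or default_overrides()
    for t in seq:
        if len(t) > 1:
            ov = ovt.lookup(t)
            if ov is not None:
                mw += ov.delta_mass_da
    return mw


def isoelectric_point(seq: TokenSeq) -> float:
    """pH at which the net charge is zero (Bjellqvist pKa set, bisection).

    NSAA tokens contribute their base residue's ionizable groups.
    """
    return ProteinAnalysis(seq.base_letters()).isoelectric_point()


def net_charge(seq: TokenSeq, ph: float = 7.0) -> float:
    """Net charge at a given pH (termini + D,E,C,Y,H,K,R side chains)."""
    return ProteinAnalysis(seq.base_letters()).charge_at_pH(ph)


def instability_index(seq: TokenSeq) -> float:
    """Guruprasad instability index: (10/L) × Σ DIWV dipeptide weights."""
    if len(seq) < 2:
        raise ValueError("instability index requires length >= 2")
    return ProteinAnalysis(seq.base_letters()).instability_index()


def compute_properties(
    seq: TokenSeq, overrides: Optional[OverrideTable] = None
) -> PropertyProfile:
    """Bundle the full physicochemical profile for one candidate."""
    g = gravy(seq, overrides)
    return PropertyProfile(
        mol_weight=molecular_weight(seq, overrides),
        isoelectric=isoelectric_point(seq),
        instability_index=instability_index(seq),
        gravy=g,
        est_logP=g,
        est_psa=estimated_psa(seq, overrides),
        net_charge_ph7=net_charge(seq, 7.0),
    )
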