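"""Protein physicochemical profiling: length, molecular weight (kDa),
isoelectric point and GRAVY.

Conventions follow the ExPASy pI/MW tool: average (not monoisotopic)
residue masses, and the Bjellqvist pKa set for the charge model.  The
pKa set is configurable because published pI values differ between
tools mainly through this table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .homology import FamilyMember
from .seqio import ProteinRecord

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "KYTE_DOOLITTLE",
    "PkaSet",
    "ProteinProfile",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "gravy",
    "profile_table",
]

# ExPASy average residue masses (Da); a peptide adds one water.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

# Kyte--Doolittle hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class PkaSet:
    """Bjellqvist/ExPASy dissociation constants for the charge model."""

    c_terminus: float = 3.55
    n_terminus: float = 7.5
    acidic: Mapping[str, float] = field(
        default_factory=lambda: {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
    )
    basic: Mapping[str, float] = field(
        default_factory=lambda: {"H": 5.98, "K": 10.0, "R": 12.0}
    )


DEFAULT_PKA = PkaSet()


@dataclass(frozen=True)
class ProteinProfile:
    protein_id: str
    gene_id: str
    group: str
    length: int
    molecular_weight_kda: float
    pi: float
    gravy: float

    @property
    def hydrophobic(self) -> bool:
        """GRAVY >= 0 (hydrophilic proteins have negative GRAVY)."""
        return self.gravy >= 0


def _check_residues(sequence: str, table: Mapping[str, float], what: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - set(table)
    if bad:
        raise ValueError(f"{what}: unknown residue(s) {sorted(bad)}")
    return seq


def molecular_weight(sequence: str) -> float:
    """Average-isotopic molecular weight in kDa (residues + one water)."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = _check_residues(sequence, AVERAGE_RESIDUE_MASS, "molecular_weight")
    da = sum(AVERAGE_RESIDUE_MASS[a] for a in seq) + WATER_MASS
    return da / 1000.0


def net_charge(sequence: str, ph: float, pka: PkaSet = DEFAULT_PKA) -> float:
    """Henderson--Hasselbalch net charge at the given pH.

    Positive groups (N-terminus, H, K, R) contribute
    1 / (1 + 10^(pH - pKa)); negative groups (C-terminus, D, E, C, Y)
    contribute -1 / (1 + 10^(pKa - pH)).
    """
    seq = sequence.upper()
    q = 1.0 / (1.0 + 10 ** (ph - pka.n_terminus))
    q -= 1.0 / (1.0 + 10 ** (pka.c_terminus - ph))
    for aa, const in pka.basic.items():
        q += seq.count(aa) / (1.0 + 10 ** (ph - const))
    for aa, const in pka.acidic.items():
        q -= seq.count(aa) / (1.0 + 10 ** (const - ph))
    return q


def isoelectric_point(
    sequence: str,
    pka: PkaSet = DEFAULT_PKA,
    charge_tol: float = 1e-4,
    ph_tol: float = 1e-9,
) -> float:
    """pH of zero net charge, by bisection on the monotone charge curve.

    Converges when |Q| < ``charge_tol`` or the bracketing interval is
    narrower than ``ph_tol`` pH units.
    """
    if not sequence:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(sequence, mid, pka)
        if abs(q) < charge_tol or (hi - lo) < ph_tol:
            return mid
        if q > 0:  # net positive: pI is higher
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte--Doolittle value."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = _check_residues(sequence, KYTE_DOOLITTLE, "gravy")
    return sum(KYTE_DOOLITTLE[a] for a in seq) / len(seq)


def profile_table(
    members: Sequence[FamilyMember],
    proteome: Sequence[ProteinRecord],
) -> pd.DataFrame:
    """One profiling row per family member, sorted by group then gene.

    Columns mirror the usual family-characterisation report: group,
    gene, length (aa), molecular weight (kDa, 5 decimals), pI, GRAVY,
    plus a ``hydrophobic`` flag for any GRAVY >= 0 row.
    """
    prot_by_id = {p.protein_id: p for p in proteome}
    rows = []
    for m in sorted(members, key=lambda m: (m.group, m.gene_id)):
        prot = prot_by_id.get(m.protein_id)
        if prot is None:
            raise ValueError(f"gene {m.gene_id}: protein {m.protein_id} missing")
        seq = prot.sequence
        rows.append(
            {
                "group": m.group,
                "gene_id": m.gene_id,
                "protein_id": m.protein_id,
                "length_aa": len(seq),
                "molecular_weight_kda": round(molecular_weight(seq), 5),
                "pi": round(isoelectric_point(seq), 2),
                "gravy": round(gravy(seq), 3),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["group", "gene_id", "protein_id", "length_aa",
                 "molecular_weight_kda", "pi", "gravy"],
    )
    df["hydrophobic"] = df["gravy"] >= 0 if len(df) else pd.Series(dtype=bool)
    return df
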