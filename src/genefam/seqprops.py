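"""Protein physicochemical profiling.

Computes, for each protein sequence, the standard report columns of a
gene-family survey table: length, average molecular weight (kDa),
isoelectric point, negatively / positively charged residue counts and
percentages, instability index with a stable/unstable call, aliphatic
index, and GRAVY (grand average of hydropathicity).

Definitions follow the canonical ProtParam conventions: Kyte-Doolittle
hydropathy for GRAVY, Ikai (1980) coefficients for the aliphatic index,
Guruprasad et al. (1990) dipeptide weights for the instability index, and
a Henderson-Hasselbalch charge model with an EMBOSS-style pKa set for the
isoelectric point. The underlying tables are packaged JSON resources
(:mod:`genefam.resources`) and can be swapped.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import ValidationError
from . import resources

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ikai (1980) aliphatic-index coefficients for Val and (Ile + Leu).
ALIPHATIC_COEF_VAL = 2.9
ALIPHATIC_COEF_ILE_LEU = 3.9

#: Instability-index threshold: II < 40 is called "stable".
INSTABILITY_THRESHOLD = 40.0


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with an optional family class label."""

    id: str
    sequence: str
    class_label: Optional[str] = None

    def __post_init__(self):
        validate_sequence(self.sequence)


@dataclass(frozen=True)
class PhysChemProfile:
    """The per-protein physicochemical report row."""

    length_aa: int
    mw_kda: float
    pi: float
    ncr: int
    pcr: int
    ncr_pct: float
    pcr_pct: float
    instability_index: float
    stability_call: str
    aliphatic_index: float
    gravy: float


def validate_sequence(seq: str) -> str:
    """Reject empty sequences and non-canonical residues (B/J/O/U/X/Z...)."""
    if not isinstance(seq, str) or not seq:
        raise ValidationError("protein sequence must be a non-empty string")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValidationError(
            f"non-canonical residues {sorted(bad)}; only the 20 one-letter "
            "amino-acid codes are accepted"
        )
    return seq


def charged_residue_fractions(seq: str) -> tuple[int, int, float, float]:
    """Counts and percentages of charged residues.

    Returns ``(ncr, pcr, ncr_pct, pcr_pct)`` where ncr counts Asp+Glu and
    pcr counts Arg+Lys; percentages are 100*count/length (unrounded here,
    rounded to one decimal in report output).
    """
    validate_sequence(seq)
    ncr = seq.count("D") + seq.count("E")
    pcr = seq.count("R") + seq.count("K")
    n = len(seq)
    return ncr, pcr, 100.0 * ncr / n, 100.0 * pcr / n


def gravy(seq: str) -> float:
    """Mean Kyte-Doolittle hydropathy; more positive = more hydrophobic."""
    validate_sequence(seq)
    table = resources.hydropathy_table()
    return sum(table[a] for a in seq) / len(seq)


def aliphatic_index(seq: str) -> float:
    """Ikai aliphatic index from mole-percent of Ala, Val, Ile, Leu.

    AI = X(Ala) + 2.9*X(Val) + 3.9*(X(Ile) + X(Leu)) with X in mole
    percent of the sequence length.
    """
    validate_sequence(seq)
    n = len(seq)
    x = lambda a: 100.0 * seq.count(a) / n
    return x("A") + ALIPHATIC_COEF_VAL * x("V") + ALIPHATIC_COEF_ILE_LEU * (
        x("I") + x("L")
    )


def instability_index(seq: str) -> tuple[float, str]:
    """Guruprasad instability index and the stable/unstable call.

    II = (10/L) * sum of DIWV(aa_i, aa_i+1) over the L-1 overlapping
    dipeptides. The call is "stable" iff II < 40 (an index of exactly 40
    is "unstable").
    """
    validate_sequence(seq)
    if len(seq) < 2:
        raise ValidationError("instability index requires length >= 2")
    diwv = resources.diwv_table()
    total = sum(diwv[a][b] for a, b in zip(seq, seq[1:]))
    ii = 10.0 * total / len(seq)
    call = "stable" if ii < INSTABILITY_THRESHOLD else "unstable"
    return ii, call


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of the peptide at a given pH."""
    validate_sequence(seq)
    pka = resources.pka_set()
    pos = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
    neg = -1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
    for aa, pk in pka["basic"].items():
        pos += seq.count(aa) / (1.0 + 10.0 ** (ph - pk))
    for aa, pk in pka["acidic"].items():
        neg -= seq.count(aa) / (1.0 + 10.0 ** (pk - ph))
    return pos + neg


def isoelectric_point(seq: str, tol: float = 1e-3) -> float:
    """pH at which the Henderson-Hasselbalch net charge is zero.

    Found by bisection on [0, 14]; net charge is monotone decreasing in
    pH, so the bracket is always valid.
    """
    validate_sequence(seq)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def molecular_weight(seq: str) -> float:
    """Average molecular mass in kDa (residue masses + one water)."""
    validate_sequence(seq)
    masses = resources.residue_masses()
    table = masses["values"]
    return (sum(table[a] for a in seq) + masses["water"]) / 1000.0


def profile(seq: str) -> PhysChemProfile:
    """Full physicochemical profile of one sequence."""
    ncr, pcr, ncr_pct, pcr_pct = charged_residue_fractions(seq)
    ii, call = instability_index(seq)
    return PhysChemProfile(
        length_aa=len(seq),
        mw_kda=molecular_weight(seq),
        pi=isoelectric_point(seq),
        ncr=ncr,
        pcr=pcr,
        ncr_pct=ncr_pct,
        pcr_pct=pcr_pct,
        instability_index=ii,
        stability_call=call,
        aliphatic_index=aliphatic_index(seq),
        gravy=gravy(seq),
    )


def profile_table(records: Iterable[ProteinRecord]) -> pd.DataFrame:
    """Profile many proteins into a report table (percentages to 1 dp)."""
    rows = []
    for rec in records:
        p = profile(rec.sequence)
        rows.append(
            {
                "id": rec.id,
                "length_aa": p.length_aa,
                "mw_kda": round(p.mw_kda, 2),
                "pi": round(p.pi, 2),
                "ncr": p.ncr,
                "ncr_pct": round(p.ncr_pct, 1),
                "pcr": p.pcr,
                "pcr_pct": round(p.pcr_pct, 1),
                "instability_index": round(p.instability_index, 2),
                "stability": p.stability_call,
                "aliphatic_index": round(p.aliphatic_index, 2),
                "gravy": round(p.gravy, 3),
            }
        )
    return pd.DataFrame(rows)
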