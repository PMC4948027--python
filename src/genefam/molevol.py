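"""Ka/Ks estimation, sliding-window selection scans, and divergence dating.

The estimator is the Nei-Gojobori (1986) counting method with the
Jukes-Cantor multiple-hit correction:

* per-codon synonymous site count s = sum over the three positions of
  (number of the three one-step nucleotide changes at that position that
  are synonymous)/3, n = 3 - s; S and N for a sequence are the sums over
  codons, and for a pair the average over the two sequences;
* synonymous/nonsynonymous difference counts Sd, Nd come from averaging
  over all minimal substitution pathways between each codon pair, with
  equal weights; pathways passing through a stop codon are excluded
  (when every pathway is blocked, all pathways are used as a documented
  fallback — this cannot occur between sense codons differing at fewer
  than two positions);
* Ks = -(3/4) ln(1 - (4/3) pS) with pS = Sd/S, Ka analogously; the
  Ka/Ks ratio is undefined (``None``, serialized "NA") when Ks = 0.

Sliding-window profiles apply the same estimator per codon-aligned
window. Divergence times use the molecular-clock form T = Ks/(2*lambda)
with the *Populus* synonymous rate lambda = 9.1e-9 substitutions per
site per year as the default.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

from Bio.Data import CodonTable

from .errors import SaturationError, ValidationError

NUCLEOTIDES = "ACGT"

#: Populus synonymous substitution rate (substitutions/site/year).
POPULUS_LAMBDA = 9.1e-9

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD.forward_table))
_AA = dict(_STANDARD.forward_table)


def _translate(codon: str) -> Optional[str]:
    """Amino acid for a sense codon, None for a stop."""
    return _AA.get(codon)


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts (s, n) of one sense codon.

    s sums, over the three codon positions, the fraction of the three
    one-step changes at that position that preserve the amino acid;
    changes to stop codons count as nonsynonymous. s + n = 3 exactly.
    """
    if codon in STOP_CODONS:
        raise ValidationError(f"stop codon {codon} has no site decomposition")
    if codon not in _AA:
        raise ValidationError(f"invalid codon {codon!r}")
    aa = _AA[codon]
    s = 0.0
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _translate(alt) == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) contribution of one aligned codon pair, pathway-averaged.

    All minimal substitution pathways between the two codons are
    enumerated; each is a permutation of the differing positions. A step
    is synonymous when the amino acid is unchanged. Pathways with a stop
    intermediate are dropped; if none survive, all are used.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                blocked = True
            if _translate(cur) is not None and _translate(cur) == _translate(nxt):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in paths if not b]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in paths]
    k = len(open_paths)
    return (
        sum(s for s, _ in open_paths) / k,
        sum(n for _, n in open_paths) / k,
    )


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Two gapless codon-aligned CDS for one paralog pair."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str
    allow_stops: bool = False

    def __post_init__(self):
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValidationError("aligned sequences must have equal length")
        if len(a) == 0 or len(a) % 3:
            raise ValidationError("alignment length must be a positive multiple of 3")
        if set(a + b) - set(NUCLEOTIDES + "-"):
            raise ValidationError("alphabet must be A/C/G/T (plus '-' for gaps)")

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Aligned codon columns, gapped columns dropped codon-wise."""
        out = []
        for i in range(0, len(self.seq_a), 3):
            ca, cb = self.seq_a[i : i + 3], self.seq_b[i : i + 3]
            if "-" in ca or "-" in cb:
                continue
            if (ca in STOP_CODONS or cb in STOP_CODONS) and not self.allow_stops:
                raise ValidationError(
                    f"internal stop codon at alignment position {i + 1}"
                )
            if ca in STOP_CODONS or cb in STOP_CODONS:
                continue
            out.append((ca, cb))
        return out


@dataclass(frozen=True)
class KaKsResult:
    """NG86 site/difference counts and Jukes-Cantor corrected rates."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: Optional[float]  # None when Ks == 0 (serialized "NA")

    @property
    def ratio_str(self) -> str:
        return "NA" if self.ratio is None else f"{self.ratio:.4f}"


def _jc_correct(p: float, what: str) -> float:
    if p >= 0.75:
        raise SaturationError(
            f"{what} proportion {p:.4f} >= 3/4; Jukes-Cantor correction undefined"
        )
    if p == 0.0:
        return 0.0
    import math

    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks_ng86(pair: CodonAlignmentPair) -> KaKsResult:
    """NG86 Ka/Ks for one codon-aligned pair (see module docstring)."""
    codons = pair.codon_pairs()
    if not codons:
        raise ValidationError("no ungapped sense codon columns to compare")
    S = N = Sd = Nd = 0.0
    for ca, cb in codons:
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        ds, dn = _pair_differences(ca, cb)
        Sd += ds
        Nd += dn
    if S <= 0 or N <= 0:
        raise ValidationError("degenerate alignment: S or N is zero")
    pS, pN = Sd / S, Nd / N
    Ks = _jc_correct(pS, "synonymous")
    Ka = _jc_correct(pN, "nonsynonymous")
    ratio = None if Ks == 0.0 else Ka / Ks
    return KaKsResult(S, N, Sd, Nd, pS, pN, Ks, Ka, ratio)


@dataclass(frozen=True)
class WindowResult:
    start_bp: int  # 1-based inclusive
    end_bp: int
    Ka: Optional[float]
    Ks: Optional[float]
    ratio: Optional[float]
    flag: str  # "ok" | "saturated" | "undefined_ratio"


@dataclass(frozen=True)
class SlidingWindowProfile:
    pair_id: str
    window_bp: int
    step_bp: int
    windows: list[WindowResult]


def sliding_window_kaks(
    pair: CodonAlignmentPair, window_bp: int = 90, step_bp: int = 9
) -> SlidingWindowProfile:
    """Per-window NG86 Ka/Ks along the alignment.

    Windows start at 1, 1+step, ... and must lie fully inside the
    alignment; window and step must be codon multiples. Windows where the
    correction saturates (or sites vanish) carry a flag instead of values.
    """
    if window_bp % 3 or step_bp % 3 or step_bp <= 0:
        raise ValidationError("window_bp and step_bp must be positive multiples of 3")
    L = len(pair.seq_a)
    if window_bp > L:
        raise ValidationError("window_bp exceeds alignment length")
    windows = []
    for start in range(0, L - window_bp + 1, step_bp):
        sub = CodonAlignmentPair(
            pair.id_a,
            pair.id_b,
            pair.seq_a[start : start + window_bp],
            pair.seq_b[start : start + window_bp],
            allow_stops=pair.allow_stops,
        )
        try:
            res = kaks_ng86(sub)
            flag = "ok" if res.ratio is not None else "undefined_ratio"
            windows.append(
                WindowResult(start + 1, start + window_bp, res.Ka, res.Ks, res.ratio, flag)
            )
        except (SaturationError, ValidationError):
            windows.append(
                WindowResult(start + 1, start + window_bp, None, None, None, "saturated")
            )
    return SlidingWindowProfile(
        f"{pair.id_a}|{pair.id_b}", window_bp, step_bp, windows
    )


@dataclass(frozen=True)
class DivergenceEstimate:
    ks: float
    lambda_rate: float
    t_mya: float


def divergence_time(ks: float, lambda_rate: float = POPULUS_LAMBDA) -> DivergenceEstimate:
    """Molecular-clock dating: T = Ks / (2*lambda), reported in MYA."""
    if ks < 0:
        raise ValidationError("Ks must be non-negative")
    if lambda_rate <= 0:
        raise ValidationError("substitution rate must be positive")
    t = ks / (2.0 * lambda_rate) / 1e6
    return DivergenceEstimate(ks, lambda_rate, t)
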