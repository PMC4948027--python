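"""Promoter extraction, IUPAC cis-element scanning, and enrichment.

Promoters are the 2 kb immediately 5' of the translation initiation
site. Scanning matches IUPAC consensus patterns (e.g. the heat stress
element AGAAnnTTCT) at every position on both strands; an N in the
*sequence* matches only the pattern code N, never a constrained code.
Overlapping matches are all reported. The enrichment level of an element
over a gene set is (total occurrences) / (genes with >= 1 occurrence).

Promoter coordinates are 1-based: position 1 is the most distal base and
position 2000 (for a full-length promoter) is the base immediately 5' of
the start codon. Hits on the minus strand report the forward-strand
start of the matched slice.
"""
from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import ValidationError
from . import resources

PROMOTER_LENGTH = 2000

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGTN"),
}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class CisElement:
    name: str
    iupac: str
    functional_class: str

    def __post_init__(self):
        if not self.iupac or set(self.iupac.upper()) - set(IUPAC):
            raise ValidationError(
                f"element {self.name!r}: malformed IUPAC pattern {self.iupac!r}"
            )
        object.__setattr__(self, "iupac", self.iupac.upper())


@dataclass(frozen=True)
class CisElementCatalog:
    entries: tuple[CisElement, ...]

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValidationError("catalog element names must be unique")

    @classmethod
    def default(cls) -> "CisElementCatalog":
        return cls.from_json(resources.default_catalog_json())

    @classmethod
    def from_json(cls, obj: Mapping) -> "CisElementCatalog":
        return cls(
            tuple(
                CisElement(e["name"], e["iupac"], e.get("functional_class", ""))
                for e in obj["entries"]
            )
        )

    @classmethod
    def from_file(cls, path) -> "CisElementCatalog":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


@dataclass(frozen=True)
class PromoterSequence:
    gene_id: str
    sequence: str
    truncated: bool = False

    def __post_init__(self):
        if len(self.sequence) > PROMOTER_LENGTH:
            raise ValidationError("promoter longer than 2000 nt")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValidationError("promoter alphabet must be A/C/G/T/N")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class ElementHit:
    gene_id: str
    element_name: str
    start: int  # 1-based position in the promoter (forward strand)
    strand: str
    matched_text: str


def extract_promoter(
    gene_id: str,
    scaffold_seq: str,
    tss: int,
    strand: str,
    length: int = PROMOTER_LENGTH,
) -> PromoterSequence:
    """Cut the ``length`` bases 5' of the translation start.

    ``tss`` is the 1-based genomic coordinate of the first base of the
    start codon. Plus strand: genomic [tss-length, tss-1] as-is; minus
    strand: reverse complement of genomic [tss+1, tss+length]. Truncated
    at scaffold edges with the flag set.
    """
    L = len(scaffold_seq)
    if not (1 <= tss <= L):
        raise ValidationError(f"tss {tss} outside scaffold of length {L}")
    if strand == "+":
        lo = max(1, tss - length)
        sub = scaffold_seq[lo - 1 : tss - 1]
        truncated = lo > tss - length
    elif strand == "-":
        hi = min(L, tss + length)
        sub = revcomp(scaffold_seq[tss : hi])
        truncated = hi < tss + length
    else:
        raise ValidationError("strand must be '+' or '-'")
    return PromoterSequence(gene_id, sub, truncated)


def _iupac_match_at(seq: str, pattern: str, i: int) -> bool:
    for j, code in enumerate(pattern):
        if seq[i + j] not in IUPAC[code]:
            return False
        if seq[i + j] == "N" and code != "N":
            return False
    return True


def scan_elements(
    promoter: PromoterSequence,
    catalog: CisElementCatalog,
    both_strands: bool = True,
) -> list[ElementHit]:
    """All catalog-pattern occurrences in one promoter.

    Minus-strand occurrences are found by matching the reverse complement
    of the pattern on the forward sequence; each (position, strand) is
    reported once. Output is ordered by (start, element, strand).
    """
    seq = promoter.sequence
    hits = []
    for element in catalog.entries:
        pats = [("+", element.iupac)]
        if both_strands:
            rc = revcomp(element.iupac)
            if rc != element.iupac:
                pats.append(("-", rc))
            else:
                # palindromic consensus: one hit per position
                pass
        for strand, pat in pats:
            m = len(pat)
            for i in range(len(seq) - m + 1):
                if _iupac_match_at(seq, pat, i):
                    hits.append(
                        ElementHit(
                            promoter.gene_id, element.name, i + 1, strand,
                            seq[i : i + m],
                        )
                    )
    hits.sort(key=lambda h: (h.start, h.element_name, h.strand))
    return hits


def scan_promoters(
    promoters: Iterable[PromoterSequence],
    catalog: CisElementCatalog,
    both_strands: bool = True,
) -> list[ElementHit]:
    out = []
    for p in promoters:
        out.extend(scan_elements(p, catalog, both_strands))
    return out


@dataclass(frozen=True)
class EnrichmentSummary:
    element_name: str
    functional_class: str
    n_genes_with_hit: int
    n_total_hits: int
    enrichment_level: float  # n_total_hits / n_genes_with_hit


def enrichment_level(n_total_hits: int, n_genes_with_hit: int) -> float:
    """Occurrences per carrying gene (>= 1 whenever any gene carries one)."""
    if n_genes_with_hit <= 0:
        raise ValidationError("enrichment undefined without carrying genes")
    return n_total_hits / n_genes_with_hit


def summarize_enrichment(
    hits: Sequence[ElementHit], catalog: Optional[CisElementCatalog] = None
) -> list[EnrichmentSummary]:
    """Per-element gene counts, total counts, and enrichment levels.

    Elements with zero hits are absent from the summary (never 0/0).
    """
    classes = (
        {e.name: e.functional_class for e in catalog.entries} if catalog else {}
    )
    genes: dict[str, set] = defaultdict(set)
    totals: dict[str, int] = defaultdict(int)
    for h in hits:
        genes[h.element_name].add(h.gene_id)
        totals[h.element_name] += 1
    return [
        EnrichmentSummary(
            name,
            classes.get(name, ""),
            len(genes[name]),
            totals[name],
            enrichment_level(totals[name], len(genes[name])),
        )
        for name in sorted(totals)
    ]


def enrichment_table(summaries: Sequence[EnrichmentSummary]) -> pd.DataFrame:
    """Report table with enrichment levels rounded to one decimal."""
    return pd.DataFrame(
        [
            {
                "element": s.element_name,
                "functional_class": s.functional_class,
                "n_genes": s.n_genes_with_hit,
                "n_hits": s.n_total_hits,
                "enrichment_level": round(s.enrichment_level, 1),
            }
            for s in summaries
        ]
    )
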