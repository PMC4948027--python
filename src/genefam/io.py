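"""File-format helpers: FASTA, locus TSV, GFF3, homolog TSV, Ct TSV.

Thin wrappers over Biopython/pyfaidx/gffutils so the analysis modules
stay format-agnostic. All tabular formats are plain TSV with headers.
"""
from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .genomevol import GeneLocus, rank_loci
from .molevol import CodonAlignmentPair
from .seqprops import ProteinRecord


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {id: sequence} preserving order (py3.7+ dicts)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_protein_fasta(path) -> list[ProteinRecord]:
    return [ProteinRecord(name, seq) for name, seq in read_fasta(path).items()]


def read_pair_fasta(path) -> CodonAlignmentPair:
    """A two-record FASTA holding one codon-aligned pair."""
    recs = read_fasta(path)
    if len(recs) != 2:
        raise ValidationError(f"{path}: expected exactly 2 records, got {len(recs)}")
    (ida, sa), (idb, sb) = recs.items()
    return CodonAlignmentPair(ida, idb, sa, sb)


def read_locus_tsv(path) -> dict[str, GeneLocus]:
    """Locus TSV (id, scaffold, start, end, strand) -> ranked loci."""
    df = pd.read_csv(path, sep="\t")
    needed = ["id", "scaffold", "start", "end", "strand"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: locus TSV missing columns {missing}")
    return rank_loci(
        GeneLocus(str(r.id), str(r.scaffold), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples()
    )


def write_locus_tsv(path, loci: dict[str, GeneLocus]) -> None:
    rows = sorted(loci.values(), key=lambda l: (l.scaffold, l.rank))
    pd.DataFrame(
        [
            {"id": l.id, "scaffold": l.scaffold, "start": l.start,
             "end": l.end, "strand": l.strand, "rank": l.rank}
            for l in rows
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gff3_loci(path) -> dict[str, GeneLocus]:
    """Gene features from a GFF3 file -> ranked loci (gffutils-backed)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    loci = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        loci.append(GeneLocus(gid, feat.seqid, feat.start, feat.end, feat.strand))
    if not loci:
        raise ValidationError(f"no gene features in {path}")
    return rank_loci(loci)


def read_homolog_tsv(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    for c in ("gene_a", "gene_b"):
        if c not in df.columns:
            raise ValidationError(f"{path}: homolog TSV missing column {c!r}")
    return [(str(a), str(b)) for a, b in zip(df["gene_a"], df["gene_b"])]


def read_ct_tsv(path) -> pd.DataFrame:
    from .expression import validate_qpcr_table

    return validate_qpcr_table(pd.read_csv(path, sep="\t"))


def sha256_file(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
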