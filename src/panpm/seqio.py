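"""File-format helpers: FASTA, GFF3 gene features, orthogroup tables.

FASTA goes through Biopython.  GFF3 handling is deliberately narrow: the
pipeline only needs gene features with an ID attribute, 1-based inclusive
coordinates and a strand, so the reader validates exactly that and reports
the offending line number on malformed input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein: (taxon, protein_id) is unique within a dataset."""

    protein_id: str
    taxon: str
    sequence: str

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[ACDEFGHIKLMNPQRSTVWYX]+", self.sequence):
            raise ValueError(
                f"{self.taxon}/{self.protein_id}: sequence contains "
                "characters outside the 20 amino acids + X"
            )


@dataclass(frozen=True)
class GeneFeature:
    """One gene line from a GFF3 file (1-based inclusive coordinates)."""

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def read_proteome(path: str | Path, taxon: str) -> list[ProteinRecord]:
    return [ProteinRecord(i, taxon, s) for i, s in read_fasta(path)]


def write_gff3(path: str | Path, features: Iterable[GeneFeature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.contig}\tpanpm\tgene\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.gene_id}\n"
            )


def read_gff3(path: str | Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: expected 9 columns")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "gene":
                continue
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: bad coordinates")
            if strand not in "+-":
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: bad strand {strand!r}")
            m = re.search(r"(?:^|;)ID=([^;]+)", attrs)
            if not m:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: missing ID attribute")
            gid = m.group(1)
            if gid in seen:
                raise ValueError(f"{path}: duplicate gene id {gid!r} at line {lineno}")
            seen.add(gid)
            feats.append(GeneFeature(contig, s, e, strand, gid))
    return feats


def write_orthogroup_table(
    path: str | Path, ogs: dict[str, dict[str, list[str]]], taxa: list[str]
) -> None:
    """Write the common 'Orthogroups.tsv' dialect.

    First column is the OG id; one column per taxon holds comma-separated
    protein ids (empty cell = absent).
    """
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(taxa) + "\n")
        for og_id in sorted(ogs):
            cells = [",".join(sorted(ogs[og_id].get(t, []))) for t in taxa]
            fh.write(og_id + "\t" + "\t".join(cells) + "\n")


def read_orthogroup_table(path: str | Path) -> tuple[dict[str, dict[str, list[str]]], list[str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        taxa = header[1:]
        ogs: dict[str, dict[str, list[str]]] = {}
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            og_id = cols[0]
            members = {
                t: cell.split(",")
                for t, cell in zip(taxa, cols[1:])
                if cell
            }
            ogs[og_id] = members
    return ogs, taxa
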