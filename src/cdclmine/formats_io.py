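"""File formats and coordinate conventions.

Every external representation the pipeline touches goes through this module:
FASTA (nucleotide and protein), GFF3 gene coordinates, FASTQ reads, HMM hit
tables (hmmsearch ``--tblout`` or a minimal 4-column TSV), Newick trees and
TSV reports.

Coordinates are 0-based half-open everywhere inside the package; GFF3 I/O
converts to and from the 1-based inclusive convention at the boundary, so
all interval arithmetic (intergenic gaps, overlaps, contig-edge checks) is
done on half-open intervals.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.iterators import DataIterator

STRANDS = frozenset({"+", "-"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContigRecord:
    """One contig of a genome assembly.

    ``sequence`` is optional for annotation-only workflows; when present its
    length must equal ``length``.
    """

    contig_id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"negative contig length for {self.contig_id}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.contig_id}: length {self.length} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class GeneRecord:
    """One annotated protein-coding gene.

    ``start``/``end`` are 0-based half-open positions on ``contig_id``;
    ``strand`` is strictly '+' or '-' (strand is load-bearing for locus
    pairing, so ambiguous strands are rejected at parse time).
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_seq: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if len(self.protein_seq) < 1:
            raise ValueError(f"gene {self.gene_id}: empty protein sequence")

    @property
    def protein_len(self) -> int:
        return len(self.protein_seq)


@dataclass(frozen=True)
class HitTableRow:
    """One target-vs-model hit from an HMM search table."""

    protein_id: str
    model_name: str
    bit_score: float
    is_partial: bool = False


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_contigs(path: str | Path) -> list[ContigRecord]:
    return [
        ContigRecord(contig_id=name, length=len(seq), sequence=seq)
        for name, seq in read_fasta(path).items()
    ]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3_with_proteins(
    gff_path: str | Path,
    protein_fasta_path: str | Path,
    genome_id: str | None = None,
) -> list[GeneRecord]:
    """Read gene coordinates from GFF3 and join protein sequences by ID.

    CDS features are used when present, otherwise ``gene`` features. GFF3's
    1-based inclusive coordinates are converted to 0-based half-open. A CDS
    whose ID has no protein in the FASTA is a hard error naming that ID.
    Output is sorted by (contig_id, start).
    """
    gff_path = Path(gff_path)
    if genome_id is None:
        genome_id = gff_path.stem.removesuffix(".gff3").removesuffix(".gff")
    proteins = read_fasta(protein_fasta_path)

    features = list(DataIterator(str(gff_path)))
    wanted = [f for f in features if f.featuretype == "CDS"]
    if not wanted:
        wanted = [f for f in features if f.featuretype == "gene"]

    genes: list[GeneRecord] = []
    for feat in wanted:
        ids = feat.attributes.get("ID")
        if not ids:
            raise ValueError(f"{gff_path}: feature without ID attribute: {feat}")
        gene_id = ids[0]
        if feat.end < feat.start:
            raise ValueError(
                f"{gff_path}: malformed coordinates for {gene_id} "
                f"(end {feat.end} < start {feat.start})"
            )
        if gene_id not in proteins:
            raise ValueError(
                f"no protein sequence for CDS {gene_id!r} in {protein_fasta_path}"
            )
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                genome_id=genome_id,
                contig_id=feat.seqid,
                start=feat.start - 1,  # 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand,
                protein_seq=proteins[gene_id],
            )
        )
    genes.sort(key=lambda g: (g.contig_id, g.start, g.end, g.gene_id))
    return genes


def write_gff3(
    genes: Iterable[GeneRecord],
    path: str | Path,
    contigs: Iterable[ContigRecord] | None = None,
) -> None:
    """Write GeneRecords as GFF3 CDS features (internal -> 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contigs is not None:
            for c in contigs:
                fh.write(f"##sequence-region {c.contig_id} 1 {c.length}\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "cdclmine",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# HMM hit tables
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "yes", "t", "y", "partial"}
_FALSY = {"0", "false", "no", "f", "n", "full", "-"}


def read_hit_table(path: str | Path) -> list[HitTableRow]:
    """Read an HMM hit table in either accepted dialect.

    Accepted dialects:

    * hmmsearch per-sequence ``--tblout`` (>= 18 whitespace columns; target
      name, model name and full-sequence bit score are columns 1, 3 and 6);
    * a minimal 4-column TSV ``protein_id  model  bit_score  partial_flag``
      for synthetic fixtures that must not require HMMER.

    Comment lines start with '#'. Rows whose bit score does not parse are
    skipped with a ``UserWarning`` (one per skipped row); an empty file
    yields an empty list.
    """
    rows: list[HitTableRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fields[0].lower() in {"protein_id", "target", "target_name"}:
                continue  # header row of the minimal dialect
            if len(fields) >= 18:
                protein_id, model, score_s = fields[0], fields[2], fields[5]
                partial = False
            elif len(fields) == 4:
                protein_id, model, score_s = fields[0], fields[1], fields[2]
                partial = fields[3].strip().lower() in _TRUTHY
            else:
                warnings.warn(
                    f"{path}:{lineno}: unrecognised hit-table row "
                    f"({len(fields)} fields); skipped"
                )
                continue
            try:
                score = float(score_s)
            except ValueError:
                warnings.warn(
                    f"{path}:{lineno}: non-numeric bit score {score_s!r}; row skipped"
                )
                continue
            if score != score:  # NaN
                warnings.warn(f"{path}:{lineno}: non-finite bit score; row skipped")
                continue
            rows.append(
                HitTableRow(
                    protein_id=protein_id,
                    model_name=model,
                    bit_score=score,
                    is_partial=partial,
                )
            )
    return rows


def write_hit_table(rows: Iterable[HitTableRow], path: str | Path) -> None:
    """Write the minimal 4-column TSV hit-table dialect."""
    with open(path, "w") as fh:
        fh.write("protein_id\tmodel\tbit_score\tpartial\n")
        for r in rows:
            fh.write(
                f"{r.protein_id}\t{r.model_name}\t{r.bit_score:g}\t"
                f"{'1' if r.is_partial else '0'}\n"
            )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) pairs; Phred+33 qualities are parsed but ignored."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq)


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write reads with a constant 'I' quality (qualities are ignored downstream)."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick text terminated by ';'.

    Labels containing Newick metacharacters (spaces, parentheses, commas,
    quotes) are single-quoted so that re-reading returns the labels exactly.
    """
    text = tree.as_string(
        schema="newick",
        preserve_spaces=True,
        suppress_rooting=True,
    ).strip()
    if not text.endswith(";"):
        text += ";"
    return text


def read_newick(text: str) -> dendropy.Tree:
    """Parse Newick text; underscores in unquoted labels are kept literal."""
    return dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )
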