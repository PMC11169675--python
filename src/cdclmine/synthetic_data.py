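"""Seeded generators for every input the pipeline consumes.

Real inputs for this kind of analysis are a RefSeq genome snapshot and
public gut metagenomes; at desk scale this module stands in for both. It
plants CDCL gene pairs/triplets (with constructed SpII, rescue-only or
signal-less leaders) and rule-violating decoys into multi-contig synthetic
genomes, emits matching hit tables, mutates proteins to a controlled
ungapped identity for clustering tests, and simulates substitution-only
reads at a controlled depth. Everything is deterministic for a fixed seed,
and every planted element carries its expected pipeline fate in a truth
table — the generator is the package's primary end-to-end test harness.

No claim of biological realism is made beyond what the discovery rules
read: protein bodies are uniform-random residues, genes are back-translated
with a fixed codon table, qualities are constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    ContigRecord,
    GeneRecord,
    HitTableRow,
    write_fasta,
    write_fastq,
    write_gff3,
    write_hit_table,
)
from .metagenome_presence import ReferenceSeq, revcomp

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_NO_CYS = AMINO_ACIDS.replace("C", "")
_BASES = "ACGT"

# one fixed codon per amino acid (back-translation is not meant to be
# biologically faithful, only invertible and deterministic)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"

#: decoy kinds; each violates exactly one discovery rule
DECOY_KINDS = (
    "low_score",
    "partial",
    "opposite_strand",
    "gap_too_large",
    "no_signal",
    "contig_edge",
)


@dataclass(frozen=True)
class LocusTemplate:
    """Template of one planted locus: per-gene protein lengths (aa),
    intergenic gaps (bp), shared strand and per-gene signal-leader type
    (``SpII`` | ``rescue`` | ``none``)."""

    lengths: tuple[int, ...] = (365, 500)
    gaps: tuple[int, ...] = (300,)
    strand: str = "+"
    signals: tuple[str, ...] = ("SpII", "SpII")

    def __post_init__(self) -> None:
        if len(self.lengths) not in (2, 3):
            raise ValueError("locus template arity must be 2 or 3")
        if len(self.gaps) != len(self.lengths) - 1:
            raise ValueError("need one gap per adjacent gene pair")
        if len(self.signals) != len(self.lengths):
            raise ValueError("need one signal type per gene")
        if any(n < 100 for n in self.lengths):
            raise ValueError("template protein lengths must be >= 100 aa")
        if any(g < 0 for g in self.gaps):
            raise ValueError("gaps must be >= 0")


def default_templates() -> list[LocusTemplate]:
    """The archetypal locus architectures: S+L pairs on both strands, a
    similar-sized pair, and an S/M/L triplet (lengths echo the observed
    ~365/~500 aa subunits and the 336-621 aa similar-size range)."""
    return [
        LocusTemplate((365, 500), (300,), "+", ("SpII", "SpII")),
        LocusTemplate((500, 365), (250,), "-", ("SpII", "SpII")),
        LocusTemplate((336, 360), (400,), "+", ("SpII", "SpII")),
        LocusTemplate((350, 450, 550), (200, 200), "+", ("SpII", "SpII", "SpII")),
        LocusTemplate((365, 500), (300,), "+", ("rescue", "SpII")),
    ]


@dataclass(frozen=True)
class PlantSpec:
    """What to plant: one locus per genome (templates cycled), plus decoys
    (each violating exactly one rule) and high-scoring singleton genes
    distributed round-robin across genomes on separate contigs."""

    n_genomes: int = 50
    templates: tuple[LocusTemplate, ...] = tuple(default_templates())
    decoy_kinds: tuple[str, ...] = DECOY_KINDS * 2
    decoy_singletons: int = 5
    seed: int = 0
    margin: int = 150  # bp between contig edge and planted genes

    def __post_init__(self) -> None:
        unknown = set(self.decoy_kinds) - set(DECOY_KINDS)
        if unknown:
            raise ValueError(f"unknown decoy kinds: {sorted(unknown)}")


@dataclass(frozen=True)
class ReadSimSpec:
    """Uniform shotgun read simulation parameters."""

    target_depth: float
    read_length: int = 100
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate <= 0.1:
            raise ValueError("substitution_rate must be in [0, 0.1]")
        if self.read_length < 31:
            raise ValueError("read_length must be >= 31")


@dataclass
class SyntheticGenomes:
    """In-memory result of ``generate_genomes`` plus a file writer."""

    contigs: dict[str, list[ContigRecord]]  # genome_id -> contigs
    genes: list[GeneRecord]
    hits: list[HitTableRow]
    truth: pd.DataFrame

    def contig_lengths(self) -> dict[tuple[str, str], int]:
        return {
            (genome_id, c.contig_id): c.length
            for genome_id, contig_list in self.contigs.items()
            for c in contig_list
        }

    def contig_sequence(self, genome_id: str, contig_id: str) -> str:
        for c in self.contigs[genome_id]:
            if c.contig_id == contig_id:
                assert c.sequence is not None
                return c.sequence
        raise KeyError((genome_id, contig_id))

    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein_seq for g in self.genes}

    def write(self, outdir: str | Path) -> None:
        """Write per-genome FASTA + GFF3 + protein FASTA, hits.tsv, truth.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for genome_id, contig_list in self.contigs.items():
            gdir = outdir / genome_id
            gdir.mkdir(exist_ok=True)
            write_fasta(
                {c.contig_id: c.sequence or "" for c in contig_list},
                gdir / f"{genome_id}.fna",
            )
            genome_genes = [g for g in self.genes if g.genome_id == genome_id]
            write_gff3(genome_genes, gdir / f"{genome_id}.gff3", contig_list)
            write_fasta(
                {g.gene_id: g.protein_seq for g in genome_genes},
                gdir / f"{genome_id}.faa",
            )
        write_hit_table(self.hits, outdir / "hits.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# protein / gene construction
# ---------------------------------------------------------------------------


def _random_residues(rng: np.random.Generator, n: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def make_protein(length: int, signal: str, rng: np.random.Generator) -> str:
    """Construct a protein of ``length`` aa with a controlled leader.

    ``SpII``: basic n-region (MKK), 8-residue leucine h-region, LAGC
    lipobox (cysteine at index 14) — satisfies the lipobox heuristic.
    ``rescue``: no K/R in the n-region and no hydrophobic h-region, but an
    SC dipeptide at index 12-13 — fails the lipobox heuristic, matches the
    [SA]C rescue scan. ``none``: cysteine-free first 35 residues — matches
    neither. The remainder of the protein is uniform-random.
    """
    if signal == "SpII":
        leader = "MKK" + "L" * 8 + "LAGC"
    elif signal == "rescue":
        leader = "M" + "T" * 11 + "SC"
    elif signal == "none":
        leader = "M" + _random_residues(rng, 34, _NO_CYS)
    else:
        raise ValueError(f"unknown signal leader type {signal!r}")
    # keep the remainder of the first 35 residues cysteine-free so the
    # leader alone controls the signal call
    pad = _random_residues(rng, max(0, 35 - len(leader)), _NO_CYS)
    body = _random_residues(rng, length - len(leader) - len(pad), AMINO_ACIDS)
    protein = leader + pad + body
    assert len(protein) == length
    return protein


def back_translate(protein: str) -> str:
    """Nucleotide CDS for a protein under the fixed codon table (+ stop)."""
    return "".join(_CODON[a] for a in protein) + _STOP


@dataclass
class _GenePlan:
    gene_id: str
    protein: str
    strand: str
    offset_gap: int  # gap after previous gene (or after margin)
    bit_score: float
    is_partial: bool = False
    at_edge: bool = False


def _lay_contig(
    genome_id: str,
    contig_id: str,
    plans: Sequence[_GenePlan],
    rng: np.random.Generator,
    margin: int,
    edge_first: bool = False,
) -> tuple[ContigRecord, list[GeneRecord]]:
    """Place genes left-to-right on a fresh random contig."""
    genes: list[GeneRecord] = []
    parts: list[str] = []
    pos = 0
    if not edge_first:
        lead = _random_dna(rng, margin)
        parts.append(lead)
        pos += margin
    for i, plan in enumerate(plans):
        if i > 0 and plan.offset_gap > 0:
            parts.append(_random_dna(rng, plan.offset_gap))
            pos += plan.offset_gap
        cds = back_translate(plan.protein)
        if plan.strand == "-":
            cds = revcomp(cds)
        start = pos
        parts.append(cds)
        pos += len(cds)
        genes.append(
            GeneRecord(
                gene_id=plan.gene_id,
                genome_id=genome_id,
                contig_id=contig_id,
                start=start,
                end=pos,
                strand=plan.strand,
                protein_seq=plan.protein,
            )
        )
    if not edge_first:
        parts.append(_random_dna(rng, margin))
        pos += margin
    contig = ContigRecord(contig_id=contig_id, length=pos, sequence="".join(parts))
    return contig, genes


def _random_dna(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(list(_BASES), size=n))


def generate_genomes(spec: PlantSpec) -> SyntheticGenomes:
    """Generate genomes with planted loci, decoys and singletons + truth table.

    Each genome carries one planted locus (templates cycled) on contig c1.
    Decoys from ``spec.decoy_kinds`` and high-scoring singletons are
    distributed round-robin over genomes, each on its own extra contig, so
    every decoy violates exactly one discovery rule. The truth table lists
    every element with its expected pipeline fate: ``locus`` (recovered),
    ``singletons`` (reported unpaired) or ``none`` (filtered/pruned away).
    """
    rng = np.random.default_rng(spec.seed)
    contigs: dict[str, list[ContigRecord]] = {}
    genes: list[GeneRecord] = []
    hits: list[HitTableRow] = []
    truth_rows: list[dict] = []

    def score(lo: float = 60.0, hi: float = 280.0) -> float:
        return float(np.round(rng.uniform(lo, hi), 1))

    for gi in range(spec.n_genomes):
        genome_id = f"g{gi:03d}"
        contigs[genome_id] = []
        template = spec.templates[gi % len(spec.templates)]

        plans = []
        for k, (length, signal) in enumerate(
            zip(template.lengths, template.signals)
        ):
            gap = template.gaps[k - 1] if k > 0 else 0
            plans.append(
                _GenePlan(
                    gene_id=f"{genome_id}_c1_{k}",
                    protein=make_protein(length, signal, rng),
                    strand=template.strand,
                    offset_gap=gap,
                    bit_score=score(),
                )
            )
        contig, contig_genes = _lay_contig(
            genome_id, "c1", plans, rng, spec.margin
        )
        contigs[genome_id].append(contig)
        genes.extend(contig_genes)
        hits.extend(
            HitTableRow(p.gene_id, "CDC_like", p.bit_score) for p in plans
        )
        truth_rows.append(
            {
                "genome_id": genome_id,
                "element_id": f"{genome_id}_locus",
                "kind": "planted_locus",
                "detail": "|".join(template.signals),
                "gene_ids": ",".join(p.gene_id for p in plans),
                "expected": "locus",
            }
        )

    # decoys, one per extra contig, round-robin over genomes
    for di, kind in enumerate(spec.decoy_kinds):
        genome_id = f"g{di % spec.n_genomes:03d}"
        contig_id = f"d{di}"
        gid = lambda k: f"{genome_id}_{contig_id}_{k}"
        lengths = (365, 500)
        signals = ["SpII", "SpII"]
        strands = ["+", "+"]
        gap = 300
        bitscores = [score(), score()]
        partial = [False, False]
        edge_first = False
        expected = "none"

        if kind == "low_score":
            bitscores = [20.0, 20.0]  # below the 25-bit gathering threshold
        elif kind == "partial":
            partial = [True, True]
        elif kind == "opposite_strand":
            strands = ["+", "-"]
            expected = "singletons"
        elif kind == "gap_too_large":
            gap = 8000  # beyond the 5 kb adjacency limit
            expected = "singletons"
        elif kind == "no_signal":
            signals = ["none", "none"]
        elif kind == "contig_edge":
            edge_first = True  # first gene starts at position 0

        plans = [
            _GenePlan(
                gene_id=gid(k),
                protein=make_protein(lengths[k], signals[k], rng),
                strand=strands[k],
                offset_gap=gap if k == 1 else 0,
                bit_score=bitscores[k],
                is_partial=partial[k],
            )
            for k in range(2)
        ]
        contig, contig_genes = _lay_contig(
            genome_id, contig_id, plans, rng, spec.margin, edge_first=edge_first
        )
        contigs[genome_id].append(contig)
        genes.extend(contig_genes)
        hits.extend(
            HitTableRow(p.gene_id, "CDC_like", p.bit_score, p.is_partial)
            for p in plans
        )
        truth_rows.append(
            {
                "genome_id": genome_id,
                "element_id": f"{genome_id}_{contig_id}",
                "kind": "decoy",
                "detail": kind,
                "gene_ids": ",".join(p.gene_id for p in plans),
                "expected": expected,
            }
        )

    # lone high-scoring SpII genes: reported as singletons, never loci
    for si in range(spec.decoy_singletons):
        genome_id = f"g{(si * 7) % spec.n_genomes:03d}"
        contig_id = f"s{si}"
        plan = _GenePlan(
            gene_id=f"{genome_id}_{contig_id}_0",
            protein=make_protein(400, "SpII", rng),
            strand="+",
            offset_gap=0,
            bit_score=score(),
        )
        contig, contig_genes = _lay_contig(
            genome_id, contig_id, [plan], rng, spec.margin
        )
        contigs[genome_id].append(contig)
        genes.extend(contig_genes)
        hits.append(HitTableRow(plan.gene_id, "CDC_like", plan.bit_score))
        truth_rows.append(
            {
                "genome_id": genome_id,
                "element_id": f"{genome_id}_{contig_id}",
                "kind": "singleton",
                "detail": "lone_gene",
                "gene_ids": plan.gene_id,
                "expected": "singletons",
            }
        )

    return SyntheticGenomes(
        contigs=contigs,
        genes=genes,
        hits=hits,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# controlled-identity mutants and read simulation
# ---------------------------------------------------------------------------


def mutate_sequence(seq: str, target_identity: float, seed: int) -> str:
    """Substitute ``round((1 - target) * len)`` positions, each to a
    different residue, chosen without replacement; realised ungapped
    identity equals the target within 1/len."""
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    n_sub = round((1.0 - target_identity) * len(seq))
    if n_sub == 0:
        return seq
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        choices = AMINO_ACIDS.replace(out[pos], "")
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_reads(
    ref: ReferenceSeq | str, spec: ReadSimSpec
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Uniform substitution-only shotgun reads over one reference.

    ``n_reads = round(target_depth * ref_len / read_length)``; start
    positions uniform on the valid range (reads never overhang), strands
    Bernoulli(0.5), substitution errors i.i.d. per base. Returns the reads
    and a truth table of (read_id, start, strand, n_subs).
    """
    sequence = ref.sequence if isinstance(ref, ReferenceSeq) else ref
    length = len(sequence)
    if spec.read_length > length:
        raise ValueError("read_length exceeds reference length")
    rng = np.random.default_rng(spec.seed)
    n_reads = round(spec.target_depth * length / spec.read_length)
    reads: list[tuple[str, str]] = []
    truth_rows = []
    for i in range(n_reads):
        start = int(rng.integers(0, length - spec.read_length + 1))
        fragment = sequence[start : start + spec.read_length]
        n_subs = 0
        if spec.substitution_rate > 0:
            frag = list(fragment)
            errs = rng.random(spec.read_length) < spec.substitution_rate
            for pos in np.flatnonzero(errs):
                frag[pos] = _BASES.replace(frag[pos].upper(), "")[
                    rng.integers(3)
                ]
                n_subs += 1
            fragment = "".join(frag)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = revcomp(fragment)
        read_id = f"read_{i:06d}"
        reads.append((read_id, fragment))
        truth_rows.append(
            {"read_id": read_id, "start": start, "strand": strand, "n_subs": n_subs}
        )
    return reads, pd.DataFrame(truth_rows)
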