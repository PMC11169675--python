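"""Discovery of multi-component CDC-like (CDCL) toxin loci.

Bacteroidota genomes frequently encode CDC/MACPF-family pore-forming
proteins as pairs or triplets of adjacent, co-oriented genes whose products
carry lipoprotein (SpII) signal peptides. This module turns HMM hits plus
gene annotations into candidate loci through a filter funnel:

1. ``filter_candidates`` — keep hits at or above the family gathering
   threshold (25 bits), drop partial proteins, apply a protein-length
   sanity window;
2. ``classify_signal_peptide`` / ``rescue_spii`` — call SpII lipoprotein
   signal peptides with a lipobox heuristic, then rescue near-misses with
   the [SA]C-in-the-first-35-residues dipeptide scan;
3. ``group_adjacent`` — maximal runs of candidates on one contig and
   strand with bounded intergenic gaps; runs of one are singletons;
4. ``prune_loci`` — remove non-SpII genes, drop loci orphaned below two
   genes, and drop loci touching a contig edge (assembly artefacts).

Every stage's output gene set is a subset of its input (funnel
monotonicity), and pairing is a partition of the retained candidates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .formats_io import GeneRecord, HitTableRow

# Kyte-Doolittle hydropathy index, used to require a hydrophobic h-region
# upstream of the lipobox.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

LIPOBOX_RE = re.compile(r"[LVI][ASTVI][GAS]C")
RESCUE_RE = re.compile(r"[SA]C")

#: the rescue scan covers "the first 35 amino acids": 0-based indices 0..34,
#: i.e. the lipobox cysteine may sit at index <= 34
RESCUE_WINDOW = 35

DEFAULT_MIN_BITSCORE = 25.0  # Pfam gathering threshold for the family HMM
DEFAULT_LEN_WINDOW = (100, 700)  # aa; observed family range is 117-674 aa
DEFAULT_MAX_GAP = 5000  # bp; permissive operon-scale intergenic distance
DEFAULT_MAX_RUN = 3  # pairs and triplets are the biological unit


@dataclass(frozen=True)
class SignalCall:
    """Signal-peptide classification of one protein.

    ``category`` is one of ``SpII`` (lipobox heuristic satisfied), ``SpI``
    (secretory signal, A-X-A fallback), ``None`` (no signal) or
    ``RescuedSpII`` ([SA]C dipeptide in the first 35 residues of a protein
    the lipobox heuristic missed). ``lipobox_cys_pos`` is the 0-based index
    of the (putative) lipid-anchored cysteine for the SpII categories.
    """

    category: str
    lipobox_cys_pos: int | None = None
    evidence: str = ""

    SPII_CATEGORIES = frozenset({"SpII", "RescuedSpII"})

    @property
    def is_spii(self) -> bool:
        return self.category in self.SPII_CATEGORIES


@dataclass(frozen=True)
class CdclCandidate:
    """A gene that passed hit filtering, with its bit score and signal call."""

    gene: GeneRecord
    bit_score: float
    signal_call: SignalCall | None = None


@dataclass(frozen=True)
class CdclLocus:
    """An ordered run of 2-3 adjacent co-oriented CDCL genes on one contig.

    Genes are stored in ascending genomic-start order regardless of strand;
    strand-relative (5'->3') order is computed on demand by the pattern
    stage.
    """

    genome_id: str
    contig_id: str
    genes: tuple[CdclCandidate, ...]
    strand: str
    max_internal_gap: int

    def __post_init__(self) -> None:
        if not 2 <= len(self.genes) <= 3:
            raise ValueError(f"locus must have 2-3 genes, got {len(self.genes)}")
        if any(c.gene.strand != self.strand for c in self.genes):
            raise ValueError("locus genes must share one strand")
        if any(c.gene.contig_id != self.contig_id for c in self.genes):
            raise ValueError("locus genes must share one contig")
        starts = [c.gene.start for c in self.genes]
        if starts != sorted(starts):
            raise ValueError("locus genes must be sorted by start")

    @property
    def start(self) -> int:
        return self.genes[0].gene.start

    @property
    def end(self) -> int:
        return self.genes[-1].gene.end

    @property
    def locus_id(self) -> str:
        return f"{self.genome_id}:{self.contig_id}:{self.start}-{self.end}"

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(c.gene.gene_id for c in self.genes)


# ---------------------------------------------------------------------------
# stage 1: hit filtering
# ---------------------------------------------------------------------------


def filter_candidates(
    hits: Iterable[HitTableRow],
    genes: Iterable[GeneRecord],
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    len_window: tuple[int, int] = DEFAULT_LEN_WINDOW,
) -> list[CdclCandidate]:
    """Apply the score / partial / length filter to HMM hits.

    A hit is retained iff ``bit_score >= min_bitscore`` (boundary
    inclusive), it is not flagged partial, and the protein length falls in
    ``len_window`` (inclusive on both ends). Each protein keeps its single
    best-scoring hit. A hit whose protein_id resolves to no gene is a hard
    error.
    """
    by_id = {g.gene_id: g for g in genes}
    best: dict[str, HitTableRow] = {}
    for hit in hits:
        if hit.protein_id not in by_id:
            raise KeyError(
                f"hit protein_id {hit.protein_id!r} does not resolve to any gene"
            )
        prev = best.get(hit.protein_id)
        if prev is None or hit.bit_score > prev.bit_score:
            best[hit.protein_id] = hit

    lo, hi = len_window
    out = []
    for pid, hit in best.items():
        gene = by_id[pid]
        if hit.is_partial:
            continue
        if hit.bit_score < min_bitscore:
            continue
        if not lo <= gene.protein_len <= hi:
            continue
        out.append(CdclCandidate(gene=gene, bit_score=hit.bit_score))
    out.sort(key=lambda c: (c.gene.genome_id, c.gene.contig_id, c.gene.start))
    return out


# ---------------------------------------------------------------------------
# stage 2: signal-peptide classification
# ---------------------------------------------------------------------------


def _mean_hydropathy(segment: str) -> float:
    vals = [KYTE_DOOLITTLE.get(a, 0.0) for a in segment]
    return sum(vals) / len(vals) if vals else 0.0


def _find_lipobox(seq: str) -> int | None:
    """Return the 0-based cysteine index of the first lipobox motif whose
    cysteine lies at index 10-34, or None. Motif occurrence only; the
    h-region and n-region charge requirements are checked by the caller."""
    for i in range(7, min(len(seq) - 3, 32)):  # cys = i + 3 in [10, 34]
        if LIPOBOX_RE.fullmatch(seq[i : i + 4]):
            cys = i + 3
            if 10 <= cys <= 34:
                return cys
    return None


def classify_signal_peptide(protein_seq: str) -> SignalCall:
    """Heuristic lipoprotein (SpII) signal-peptide call.

    SpII requires a lipobox ``[LVI][ASTVI][GAS]C`` with the cysteine at
    0-based index 10-34, a hydrophobic h-region (mean Kyte-Doolittle
    hydropathy of the 8 residues preceding the lipobox > 0) and a basic
    n-region (at least one K/R among residues 1-7). The SpI fallback looks
    for an A-X-A cleavage motif at index 15-30 behind a hydrophobic
    stretch, with the same basic n-region requirement and no lipobox.
    Sequences shorter than 20 aa are uncallable.
    """
    if len(protein_seq) < 20:
        return SignalCall(category="None", evidence="too_short")

    n_region_basic = any(a in "KR" for a in protein_seq[1:8])
    for i in range(7, min(len(protein_seq) - 3, 32)):
        if not LIPOBOX_RE.fullmatch(protein_seq[i : i + 4]):
            continue
        cys = i + 3
        if not 10 <= cys <= 34:
            continue
        if i < 8:
            continue
        if _mean_hydropathy(protein_seq[i - 8 : i]) > 0 and n_region_basic:
            return SignalCall(category="SpII", lipobox_cys_pos=cys, evidence="lipobox")

    # SpI fallback: A-X-A at index 15-30 with a hydrophobic stretch before
    # it, a basic n-region, and no lipobox motif anywhere in the window
    if n_region_basic and _find_lipobox(protein_seq) is None:
        for i in range(15, min(len(protein_seq) - 2, 31)):
            if (
                protein_seq[i] == "A"
                and protein_seq[i + 2] == "A"
                and _mean_hydropathy(protein_seq[i - 8 : i]) > 0
            ):
                return SignalCall(category="SpI", evidence="axa_motif")
    return SignalCall(category="None", evidence="no_motif")


def rescue_spii(protein_seq: str) -> bool:
    """Second-pass rescue: does ``[SA]C`` occur in the first 35 residues?

    True iff an S or A immediately followed by a cysteine lies entirely
    within 0-based indices 0..34. Applied only to proteins the lipobox
    heuristic did not already call SpII.
    """
    return RESCUE_RE.search(protein_seq[:RESCUE_WINDOW]) is not None


def apply_signal_calls(
    candidates: Iterable[CdclCandidate],
    call_table: Mapping[str, str] | None = None,
) -> list[CdclCandidate]:
    """Attach a SignalCall to every candidate.

    With ``call_table`` (protein_id -> category, e.g. ingested from an
    external signal-peptide predictor) the category is used verbatim; else the
    built-in heuristic runs. In both paths, candidates not called SpII are
    re-examined by the [SA]C rescue scan and promoted to RescuedSpII on a
    match.
    """
    out = []
    for cand in candidates:
        seq = cand.gene.protein_seq
        if call_table is not None:
            cat = call_table.get(cand.gene.gene_id, "None")
            call = SignalCall(category=cat, evidence="table")
        else:
            call = classify_signal_peptide(seq)
        if call.category != "SpII" and rescue_spii(seq):
            m = RESCUE_RE.search(seq[:RESCUE_WINDOW])
            assert m is not None
            call = SignalCall(
                category="RescuedSpII",
                lipobox_cys_pos=m.start() + 1,
                evidence="rescue_regex",
            )
        out.append(replace(cand, signal_call=call))
    return out


# ---------------------------------------------------------------------------
# stage 3: adjacency grouping
# ---------------------------------------------------------------------------


def group_adjacent(
    candidates: Iterable[CdclCandidate],
    max_gap: int = DEFAULT_MAX_GAP,
    max_run: int = DEFAULT_MAX_RUN,
) -> tuple[list[CdclLocus], list[CdclCandidate]]:
    """Group candidates into maximal same-contig, same-strand adjacency runs.

    Consecutive candidates on one contig and strand belong to the same run
    when the intergenic gap ``next.start - prev.end`` is at most
    ``max_gap`` (overlapping genes count as gap 0). Runs of one gene are
    returned separately as singletons; runs longer than ``max_run`` keep
    the first ``max_run`` genes by coordinate (extras become singletons,
    with a warning).

    Returns ``(loci, singletons)``, loci sorted by genome, contig, start.
    """
    loci: list[CdclLocus] = []
    singletons: list[CdclCandidate] = []

    groups: dict[tuple[str, str, str], list[CdclCandidate]] = {}
    for cand in candidates:
        key = (cand.gene.genome_id, cand.gene.contig_id, cand.gene.strand)
        groups.setdefault(key, []).append(cand)

    for (genome_id, contig_id, strand), members in sorted(groups.items()):
        members.sort(key=lambda c: c.gene.start)
        run: list[CdclCandidate] = [members[0]]
        runs: list[list[CdclCandidate]] = []
        for cand in members[1:]:
            gap = max(0, cand.gene.start - run[-1].gene.end)
            if gap <= max_gap:
                run.append(cand)
            else:
                runs.append(run)
                run = [cand]
        runs.append(run)

        for run in runs:
            if len(run) == 1:
                singletons.append(run[0])
                continue
            if len(run) > max_run:
                warnings.warn(
                    f"{genome_id}/{contig_id}: adjacency run of {len(run)} "
                    f"genes truncated to {max_run}"
                )
                singletons.extend(run[max_run:])
                run = run[:max_run]
            gaps = [
                max(0, b.gene.start - a.gene.end) for a, b in zip(run, run[1:])
            ]
            loci.append(
                CdclLocus(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    genes=tuple(run),
                    strand=strand,
                    max_internal_gap=max(gaps),
                )
            )

    loci.sort(key=lambda l: (l.genome_id, l.contig_id, l.start))
    singletons.sort(key=lambda c: (c.gene.genome_id, c.gene.contig_id, c.gene.start))
    return loci, singletons


# ---------------------------------------------------------------------------
# stage 4: orphan / defect pruning
# ---------------------------------------------------------------------------


def prune_loci(
    loci: Iterable[CdclLocus],
    contig_lengths: Mapping[tuple[str, str], int] | None = None,
) -> list[CdclLocus]:
    """Remove non-SpII genes, orphaned loci and contig-edge artefacts.

    1. genes whose signal category is neither SpII nor RescuedSpII are
       removed from their locus;
    2. loci reduced below 2 genes are dropped (the remaining gene is
       orphaned);
    3. loci containing a gene whose interval touches a contig boundary
       (``start == 0`` or ``end == contig length``) are dropped — such
       genes are likely truncated by the assembly.

    ``contig_lengths`` maps ``(genome_id, contig_id)`` to contig length;
    when None, the boundary rule is skipped.
    """
    out: list[CdclLocus] = []
    for locus in loci:
        kept = [
            c
            for c in locus.genes
            if c.signal_call is not None and c.signal_call.is_spii
        ]
        if len(kept) < 2:
            continue
        if contig_lengths is not None:
            length = contig_lengths.get((locus.genome_id, locus.contig_id))
            if length is not None and any(
                c.gene.start == 0 or c.gene.end == length for c in kept
            ):
                continue
        gaps = [max(0, b.gene.start - a.gene.end) for a, b in zip(kept, kept[1:])]
        out.append(
            CdclLocus(
                genome_id=locus.genome_id,
                contig_id=locus.contig_id,
                genes=tuple(kept),
                strand=locus.strand,
                max_internal_gap=max(gaps),
            )
        )
    return out


# ---------------------------------------------------------------------------
# end-to-end funnel
# ---------------------------------------------------------------------------


@dataclass
class MineResult:
    loci: list[CdclLocus]
    singletons: list[CdclCandidate]
    funnel: dict[str, int] = field(default_factory=dict)


def mine(
    hits: Iterable[HitTableRow],
    genes: Iterable[GeneRecord],
    contig_lengths: Mapping[tuple[str, str], int] | None = None,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    len_window: tuple[int, int] = DEFAULT_LEN_WINDOW,
    max_gap: int = DEFAULT_MAX_GAP,
    max_run: int = DEFAULT_MAX_RUN,
    signal_table: Mapping[str, str] | None = None,
) -> MineResult:
    """Run the whole discovery funnel and report per-stage counts."""
    hits = list(hits)
    genes = list(genes)
    candidates = filter_candidates(hits, genes, min_bitscore, len_window)
    candidates = apply_signal_calls(candidates, call_table=signal_table)
    loci, singletons = group_adjacent(candidates, max_gap=max_gap, max_run=max_run)
    pruned = prune_loci(loci, contig_lengths)
    funnel = {
        "n_hits": len(hits),
        "n_candidates": len(candidates),
        "n_spii": sum(
            1 for c in candidates if c.signal_call and c.signal_call.is_spii
        ),
        "n_loci_prefilter": len(loci),
        "n_singletons": len(singletons),
        "n_loci": len(pruned),
        "n_genes_in_loci": sum(len(l.genes) for l in pruned),
    }
    return MineResult(loci=pruned, singletons=singletons, funnel=funnel)
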