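"""Protein clustering at a percent-identity threshold and locus patterns.

CDCL proteins from discovered loci are binned at >= 96% global identity
(greedy, representative-based, CD-HIT-style), and each locus is summarised
as an ordered tuple of cluster labels in strand-relative 5'->3' order — its
"pattern". Pairs come in two flavours: a small-subunit/large-subunit pair
(archetype ~365 aa CDCL-S upstream of ~500 aa CDCL-L) or a similar-sized
pair; triplets are typed gene-by-gene against the length extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .locus_discovery import CdclLocus

DEFAULT_IDENTITY_THRESHOLD = 0.96


@dataclass(frozen=True)
class IdentityResult:
    """Global percent identity between two protein sequences."""

    seq_a_id: str
    seq_b_id: str
    identity: float
    aligned_cols: int


@dataclass
class Cluster:
    """A >= threshold-identity protein bin around a representative."""

    cluster_id: int
    representative_id: str
    member_ids: list[str]


@dataclass(frozen=True)
class SizeClassConfig:
    """Length-ratio rule separating S+L pairs from similar-sized pairs.

    The archetype small/large subunit lengths are ~365 aa and ~500 aa
    (ratio 0.73), which must classify as "different"; 0.85 leaves margin on
    both sides. Reference lengths are annotations only.
    """

    similar_ratio_min: float = 0.85
    small_ref_aa: int = 365
    large_ref_aa: int = 500

    def __post_init__(self) -> None:
        if not 0 < self.similar_ratio_min <= 1:
            raise ValueError("similar_ratio_min must be in (0, 1]")


@dataclass(frozen=True)
class LocusTyping:
    """Strand-relative typing of one locus."""

    locus_type: str  # "S+L pair" | "similar-sized pair" | "triplet"
    size_classes: tuple[str, ...]  # per-gene, strand-relative 5'->3'
    gene_ids_5p: tuple[str, ...]
    anomalous: bool = False  # upstream-larger pair


@dataclass
class PatternGroup:
    """All loci sharing one ordered cluster signature."""

    pattern_id: int
    signature: tuple[tuple[int, str], ...]  # (cluster_id, size_class) 5'->3'
    locus_ids: list[str]
    locus_type: str
    genomes: list[str] = field(default_factory=list)


def _make_aligner() -> Align.PairwiseAligner:
    # identity substitution model: match +1, mismatch 0; affine gaps -10/-0.5
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-10,
        extend_gap_score=-0.5,
    )
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(
    a: str,
    b: str,
    seq_a_id: str = "a",
    seq_b_id: str = "b",
    denominator: str = "alignment_cols",
) -> IdentityResult:
    """Global-alignment percent identity between two protein sequences.

    The alignment uses an identity substitution model (match +1, mismatch
    0) with affine gaps (open -10, extend -0.5). Identity is identical
    aligned residue pairs divided by either the total alignment columns
    (terminal gaps included; default) or the shorter sequence length,
    selected by ``denominator``.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if denominator not in {"alignment_cols", "shorter_seq"}:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    cols = aln.length
    denom = cols if denominator == "alignment_cols" else min(len(a), len(b))
    return IdentityResult(
        seq_a_id=seq_a_id,
        seq_b_id=seq_b_id,
        identity=counts.identities / denom,
        aligned_cols=cols,
    )


def greedy_cluster(
    seqs: Mapping[str, str],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    denominator: str = "alignment_cols",
) -> list[Cluster]:
    """Greedy single-pass representative clustering (CD-HIT style).

    Sequences are processed in decreasing-length order (ties broken by id);
    each joins the first existing cluster (creation order) whose
    representative identity is >= ``threshold``, else founds a new cluster
    with itself as representative. With a 96% threshold and well-separated
    families the resulting partition is insensitive to the greedy order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    clusters: list[Cluster] = []
    for seq_id in order:
        seq = seqs[seq_id]
        for cluster in clusters:
            ident = pairwise_identity(
                seqs[cluster.representative_id],
                seq,
                cluster.representative_id,
                seq_id,
                denominator=denominator,
            ).identity
            if ident >= threshold:
                cluster.member_ids.append(seq_id)
                break
        else:
            clusters.append(
                Cluster(
                    cluster_id=len(clusters) + 1,
                    representative_id=seq_id,
                    member_ids=[seq_id],
                )
            )
    return clusters


def genes_in_5p_order(locus: CdclLocus):
    """Locus genes reordered strand-relative so the upstream gene is first."""
    genes = list(locus.genes)
    if locus.strand == "-":
        genes.reverse()
    return genes


def assign_locus_type(
    locus: CdclLocus, cfg: SizeClassConfig = SizeClassConfig()
) -> LocusTyping:
    """Type a locus by the lengths of its strand-relative gene order.

    Pairs whose length ratio (min/max) is >= ``similar_ratio_min`` are
    similar-sized (both genes class "M"); otherwise the shorter gene is "S"
    and the longer "L", with the canonical architecture having S upstream
    (an upstream-larger pair is kept but flagged anomalous). Triplet genes
    are labelled S if within the ratio of the shortest gene, L if within
    the ratio of the longest, else M — a heuristic generalisation of the
    pair rule.
    """
    genes = genes_in_5p_order(locus)
    lengths = [c.gene.protein_len for c in genes]
    gene_ids = tuple(c.gene.gene_id for c in genes)
    lo, hi = min(lengths), max(lengths)
    r = cfg.similar_ratio_min

    if len(genes) == 2:
        if lo / hi >= r:
            return LocusTyping("similar-sized pair", ("M", "M"), gene_ids)
        classes = tuple("S" if n == lo else "L" for n in lengths)
        return LocusTyping(
            "S+L pair", classes, gene_ids, anomalous=(classes[0] == "L")
        )

    if lo / hi >= r:
        classes: tuple[str, ...] = ("M",) * len(genes)
    else:
        labelled = []
        for n in lengths:
            if lo / n >= r:
                labelled.append("S")
            elif n / hi >= r:
                labelled.append("L")
            else:
                labelled.append("M")
        classes = tuple(labelled)
    return LocusTyping("triplet", classes, gene_ids)


def derive_patterns(
    loci: Iterable[CdclLocus],
    clusters: Iterable[Cluster],
    cfg: SizeClassConfig = SizeClassConfig(),
) -> list[PatternGroup]:
    """Group loci by their ordered (strand-relative) cluster signature.

    Each locus gene must belong to exactly one cluster; a gene absent from
    all clusters is a hard error. Pattern ids are assigned by decreasing
    group size, ties broken by lexicographic signature.
    """
    member_to_cluster: dict[str, int] = {}
    for cluster in clusters:
        for member in cluster.member_ids:
            if member in member_to_cluster:
                raise ValueError(f"gene {member!r} appears in two clusters")
            member_to_cluster[member] = cluster.cluster_id

    groups: dict[tuple[int, ...], list[tuple[CdclLocus, LocusTyping]]] = {}
    for locus in loci:
        typing = assign_locus_type(locus, cfg)
        key = []
        for gid in typing.gene_ids_5p:
            if gid not in member_to_cluster:
                raise KeyError(f"locus gene {gid!r} is absent from all clusters")
            key.append(member_to_cluster[gid])
        groups.setdefault(tuple(key), []).append((locus, typing))

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    patterns = []
    for pattern_id, (key, members) in enumerate(ordered, start=1):
        first_typing = members[0][1]
        patterns.append(
            PatternGroup(
                pattern_id=pattern_id,
                signature=tuple(zip(key, first_typing.size_classes)),
                locus_ids=[locus.locus_id for locus, _ in members],
                locus_type=first_typing.locus_type,
                genomes=sorted({locus.genome_id for locus, _ in members}),
            )
        )
    return patterns
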