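"""Competitive read mapping and locus presence calling in metagenomes.

Reads are mapped against all reference loci simultaneously; an ambiguous
read (matching more than one reference) is assigned to its single best
match and counted once. A reference is called present in a sample when it
is covered over at least 75% of its length, by at least 20 assigned reads,
at an average depth of at least five-fold per reference base — all
thresholds inclusive.

The aligner is a deliberately simple exact k-mer seed + ungapped extension
scheme: presence calling, not alignment fidelity, is the computation being
reproduced, so indels are out of scope and the companion read simulator
generates substitution-only errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .locus_discovery import CdclLocus

DEFAULT_K = 21
DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MIN_BREADTH = 0.75
DEFAULT_MIN_READS = 20
DEFAULT_MIN_DEPTH = 5.0

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSeq:
    """One nucleotide reference: the DNA spanning a locus's CDCL genes."""

    ref_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadAssignment:
    """Best-match assignment of one read to one reference (or none)."""

    read_id: str
    ref_id: str | None
    ref_start: int = 0
    matches: int = 0
    aln_len: int = 0
    strand: str = "+"


@dataclass(frozen=True)
class CoverageStats:
    """Per-reference breadth / read-count / depth summary.

    ``breadth`` is the fraction of reference positions with depth >= 1;
    ``mean_depth`` averages over all reference positions, covered or not.
    """

    ref_id: str
    ref_len: int
    breadth: float
    n_reads: int
    mean_depth: float


@dataclass(frozen=True)
class PresenceCall:
    ref_id: str
    present: bool
    stats: CoverageStats
    min_breadth: float = DEFAULT_MIN_BREADTH
    min_reads: int = DEFAULT_MIN_READS
    min_depth: float = DEFAULT_MIN_DEPTH


def build_locus_reference(contig_sequence: str, locus: CdclLocus) -> ReferenceSeq:
    """Extract the DNA spanning a locus, from its first gene's start to its
    last gene's end (intergenic DNA included, flanks excluded)."""
    return ReferenceSeq(
        ref_id=locus.locus_id, sequence=contig_sequence[locus.start : locus.end]
    )


def _build_index(
    refs: Sequence[ReferenceSeq], k: int
) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ref_idx, ref in enumerate(refs):
        seq = ref.sequence.upper()
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((ref_idx, pos))
    return index


def _ungapped_score(
    read: str, ref_seq: str, ref_start: int
) -> tuple[int, int, int]:
    """(matches, aln_len, clipped_start) of the read laid at ref_start,
    truncated at the reference ends."""
    lo = max(0, ref_start)
    hi = min(len(ref_seq), ref_start + len(read))
    if hi <= lo:
        return 0, 0, lo
    read_segment = read[lo - ref_start : hi - ref_start]
    ref_segment = ref_seq[lo:hi]
    matches = sum(a == b for a, b in zip(read_segment, ref_segment))
    return matches, hi - lo, lo


def map_reads(
    reads: Iterable[tuple[str, str]],
    refs: Sequence[ReferenceSeq],
    k: int = DEFAULT_K,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[ReadAssignment]:
    """Competitive best-match mapping of reads against all references.

    Each read (both orientations) is seeded by exact k-mers against a
    forward index of all references and extended ungapped to the full read
    length (truncated at reference ends). The candidate with the most
    matching bases wins; ties are broken by lowest reference index, then
    leftmost position, then forward orientation — so an ambiguous read is
    deterministically counted once. Candidates below ``min_identity``
    (matches / aligned length) leave the read unassigned.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    usable = [r for r in refs if len(r) >= k]
    for r in refs:
        if len(r) < k:
            warnings.warn(f"reference {r.ref_id} shorter than k={k}; excluded")
    index = _build_index(usable, k)
    ref_seqs = [r.sequence.upper() for r in usable]

    assignments: list[ReadAssignment] = []
    for read_id, seq in reads:
        seq = seq.upper()
        best: tuple[int, int, int, int, int, str] | None = None
        # sort key: (-matches, ref_idx, ref_start, strand_rank)
        for strand_rank, (strand, oriented) in enumerate(
            (("+", seq), ("-", revcomp(seq)))
        ):
            if len(oriented) < k:
                continue
            candidates: set[tuple[int, int]] = set()
            for offset in range(len(oriented) - k + 1):
                for ref_idx, pos in index.get(oriented[offset : offset + k], ()):
                    candidates.add((ref_idx, pos - offset))
            for ref_idx, ref_start in sorted(candidates):
                matches, aln_len, clipped = _ungapped_score(
                    oriented, ref_seqs[ref_idx], ref_start
                )
                if aln_len == 0 or matches / aln_len < min_identity:
                    continue
                key = (-matches, ref_idx, clipped, strand_rank)
                if best is None or key < best[:4]:
                    best = (*key, aln_len, strand)
        if best is None:
            assignments.append(ReadAssignment(read_id=read_id, ref_id=None))
        else:
            neg_matches, ref_idx, clipped, _rank, aln_len, strand = best
            assignments.append(
                ReadAssignment(
                    read_id=read_id,
                    ref_id=usable[ref_idx].ref_id,
                    ref_start=clipped,
                    matches=-neg_matches,
                    aln_len=aln_len,
                    strand=strand,
                )
            )
    return assignments


def coverage_stats(
    assignments: Iterable[ReadAssignment], ref: ReferenceSeq
) -> CoverageStats:
    """Accumulate per-base depth for one reference and summarise it.

    Depth is added over ``[ref_start, ref_start + aln_len)``; intervals
    exceeding the reference end are truncated with a warning. ``breadth``
    is covered positions / reference length; ``mean_depth`` is total
    aligned bases / reference length.
    """
    length = len(ref)
    depth = np.zeros(length, dtype=np.int64)
    n_reads = 0
    for a in assignments:
        if a.ref_id != ref.ref_id:
            continue
        n_reads += 1
        lo = max(0, a.ref_start)
        hi = a.ref_start + a.aln_len
        if hi > length:
            warnings.warn(
                f"assignment of {a.read_id} exceeds {ref.ref_id} end; truncated"
            )
            hi = length
        if hi > lo:
            depth[lo:hi] += 1
    return CoverageStats(
        ref_id=ref.ref_id,
        ref_len=length,
        breadth=float(np.count_nonzero(depth)) / length,
        n_reads=n_reads,
        mean_depth=float(depth.sum()) / length,
    )


def call_presence(
    stats: CoverageStats,
    min_breadth: float = DEFAULT_MIN_BREADTH,
    min_reads: int = DEFAULT_MIN_READS,
    min_depth: float = DEFAULT_MIN_DEPTH,
) -> PresenceCall:
    """Three-threshold presence decision, every threshold inclusive (>=)."""
    present = (
        stats.breadth >= min_breadth
        and stats.n_reads >= min_reads
        and stats.mean_depth >= min_depth
    )
    return PresenceCall(
        ref_id=stats.ref_id,
        present=present,
        stats=stats,
        min_breadth=min_breadth,
        min_reads=min_reads,
        min_depth=min_depth,
    )


def _percent_1dp(n_detected: int, n_samples: int) -> float:
    """100 * n/N rounded to one decimal, half away from zero."""
    frac = Decimal(100 * n_detected) / Decimal(n_samples)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def prevalence_report(
    calls: Mapping[str, Mapping[str, "PresenceCall | bool"]],
) -> pd.DataFrame:
    """Per-pattern detection counts across samples.

    ``calls`` maps sample -> pattern -> presence (a PresenceCall or plain
    bool); every sample must carry an entry for every pattern. A pattern
    counts as detected in a sample if any of its reference loci is present.
    Returns a DataFrame with columns pattern, n_detected, n_samples,
    percent (one decimal, round half away from zero).
    """
    if not calls:
        raise ValueError("prevalence_report requires at least one sample")
    samples = list(calls)
    patterns = sorted(calls[samples[0]])
    for sample in samples:
        if sorted(calls[sample]) != patterns:
            raise ValueError(
                f"sample {sample!r} was not evaluated for every pattern"
            )
    rows = []
    n_samples = len(samples)
    for pattern in patterns:
        n_detected = 0
        for sample in samples:
            call = calls[sample][pattern]
            present = call.present if isinstance(call, PresenceCall) else bool(call)
            n_detected += present
        rows.append(
            {
                "pattern": pattern,
                "n_detected": n_detected,
                "n_samples": n_samples,
                "percent": _percent_1dp(n_detected, n_samples),
            }
        )
    return pd.DataFrame(rows)
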