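# Methods

This note documents the models, heuristics and numerical choices behind
`cdclmine`, and what its synthetic-data tests do and do not demonstrate.

## Locus discovery

The discovery funnel operationalises a simple biological model: a
functional multi-component CDCL toxin locus is 2–3 CDC/MACPF-family genes
that are *adjacent*, *co-oriented*, and encode *surface-exposed
lipoproteins* (SpII signal peptides), on a contig that is intact around
them.

Parameters, with defaults and rationale:

| parameter | default | units | why |
|---|---|---|---|
| `min_bitscore` | 25 | bits | the Pfam gathering threshold of the family HMM; inclusive (≥) |
| `len_window` | (100, 700) | aa | generous envelope around the observed 117–674 aa family range |
| `max_gap` | 5000 | bp | "near each other" is not defined operationally anywhere we could adopt it from; co-transcribed genes sit within a few hundred bp, and 5 kb is permissive without merging unrelated operons. Configurable. |
| `max_run` | 3 | genes | pairs and triplets are the biological unit; longer runs are truncated to the first 3 genes by coordinate with a warning — they are anomalies to surface, not to crash on |

Intervals are 0-based half-open internally; GFF3 I/O converts at the
boundary, so gap arithmetic has no off-by-one cases. Overlapping genes
count as gap 0 (overlapping ORFs are common in operons). Loci and genes
are always stored in genomic-coordinate order; strand-relative order is
derived on demand.

"Partial protein" has two machine-statable readings and both are honored:
a partial flag in the hit table (dropped at the filter stage) and a gene
interval touching a contig boundary (`start == 0` or `end == contig
length`; the whole locus is dropped at the prune stage, since a truncated
gene makes the locus architecture unknowable).

### Signal-peptide heuristic

A published lipoprotein-signal predictor's HMM parameters are not
reproducible from its description, so SpII calling is a documented
heuristic: a lipobox `[LVI][ASTVI][GAS]C` whose cysteine lies at 0-based
index 10–34, a hydrophobic h-region (mean Kyte–Doolittle hydropathy of
the 8 residues preceding the lipobox > 0), and a basic n-region (≥ 1 K/R
among residues 1–7). An ingestion path (`signal_table`) accepts a
precomputed per-protein call table for users who run an external
predictor.

The SpI fallback (A-X-A motif starting at index 15–30 behind a
hydrophobic stretch, same basic-n-region requirement, no lipobox) exists
only for reporting parity; downstream, only the SpII/non-SpII boundary
matters. The basic-n-region requirement is applied to SpI as well as
SpII — without it, low-complexity sequences (e.g. poly-alanine) would be
spuriously called secretory.

The rescue scan is exactly the dipeptide regular expression `[SA]C`
applied to the first 35 residues (cysteine index ≤ 34), applied only to
proteins not already called SpII. Its property test and acceptance check
compare it against a brute-force enumeration of all windows.

## Clustering and patterns

Pairwise identity is computed from a global alignment under an identity
substitution model (match +1, mismatch 0) with affine gaps (open −10,
extend −0.5; Biopython's convention charges the open score for a gap's
first column). The identity denominator is the number of alignment
columns *including terminal gaps* — the conservative reading of
"protein-level ID" — switchable to `shorter_seq` via
`identity_denominator`.

Clustering is greedy single-pass (CD-HIT style): sequences in decreasing
length order (ties by id) join the first cluster whose representative
identity is ≥ 0.96, else found a new cluster. A full multiple-alignment
workflow would be another defensible choice; at a 96% threshold with
well-separated families the partition is insensitive to this, which the
property suite checks directly (98%-identity mutants co-cluster, 90% do
not — the 0.90/0.98 margin absorbs alignment noise around the 0.96
boundary).

Size classes: a pair is "similar-sized" when min/max length ≥ 0.85 — a
threshold placed between the archetype S+L ratio (365/500 = 0.73, which
must read "different") and 1. Triplet genes are labelled S if within the
ratio of the shortest gene, L if within the ratio of the longest, else M;
this is a heuristic generalisation and is flagged as such in outputs.
Patterns group loci by the ordered tuple of cluster ids in strand-relative
5′→3′ order; pattern ids are assigned by decreasing group size, ties by
lexicographic signature, so numbering is deterministic and
input-order-invariant.

## Phylogeny

The tree of cluster representatives uses neighbor joining on
1 − identity. NJ was chosen for determinism and desk-scale speed; no
claim is made that its topology matches any published figure built with a
different (unstated) method and alignment. Tie-breaks in the Q-criterion
go to the smallest (i, j) index pair; negative branch-length estimates
are clamped to 0 with a warning; a 2-taxon input returns a single split
edge of d/2 per branch. Correctness is checked two ways: recovery of the
generating topology from path-length (additive) matrices of random 5–8
leaf trees, and topological agreement with scikit-bio's independent NJ
implementation.

## Metagenomic presence

The mapper reproduces competitive best-match semantics: all references
are indexed together (forward strand, exact k = 21 seeds), each read
(both orientations) is extended ungapped to full length, the candidate
with the most matching bases wins, and ties go to the lowest reference
index, then the leftmost position, then the forward orientation — so an
ambiguous read is counted exactly once. Candidates below 95% identity
leave the read unassigned. Indels are deliberately out of scope (the read
simulator generates substitution-only errors): the computation being
reproduced is presence calling, not alignment fidelity.

Presence requires, inclusively: breadth ≥ 0.75, assigned reads ≥ 20, and
mean depth ≥ 5.0× — with mean depth averaged over *all* reference
positions ("per reference base"), and "minimum of 20 reads" read as 20
assigned reads per reference, not per position. Reference sequences span
from the first to the last CDCL gene of a locus, inclusive of intergenic
DNA, exclusive of flanks. Prevalence percentages are rounded to one
decimal, half away from zero. A pattern counts as detected in a sample if
any of its reference loci is present; with one representative locus per
pattern (the default), this coincides with per-reference detection.

## Synthetic data

The generator emulates only the statistical structure the discovery rules
read: genomes are random DNA with back-translated genes (fixed codon
table) placed at controlled gaps and strands; protein bodies are
uniform-random residues behind constructed leaders (SpII-satisfying,
rescue-only, or cysteine-free "none" leaders); qualities are a constant
'I'. Default plant: 50 genomes, one locus each, cycling S+L pairs on both
strands (365/500 aa), a similar-sized pair (336/360 aa), an S/M/L triplet
(350/450/550 aa) and a rescue-leader pair; two decoys of each of the six
violation kinds (score < 25, partial flag, opposite strand, gap 8 kb,
no signal, contig edge) and five lone high-scoring genes, each on its own
contig so every decoy violates exactly one rule.

What passing tests show: the *rules* are implemented exactly as stated —
each decoy falls out at the stage whose rule it breaks, and recovery is
perfect by construction. What they do not show: performance on real
genomes, where gene calling errors, diverged homologs near the score
threshold, fragmented assemblies and genuine biological ambiguity make
precision/recall an empirical question this package cannot answer from
synthetic data.

Read simulation draws `round(depth · L / read_len)` start positions
uniformly on the valid range (reads never overhang), strands
Bernoulli(0.5), substitutions i.i.d. For depth D the realised mean depth
deviates from D by at most ~3·√(D·read_len/L) (Poisson sampling bound),
which is what the presence-flip check at 4.5× vs 5.5× allows for.

## Assay reductions

Geometry estimates round half away from zero (so π·20 = 62.8 → 63 nm and
63/2.1 = 30 monomers reproduce the published values under one stated
convention). The FRET correction subtracts the unlabelled-sample
backgrounds pairwise (DU − U, DA − UA) before forming the percentage, and
is invariant to a common offset applied to a signal and its background —
the property test for the correction algebra. Replicates are corrected
individually and then averaged. PI positivity is strict (">" the
background of 7498 a.u.), per the defining wording. The experimental
saturation of pore activity at ~25–30 small subunits per large subunit is
not modelled; only the geometric consistency estimate (~30 monomers) is
computed.

## Problem sizes

Tests and the acceptance script run on deliberately small instances — 50
synthetic genomes, 3 protein families of 350 aa, 10⁴ random sequences for
the regex equivalence, 10³ random coverage sets, 10² random trees, one
~2.9 kb reference for the presence flip — sizes at which every check
completes in seconds while still exercising each rule and boundary.
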