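import numpy as np
import pytest

from cdclmine import (
    CdclCandidate,
    GeneRecord,
    SignalCall,
    SizeClassConfig,
    assign_locus_type,
    derive_patterns,
    greedy_cluster,
    mutate_sequence,
    pairwise_identity,
)
from cdclmine.locus_discovery import CdclLocus


def _random_protein(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("PEPTIDE", "PEPTIDE", 1.0),
            ("AAAA", "TTTT", 0.0),
            ("ACDEFGHIK", "ACDEFGHIR", 8 / 9),  # single gapless optimum
        ],
    )
    def test_known_values(self, a, b, expected):
        assert pairwise_identity(a, b).identity == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = _random_protein(rng, int(rng.integers(30, 120)))
            b = _random_protein(rng, int(rng.integers(30, 120)))
            assert pairwise_identity(a, b).identity == pytest.approx(
                pairwise_identity(b, a).identity, abs=1e-12
            )

    def test_identity_one_iff_equal(self):
        assert pairwise_identity("MKV", "MKVA").identity < 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MKV")

    def test_shorter_seq_denominator(self):
        res = pairwise_identity("MKVLL", "MKVLLAAAA", denominator="shorter_seq")
        assert res.identity == pytest.approx(1.0)


class TestGreedyCluster:
    def test_identical_sequences_co_cluster(self):
        clusters = greedy_cluster({"a": "MKVL" * 30, "b": "MKVL" * 30})
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == ["a", "b"]

    def test_ninety_percent_pair_splits_at_96(self):
        rng = np.random.default_rng(7)
        base = _random_protein(rng, 200)
        variant = mutate_sequence(base, 0.90, seed=1)
        assert pairwise_identity(base, variant).identity == pytest.approx(0.90, abs=0.01)
        clusters = greedy_cluster({"a": base, "b": variant}, threshold=0.96)
        assert len(clusters) == 2

    def test_threshold_one_is_exact_equality(self):
        seqs = {"a": "MKVLA" * 40, "b": "MKVLC" * 40, "c": "MKVLD" * 40,
                "d": "MKVLA" * 40}
        clusters = greedy_cluster(seqs, threshold=1.0)
        assert len(clusters) == 3
        partition = {frozenset(c.member_ids) for c in clusters}
        assert frozenset({"a", "d"}) in partition

    def test_partition_and_representative_contract(self):
        """Clustering is a partition and every member is >= threshold
        identity to its representative, recomputed independently."""
        rng = np.random.default_rng(21)
        seqs = {}
        for fam in range(4):
            base = _random_protein(rng, 300)
            for v in range(3):
                seqs[f"f{fam}_v{v}"] = mutate_sequence(base, 0.98, seed=fam * 10 + v)
        clusters = greedy_cluster(seqs, threshold=0.96)
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == sorted(seqs)
        for c in clusters:
            assert c.representative_id in c.member_ids
            for m in c.member_ids:
                ident = pairwise_identity(
                    seqs[c.representative_id], seqs[m]
                ).identity
                assert ident >= 0.96

    def test_mutation_margins(self):
        """Families at 98% identity co-cluster at the 96% threshold;
        sequences at 90% identity do not."""
        rng = np.random.default_rng(8)
        base = _random_protein(rng, 400)
        near = {f"n{i}": mutate_sequence(base, 0.98, seed=i) for i in range(3)}
        far = {f"x{i}": mutate_sequence(base, 0.90, seed=100 + i) for i in range(2)}
        clusters = greedy_cluster({"base": base, **near, **far}, threshold=0.96)
        by_member = {m: c.cluster_id for c in clusters for m in c.member_ids}
        assert len({by_member[k] for k in ["base", *near]}) == 1
        for k in far:
            assert by_member[k] != by_member["base"]


def _locus(lengths, strand="+", genome="g0", contig="c1", start=1000,
           prefix="g"):
    genes = []
    pos = start
    for i, aa in enumerate(lengths):
        prot = "MKK" + "L" * 8 + "LAGC" + "G" * (aa - 15)
        gene = GeneRecord(gene_id=f"{prefix}{i}", genome_id=genome,
                          contig_id=contig, start=pos, end=pos + 3 * (aa + 1),
                          strand=strand, protein_seq=prot)
        genes.append(CdclCandidate(gene=gene, bit_score=100.0,
                                   signal_call=SignalCall("SpII", 14)))
        pos = gene.end + 200
    return CdclLocus(genome_id=genome, contig_id=contig, genes=tuple(genes),
                     strand=strand, max_internal_gap=200)


class TestLocusTyping:
    def test_archetype_pair_is_s_plus_l(self):
        typing = assign_locus_type(_locus([365, 500]))
        assert typing.locus_type == "S+L pair"
        assert typing.size_classes == ("S", "L")
        assert not typing.anomalous

    def test_similar_sized_pair(self):
        typing = assign_locus_type(_locus([336, 360]))
        assert typing.locus_type == "similar-sized pair"
        assert typing.size_classes == ("M", "M")

    def test_minus_strand_reverses_to_upstream_first(self):
        # genomic order (500, 365) on '-' strand reads (365, 500) 5'->3'
        typing = assign_locus_type(_locus([500, 365], strand="-"))
        assert typing.size_classes == ("S", "L")
        assert not typing.anomalous

    def test_upstream_larger_pair_flagged(self):
        typing = assign_locus_type(_locus([500, 365]))
        assert typing.anomalous

    def test_triplet_extreme_labelling(self):
        typing = assign_locus_type(_locus([350, 450, 550]))
        assert typing.locus_type == "triplet"
        assert typing.size_classes == ("S", "M", "L")


class TestDerivePatterns:
    def _clusters_for(self, loci):
        from cdclmine.cluster_patterns import Cluster

        # put every gene of equal protein length in one cluster
        by_len = {}
        for locus in loci:
            for c in locus.genes:
                by_len.setdefault(c.gene.protein_len, []).append(c.gene.gene_id)
        return [
            Cluster(cluster_id=i + 1, representative_id=m[0], member_ids=m)
            for i, (_, m) in enumerate(sorted(by_len.items()))
        ]

    def test_same_signature_groups(self):
        l1 = _locus([365, 500], genome="g0", prefix="a")
        l2 = _locus([365, 500], genome="g1", prefix="b")
        patterns = derive_patterns([l1, l2], self._clusters_for([l1, l2]))
        assert len(patterns) == 1
        assert len(patterns[0].locus_ids) == 2

    def test_order_sensitivity(self):
        # (S, L) on + strand vs genomic (S, L) on - strand: strand-relative
        # signatures differ, so they are distinct patterns
        l1 = _locus([365, 500], prefix="a")
        l2 = _locus([365, 500], strand="-", prefix="b", genome="g1")
        patterns = derive_patterns([l1, l2], self._clusters_for([l1, l2]))
        assert len(patterns) == 2
        sigs = {p.signature for p in patterns}
        assert len(sigs) == 2

    def test_numbering_by_group_size(self):
        l1 = _locus([365, 500], genome="g0", prefix="a")
        l2 = _locus([365, 500], genome="g1", prefix="b")
        l3 = _locus([336, 360], genome="g2", prefix="c")
        patterns = derive_patterns([l1, l2, l3], self._clusters_for([l1, l2, l3]))
        assert patterns[0].pattern_id == 1 and len(patterns[0].locus_ids) == 2
        assert patterns[1].pattern_id == 2 and len(patterns[1].locus_ids) == 1

    def test_gene_absent_from_clusters_is_error(self):
        l1 = _locus([365, 500])
        with pytest.raises(KeyError):
            derive_patterns([l1], [])

    def test_input_order_invariance(self):
        loci = [
            _locus([365, 500], genome=f"g{i}", prefix=f"p{i}_") for i in range(3)
        ] + [_locus([336, 360], genome="g9", prefix="q")]
        clusters = self._clusters_for(loci)
        a = derive_patterns(loci, clusters)
        b = derive_patterns(list(reversed(loci)), clusters)
        assert {frozenset(p.locus_ids) for p in a} == {
            frozenset(p.locus_ids) for p in b
        }
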