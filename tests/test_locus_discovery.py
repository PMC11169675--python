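import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdclmine import (
    CdclCandidate,
    GeneRecord,
    HitTableRow,
    SignalCall,
    apply_signal_calls,
    classify_signal_peptide,
    filter_candidates,
    group_adjacent,
    mine,
    prune_loci,
    rescue_spii,
)
from cdclmine.locus_discovery import CdclLocus


def _gene(gene_id, start, end=None, strand="+", contig="c1", genome="g0",
          prot=None, aa=365):
    if prot is None:
        prot = "MKK" + "L" * 8 + "LAGC" + "G" * (aa - 15)
    if end is None:
        end = start + 3 * (len(prot) + 1)
    return GeneRecord(gene_id=gene_id, genome_id=genome, contig_id=contig,
                      start=start, end=end, strand=strand, protein_seq=prot)


def _cand(gene, score=100.0, category="SpII"):
    return CdclCandidate(
        gene=gene, bit_score=score,
        signal_call=SignalCall(category=category,
                               lipobox_cys_pos=14 if category in ("SpII", "RescuedSpII") else None),
    )


class TestFilterCandidates:
    @pytest.mark.parametrize(
        "score,partial,aa,kept",
        [
            (25.0, False, 365, True),   # gathering threshold is inclusive
            (24.9, False, 365, False),  # just below threshold
            (80.0, True, 365, False),   # partial proteins are eliminated
            (100.0, False, 99, False),  # below length window
            (100.0, False, 700, True),  # window inclusive at the top
            (100.0, False, 701, False),
        ],
    )
    def test_filter_rules(self, score, partial, aa, kept):
        gene = _gene("gA", 1000, aa=aa)
        hits = [HitTableRow("gA", "CDC", score, partial)]
        out = filter_candidates(hits, [gene])
        assert (len(out) == 1) is kept

    def test_unresolvable_protein_is_hard_error(self):
        with pytest.raises(KeyError, match="ghost"):
            filter_candidates([HitTableRow("ghost", "CDC", 50.0)], [_gene("gA", 0)])

    def test_best_hit_per_protein_kept(self):
        gene = _gene("gA", 1000)
        hits = [HitTableRow("gA", "CDC", 30.0), HitTableRow("gA", "CDC", 90.0)]
        (cand,) = filter_candidates(hits, [gene])
        assert cand.bit_score == 90.0


class TestSignalPeptide:
    def test_constructed_spii(self):
        seq = "MKKLLLVLAALLVAGCSSNE" + "G" * 200
        call = classify_signal_peptide(seq)
        assert call.category == "SpII"
        assert seq[call.lipobox_cys_pos] == "C"

    def test_no_cysteine_in_window_is_none(self):
        assert classify_signal_peptide("MSTNPKPQRDPLLA" + "G" * 50).category == "None"

    def test_cys_outside_window_is_none(self):
        seq = "M" + "A" * 49 + "C" + "A" * 50
        assert classify_signal_peptide(seq).category == "None"

    def test_no_basic_n_region_fails_lipobox(self):
        # same lipobox/h-region but no K/R among residues 1-7
        seq = "MTT" + "L" * 8 + "LAGC" + "G" * 200
        assert classify_signal_peptide(seq).category != "SpII"

    def test_spi_fallback(self):
        # A-X-A at index 20 behind a hydrophobic stretch, no lipobox
        seq = "MKT" + "G" * 9 + "LLLLLLLL" + "AKA" + "G" * 80
        assert classify_signal_peptide(seq).category == "SpI"

    def test_too_short(self):
        call = classify_signal_peptide("MKKLLLVLAA")
        assert (call.category, call.evidence) == ("None", "too_short")


class TestRescue:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("M" + "L" * 18 + "SC" + "G" * 50, True),    # SC at 19-20
            ("M" + "L" * 34 + "AC" + "G" * 50, False),   # C at index 36
            ("M" + "L" * 10 + "TC" + "G" * 50, False),   # [SA] class unmatched
            ("S" + "C" + "G" * 50, True),                # at the very start
            ("L" * 33 + "AC" + "G" * 50, True),          # C exactly at index 34
            ("L" * 34 + "AC" + "G" * 50, False),         # C at index 35
        ],
    )
    def test_window_boundaries(self, seq, expected):
        assert rescue_spii(seq) is expected

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=80))
    @settings(max_examples=500, derandomize=True)
    def test_equals_brute_force_window_scan(self, seq):
        """rescue_spii must agree with an exhaustive scan of windows
        i in [0, 33]: seq[i] in {S, A} and seq[i+1] == C."""
        brute = any(
            seq[i] in "SA" and seq[i + 1] == "C"
            for i in range(min(34, len(seq) - 1))
        )
        assert rescue_spii(seq) is brute

    def test_rescued_category_assigned(self):
        gene = _gene("gA", 500, prot="M" + "T" * 11 + "SC" + "G" * 350)
        (cand,) = apply_signal_calls([CdclCandidate(gene=gene, bit_score=60.0)])
        assert cand.signal_call.category == "RescuedSpII"
        assert cand.signal_call.lipobox_cys_pos <= 34


class TestGroupAdjacent:
    def test_pair_within_gap(self):
        a, b = _gene("gA", 1000), _gene("gB", 1000 + 3 * 366 + 400)
        loci, singles = group_adjacent([_cand(a), _cand(b)], max_gap=5000)
        assert len(loci) == 1 and len(loci[0].genes) == 2
        assert singles == []
        assert loci[0].max_internal_gap == 400

    def test_opposite_strands_become_singletons(self):
        a = _gene("gA", 1000)
        b = _gene("gB", a.end + 50, strand="-")
        loci, singles = group_adjacent([_cand(a), _cand(b)])
        assert loci == [] and len(singles) == 2

    def test_triplet(self):
        a = _gene("gA", 1000)
        b = _gene("gB", a.end + 200)
        c = _gene("gC", b.end + 200)
        loci, _ = group_adjacent([_cand(a), _cand(b), _cand(c)])
        assert len(loci) == 1 and len(loci[0].genes) == 3

    def test_gap_exceeded_splits(self):
        a = _gene("gA", 1000)
        b = _gene("gB", a.end + 5001)
        loci, singles = group_adjacent([_cand(a), _cand(b)], max_gap=5000)
        assert loci == [] and len(singles) == 2

    def test_overlapping_genes_count_as_gap_zero(self):
        a = _gene("gA", 1000)
        b = _gene("gB", a.end - 30)
        loci, _ = group_adjacent([_cand(a), _cand(b)], max_gap=0)
        assert len(loci) == 1
        assert loci[0].max_internal_gap == 0

    def test_run_longer_than_max_truncated(self):
        genes = []
        pos = 1000
        for i in range(4):
            g = _gene(f"g{i}", pos)
            genes.append(g)
            pos = g.end + 100
        with pytest.warns(UserWarning, match="truncated"):
            loci, singles = group_adjacent([_cand(g) for g in genes])
        assert len(loci) == 1 and len(loci[0].genes) == 3
        assert [c.gene.gene_id for c in loci[0].genes] == ["g0", "g1", "g2"]
        assert len(singles) == 1

    def test_partition_no_candidate_in_two_loci(self, small_synthetic):
        syn = small_synthetic
        cands = apply_signal_calls(
            filter_candidates(syn.hits, syn.genes)
        )
        loci, singles = group_adjacent(cands)
        seen = [c.gene.gene_id for l in loci for c in l.genes]
        seen += [c.gene.gene_id for c in singles]
        assert len(seen) == len(set(seen)) == len(cands)


class TestPrune:
    def _locus(self, categories, start=1000, contig_len=100_000, edge=False):
        genes = []
        pos = 0 if edge else start
        for i, cat in enumerate(categories):
            g = _gene(f"g{i}", pos)
            genes.append(_cand(g, category=cat))
            pos = g.end + 200
        locus = CdclLocus(genome_id="g0", contig_id="c1",
                          genes=tuple(genes), strand="+", max_internal_gap=200)
        return locus, {("g0", "c1"): contig_len}

    def test_orphaned_pair_dropped(self):
        locus, lengths = self._locus(["SpII", "None"])
        assert prune_loci([locus], lengths) == []

    def test_triplet_reduced_to_pair_retained(self):
        locus, lengths = self._locus(["SpII", "SpI", "RescuedSpII"])
        (out,) = prune_loci([locus], lengths)
        assert len(out.genes) == 2
        assert [c.gene.gene_id for c in out.genes] == ["g0", "g2"]

    def test_contig_edge_locus_dropped(self):
        locus, lengths = self._locus(["SpII", "SpII"], edge=True)
        assert prune_loci([locus], lengths) == []

    def test_gene_ending_at_contig_length_dropped(self):
        locus, _ = self._locus(["SpII", "SpII"])
        lengths = {("g0", "c1"): locus.genes[-1].gene.end}
        assert prune_loci([locus], lengths) == []


class TestFunnel:
    def test_monotonic_gene_subsets(self, small_synthetic):
        """Every funnel stage's gene set is a subset of the previous one."""
        syn = small_synthetic
        cands = filter_candidates(syn.hits, syn.genes)
        all_hit_ids = {h.protein_id for h in syn.hits}
        cand_ids = {c.gene.gene_id for c in cands}
        assert cand_ids <= all_hit_ids
        called = apply_signal_calls(cands)
        loci, singles = group_adjacent(called)
        grouped_ids = {c.gene.gene_id for l in loci for c in l.genes}
        assert grouped_ids <= cand_ids
        pruned = prune_loci(loci, syn.contig_lengths())
        pruned_ids = {c.gene.gene_id for l in pruned for c in l.genes}
        assert pruned_ids <= grouped_ids

    def test_mine_recovers_truth_exactly(self, small_synthetic):
        syn = small_synthetic
        result = mine(syn.hits, syn.genes, syn.contig_lengths())
        predicted = {l.gene_ids for l in result.loci}
        expected = {
            tuple(row.gene_ids.split(","))
            for row in syn.truth.itertuples()
            if row.expected == "locus"
        }
        assert predicted == expected
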