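"""Core model: gene structure, CDS extraction, coordinate mapping, MSpA
validity."""

import pytest
from hypothesis import given, settings, strategies as st

from mspa import (
    GeneModel,
    MSpA,
    MspaError,
    Multiblock,
    Relation,
    Segment,
    blocks_consistent,
    cds_sequence,
    consistent_with_mspa,
    gene_structure,
    gpos,
    induce_pspa,
    validate_mspa,
)
from mspa.model import cds_length, project_segment


def _gene_from_exons(exon_pairs, length=200):
    """One-CDS-per-exon gene model so E(g) equals the given exon set."""
    cds = {f"t{i}": (Segment("g", a, b),) for i, (a, b) in enumerate(exon_pairs)}
    return GeneModel("g", "A" * length, cds)


def _structure_oracle(exon_pairs):
    """Union of exon position sets, then maximal runs."""
    positions = sorted({p for a, b in exon_pairs for p in range(a, b + 1)})
    runs = []
    for p in positions:
        if runs and runs[-1][1] + 1 == p:
            runs[-1][1] = p
        else:
            runs.append([p, p])
    return [tuple(r) for r in runs]


class TestGeneStructure:
    def test_worked_example(self, models):
        segs = gene_structure(models["g"]).segments
        assert [(s.start, s.end) for s in segs] == [(4, 12), (25, 36), (41, 46), (51, 59)]

    def test_empty_cds_set_gives_empty_structure(self):
        model = GeneModel("g", "ACGT" * 10, {})
        assert gene_structure(model).segments == ()

    def test_merges_overlapping_not_abutting(self):
        segs = gene_structure(_gene_from_exons([(1, 5), (3, 8), (10, 12)])).segments
        assert [(s.start, s.end) for s in segs] == [(1, 8), (10, 12)]
        # abutting exons stay separate
        segs = gene_structure(_gene_from_exons([(1, 5), (6, 9)])).segments
        assert [(s.start, s.end) for s in segs] == [(1, 5), (6, 9)]

    @given(st.lists(st.tuples(st.integers(1, 40), st.integers(0, 8)), min_size=1, max_size=8))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_position_set_oracle(self, raw):
        exons = [(a, a + w) for a, w in raw]
        segs = gene_structure(_gene_from_exons(exons)).segments
        merged = [(s.start, s.end) for s in segs]
        oracle = _structure_oracle(exons)
        # merging only by overlap: abutting runs may stay split in the output,
        # but the covered position sets must agree and segments must be sorted
        covered = {p for a, b in merged for p in range(a, b + 1)}
        assert covered == {p for a, b in oracle for p in range(a, b + 1)}
        assert merged == sorted(merged)
        # and no two output segments overlap
        for (a1, b1), (a2, b2) in zip(merged, merged[1:]):
            assert b1 < a2


class TestCdsSequence:
    def test_worked_example_c1(self, models):
        seq, chart = cds_sequence(models["g"], "c1")
        assert seq == "ATGCAAGCAGGTCTGGGGTGA"
        assert len(seq) == 21
        assert [(s.start, s.end) for s in chart] == [(1, 4), (5, 16), (17, 21)]
        assert sum(s.length for s in chart) == len(seq)

    def test_single_exon_covers_whole_gene(self):
        model = GeneModel("g", "ACGTACGT", {"c": (Segment("g", 1, 8),)})
        seq, chart = cds_sequence(model, "c")
        assert seq == "ACGTACGT"
        assert [(s.start, s.end) for s in chart] == [(1, 8)]

    def test_concatenation_by_hand(self):
        model = GeneModel("g", "AAACCCGGG", {"c": (Segment("g", 1, 3), Segment("g", 7, 9))})
        seq, chart = cds_sequence(model, "c")
        assert seq == "AAAGGG"
        assert [(s.start, s.end) for s in chart] == [(1, 3), (4, 6)]

    def test_unknown_cds_raises(self, models):
        with pytest.raises(MspaError):
            cds_sequence(models["g"], "nope")


class TestGpos:
    def test_worked_example_values(self, models):
        g = models["g"]
        assert gpos(g, "c1", 1) == 9
        assert gpos(g, "c1", 5) == 25
        assert gpos(g, "c1", 17) == 51

    def test_single_exon_is_identity_shift(self):
        model = GeneModel("g", "A" * 30, {"c": (Segment("g", 7, 18),)})
        for k in range(1, 13):
            assert gpos(model, "c", k) == 7 + k - 1

    def test_out_of_range(self, models):
        with pytest.raises(MspaError):
            gpos(models["g"], "c1", 0)
        with pytest.raises(MspaError):
            gpos(models["g"], "c1", 22)

    @given(st.lists(st.tuples(st.integers(1, 10), st.integers(0, 5)), min_size=1, max_size=5))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_concatenation_map(self, raw):
        # build a strictly increasing exon chain
        exons, pos = [], 0
        for gap, w in raw:
            start = pos + gap
            exons.append((start, start + w))
            pos = start + w
        model = GeneModel("g", "A" * (pos + 1), {"c": tuple(Segment("g", a, b) for a, b in exons)})
        oracle = [p for a, b in exons for p in range(a, b + 1)]
        got = [gpos(model, "c", k) for k in range(1, len(oracle) + 1)]
        assert got == oracle
        assert got == sorted(set(got))  # strictly increasing


class TestBlocksConsistent:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"g": (4, 12)}, {"g": (25, 36)}, Relation.BEFORE),
            ({"g": (25, 36)}, {"g": (4, 12)}, Relation.AFTER),
            ({"g": (4, 12), "h": (30, 40)}, {"g": (25, 36), "h": (5, 10)}, Relation.INCONSISTENT),
            ({"g": (4, 12)}, {"g": (10, 20)}, Relation.OVERLAPS),
            ({"g": (4, 12)}, {"h": (1, 5)}, Relation.BEFORE),  # disjoint keys: free
        ],
    )
    def test_classification(self, a, b, expected):
        mba = Multiblock({k: Segment(k, s, e) for k, (s, e) in a.items()})
        mbb = Multiblock({k: Segment(k, s, e) for k, (s, e) in b.items()})
        assert blocks_consistent(mba, mbb) is expected

    def test_identical_nonempty_overlaps(self):
        mb = Multiblock({"g": Segment("g", 5, 9)})
        assert blocks_consistent(mb, mb) is Relation.OVERLAPS


class TestConsistentWithMspa:
    def test_any_multiblock_vs_empty_chain(self):
        empty = MSpA(frozenset(), frozenset(), ())
        assert consistent_with_mspa(Multiblock({"g": Segment("g", 1, 5)}), empty)

    def test_reference_first_multiblock_vs_rest(self, reference):
        first = reference.multiblocks[0]
        rest = MSpA(reference.cds_ids, reference.gene_ids, reference.multiblocks[1:])
        assert consistent_with_mspa(first, rest)

    def test_spanning_two_multiblocks_is_inconsistent(self, reference):
        spanning = Multiblock({"g": Segment("g", 10, 30)})  # spans A[2] and A[3] g segments
        assert not consistent_with_mspa(spanning, reference)


class TestInducePspa:
    def test_c3_vs_g_three_blocks(self, reference):
        pspa = induce_pspa(reference, "c3", "g")
        assert len(pspa.blocks) == 3
        assert all(b.conserved for b in pspa.blocks)

    def test_single_multiblock_roundtrip(self):
        mspa = MSpA(
            frozenset({"c"}), frozenset({"g"}),
            (Multiblock({"c": Segment("c", 1, 9), "g": Segment("g", 11, 19)}),),
        )
        pspa = induce_pspa(mspa, "c", "g")
        assert len(pspa.blocks) == 1 and pspa.blocks[0].conserved

    def test_c2_vs_g_four_conserved_blocks(self, reference):
        pspa = induce_pspa(reference, "c2", "g")
        assert len(pspa.blocks) == 4
        assert all(b.conserved for b in pspa.blocks)

    def test_missing_gene_becomes_deleted_block(self, reference, models):
        # drop h from the fourth multiblock: c2's third block loses its partner
        mbs = list(reference.multiblocks)
        mbs[3] = Multiblock({"g": mbs[3]["g"], "c2": mbs[3]["c2"]})
        mspa = MSpA(reference.cds_ids, reference.gene_ids, tuple(mbs))
        pspa = induce_pspa(mspa, "c2", "h")
        assert [b.conserved for b in pspa.blocks] == [True, True, False, True]

    def test_brute_force_reduction(self, reference):
        for cds_id, gene_id in [("c1", "g"), ("c2", "h"), ("c4", "g")]:
            pspa = induce_pspa(reference, cds_id, gene_id)
            expected = [mb for mb in reference.multiblocks if cds_id in mb]
            assert len(pspa.blocks) == len(expected)
            for block, mb in zip(pspa.blocks, expected):
                assert block.cds_segment == mb[cds_id]
                assert block.conserved == (gene_id in mb)


# ---------------------------------------------------------------------------
# validate_mspa


def _brute_force_violations(mspa, models):
    """Independent expansion of the four validity conditions by enumeration."""
    from mspa.model import cds_to_gene_map

    cds_gene = cds_to_gene_map(models)
    bad = set()
    for i, mb in enumerate(mspa.multiblocks):
        if mb.size == 0:
            bad.add(1)
    for x in {sid for mb in mspa.multiblocks for sid in mb.keys()}:
        idx = [i for i, mb in enumerate(mspa.multiblocks) if x in mb]
        for i1 in idx:
            for i2 in idx:
                if i1 < i2 and not (
                    mspa.multiblocks[i1][x].end < mspa.multiblocks[i2][x].start
                ):
                    bad.add(2)
    for c in mspa.cds_ids:
        total = cds_length(models[cds_gene[c]], c)
        covered = set()
        for mb in mspa.multiblocks:
            if c in mb:
                covered.update(range(mb[c].start, mb[c].end + 1))
        if covered != set(range(1, total + 1)):
            bad.add(3)
    for mb in mspa.multiblocks:
        for c in mspa.cds_ids:
            if c not in mb:
                continue
            g = cds_gene[c]
            if g not in mb:
                bad.add(4)
                continue
            proj = project_segment(models[g], c, mb[c])
            if not (mb[g].start <= proj.start and proj.end <= mb[g].end):
                bad.add(4)
    return bad


class TestValidateMspa:
    def test_reference_is_valid(self, reference, models):
        assert validate_mspa(reference, models) == []

    def test_overlapping_cds_segments_violate_condition_2(self, models):
        mspa = MSpA(
            frozenset({"c1"}), frozenset({"g"}),
            (
                Multiblock({"c1": Segment("c1", 1, 10), "g": Segment("g", 9, 30)}),
                Multiblock({"c1": Segment("c1", 8, 21), "g": Segment("g", 31, 55)}),
            ),
        )
        assert 2 in {v.condition for v in validate_mspa(mspa, models)}

    def test_dropping_a_multiblock_breaks_coverage(self, reference, models):
        mbs = tuple(mb for i, mb in enumerate(reference.multiblocks) if i != 2)
        broken = MSpA(reference.cds_ids, reference.gene_ids, mbs)
        conds = {(v.condition, v.seq_id) for v in validate_mspa(broken, models)}
        assert (3, "c1") in conds

    @given(data=st.data())
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_agrees_with_brute_force_checker(self, models, reference, data):
        # perturb the valid reference chain randomly and compare verdicts
        mbs = list(reference.multiblocks)
        op = data.draw(st.sampled_from(["drop", "strip_gene", "shift", "swap", "none"]))
        if op == "drop":
            del mbs[data.draw(st.integers(0, len(mbs) - 1))]
        elif op == "strip_gene":
            i = data.draw(st.integers(1, len(mbs) - 1))
            kept = {k: v for k, v in mbs[i].entries.items() if k not in ("g", "h")}
            if kept:
                mbs[i] = Multiblock(kept)
        elif op == "shift":
            i = data.draw(st.integers(0, len(mbs) - 1))
            delta = data.draw(st.integers(-4, 4))
            entries = {}
            for k, seg in mbs[i].entries.items():
                s, e = max(1, seg.start + delta), max(1, seg.end + delta)
                entries[k] = Segment(k, min(s, e), max(s, e))
            mbs[i] = Multiblock(entries)
        elif op == "swap":
            i = data.draw(st.integers(0, len(mbs) - 2))
            mbs[i], mbs[i + 1] = mbs[i + 1], mbs[i]
        mspa = MSpA(reference.cds_ids, reference.gene_ids, tuple(mbs))
        try:
            got = {v.condition for v in validate_mspa(mspa, models)}
        except MspaError:
            return  # segment fell outside the sequence: rejected earlier
        assert got == _brute_force_violations(mspa, models)
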