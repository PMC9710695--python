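"""Derivations from an MSpA: CDS MSA, ortholog groups, predicted gene models."""

import pytest

from mspa import (
    GeneModel,
    MSpA,
    Multiblock,
    PredictionRejected,
    Segment,
    cds_sequence,
    mspa_to_cds_msa,
    orthology_groups,
    predict_all,
    predict_cds,
)
from mspa.model import cds_to_gene_map


class TestCdsMsa:
    def test_rows_ungap_to_cds_sequences(self, reference, models):
        msa = mspa_to_cds_msa(reference, models)
        cds_gene = cds_to_gene_map(models)
        assert set(msa.rows) == set(reference.cds_ids)
        for cds_id in msa.rows:
            assert msa.ungapped(cds_id) == cds_sequence(models[cds_gene[cds_id]], cds_id)[0]
        lengths = {len(row) for row in msa.rows.values()}
        assert lengths == {msa.n_columns}

    def test_single_cds_alignment_is_gap_free(self):
        model = GeneModel("g", "TTT" + "ACGACG" + "TT" + "GGTTGG" + "TTT",
                          {"c": (Segment("g", 4, 9), Segment("g", 12, 17))})
        mspa = MSpA(frozenset({"c"}), frozenset({"g"}), (
            Multiblock({"c": Segment("c", 1, 6), "g": Segment("g", 4, 9)}),
            Multiblock({"c": Segment("c", 7, 12), "g": Segment("g", 12, 17)}),
        ))
        msa = mspa_to_cds_msa(mspa, {"g": model})
        assert msa.rows["c"] == "ACGACGGGTTGG"

    def test_identical_genes_align_without_gaps(self):
        seq = "TT" + "ATGGCA" + "TTT" + "CCGTAA" + "TT"
        exons = (Segment("g1", 3, 8), Segment("g1", 12, 17))
        m1 = GeneModel("g1", seq, {"a": exons})
        exons2 = (Segment("g2", 3, 8), Segment("g2", 12, 17))
        m2 = GeneModel("g2", seq, {"b": exons2})
        mspa = MSpA(frozenset({"a", "b"}), frozenset({"g1", "g2"}), (
            Multiblock({"a": Segment("a", 1, 6), "b": Segment("b", 1, 6),
                        "g1": Segment("g1", 3, 8), "g2": Segment("g2", 3, 8)}),
            Multiblock({"a": Segment("a", 7, 12), "b": Segment("b", 7, 12),
                        "g1": Segment("g1", 12, 17), "g2": Segment("g2", 12, 17)}),
        ))
        msa = mspa_to_cds_msa(mspa, {"g1": m1, "g2": m2})
        assert msa.rows["a"] == msa.rows["b"] == "ATGGCACCGTAA"

    def test_invalid_mspa_rejected(self, reference, models):
        broken = MSpA(reference.cds_ids, reference.gene_ids, reference.multiblocks[:2])
        with pytest.raises(Exception, match="invalid MSpA"):
            mspa_to_cds_msa(broken, models)


class TestOrthologyGroups:
    def test_worked_example_groups(self, reference, models):
        partition = orthology_groups(reference, models)
        groups = sorted(sorted(g) for g in partition.groups)
        assert ["c1", "c3"] in groups  # same multiblocks, congruent lengths
        assert ["c2"] in groups and ["c4"] in groups

    def test_partition_covers_cds_set(self, reference, models):
        partition = orthology_groups(reference, models)
        flat = sorted(sid for g in partition.groups for sid in g)
        assert flat == sorted(reference.cds_ids)

    def test_idempotent(self, reference, models):
        assert orthology_groups(reference, models) == orthology_groups(reference, models)

    def test_singleton_cds(self):
        model = GeneModel("g", "TT" + "ATGTAA" + "TT", {"c": (Segment("g", 3, 8),)})
        mspa = MSpA(frozenset({"c"}), frozenset({"g"}),
                    (Multiblock({"c": Segment("c", 1, 6), "g": Segment("g", 3, 8)}),))
        partition = orthology_groups(mspa, {"g": model})
        assert partition.groups == frozenset({frozenset({"c"})})

    def test_transitive_closure_joins_chained_relations(self):
        # c_a ~ c_b and c_b ~ c_c on distinct gene pairs close into one group
        seq = "T" * 2 + "AAATTT" + "T" * 2
        def gene(name):
            return GeneModel(name, seq, {f"c_{name}": (Segment(name, 3, 8),)})
        models = {n: gene(n) for n in ("x", "y", "z")}
        mspa = MSpA(
            frozenset({"c_x", "c_y", "c_z"}), frozenset(models),
            (
                Multiblock({"c_x": Segment("c_x", 1, 6), "x": Segment("x", 3, 8),
                            "c_y": Segment("c_y", 1, 6), "y": Segment("y", 3, 8),
                            "c_z": Segment("c_z", 1, 6), "z": Segment("z", 3, 8)}),
            ),
        )
        partition = orthology_groups(mspa, models)
        assert partition.groups == frozenset({frozenset({"c_x", "c_y", "c_z"})})


class TestPredictCds:
    def test_worked_example_prediction(self, reference, models):
        pred = predict_cds(reference, "c4", "g", models)
        assert pred.sequence == "AAGCAGGTCTGGGGTGATTGA"
        assert [(e.start, e.end) for e in pred.exons] == [(25, 36), (51, 59)]
        assert pred.source_cds_id == "c4"

    def test_prediction_joins_source_group(self, reference, models):
        """Adding the prediction to the family places it with its source."""
        pred = predict_cds(reference, "c4", "g", models)
        g = models["g"]
        extended_g = GeneModel("g", g.sequence, {**g.cds_models, "cpred": pred.exons})
        new_models = {"g": extended_g, "h": models["h"]}
        mbs = []
        for mb in reference.multiblocks:
            entries = dict(mb.entries)
            if "c4" in entries:
                seg = entries["g"]
                # the predicted CDS occupies exactly the gene segments of c4's
                # multiblocks; compute its CDS-coordinate span
                mbs.append((entries, seg))
            else:
                mbs.append((entries, None))
        pos = 0
        rebuilt = []
        for entries, seg in mbs:
            entries = dict(entries)
            if seg is not None:
                entries["cpred"] = Segment("cpred", pos + 1, pos + seg.length)
                pos += seg.length
            rebuilt.append(Multiblock(entries))
        mspa = MSpA(reference.cds_ids | {"cpred"}, reference.gene_ids, tuple(rebuilt))
        partition = orthology_groups(mspa, new_models)
        assert partition.group_of("cpred") == partition.group_of("c4")

    def test_frame_shifted_source_rejected(self, reference, models):
        # c3 shares multiblocks with g, but its first segment (length 4) is
        # not congruent to g's multiblock segment (length 9) modulo 3
        with pytest.raises(PredictionRejected, match="modulo 3"):
            predict_cds(reference, "c3", "g", models)

    def test_existing_cds_rejected(self):
        seq = "TT" + "ATGTGA" + "TT"
        g1 = GeneModel("g1", seq, {"c_a": (Segment("g1", 3, 8),)})
        g2 = GeneModel("g2", seq, {"c_b": (Segment("g2", 3, 8),)})
        mspa = MSpA(
            frozenset({"c_a", "c_b"}), frozenset({"g1", "g2"}),
            (Multiblock({"c_a": Segment("c_a", 1, 6), "g1": Segment("g1", 3, 8),
                         "c_b": Segment("c_b", 1, 6), "g2": Segment("g2", 3, 8)}),),
        )
        with pytest.raises(PredictionRejected, match="existing CDS c_b"):
            predict_cds(mspa, "c_a", "g2", {"g1": g1, "g2": g2})

    def test_membership_mismatch_rejected(self, reference, models):
        mbs = list(reference.multiblocks)
        mbs[2] = Multiblock({k: v for k, v in mbs[2].entries.items() if k != "g"})
        broken = MSpA(reference.cds_ids, reference.gene_ids, tuple(mbs))
        with pytest.raises(PredictionRejected, match="not g"):
            predict_cds(broken, "c4", "g", models)

    def test_mod3_violation_rejected(self, reference, models):
        mbs = list(reference.multiblocks)
        entries = dict(mbs[2].entries)
        entries["c4"] = Segment("c4", 1, 11)  # length 11 vs gene length 12
        entries["c1"] = Segment("c1", 5, 15)
        entries["c3"] = Segment("c3", 5, 15)
        mbs[2] = Multiblock(entries)
        broken = MSpA(reference.cds_ids, reference.gene_ids, tuple(mbs))
        with pytest.raises(PredictionRejected, match="modulo 3"):
            predict_cds(broken, "c4", "g", models)

    def test_internal_stop_rejected(self):
        # target gene whose homologous segment carries an in-frame TAA
        src = GeneModel("s", "TT" + "ATGAAA" + "TT", {"cs": (Segment("s", 3, 8),)})
        tgt = GeneModel("t", "TT" + "ATGTAAGGG" + "TT", {"ct": (Segment("t", 3, 5),)})
        mspa = MSpA(
            frozenset({"cs", "ct"}), frozenset({"s", "t"}),
            (
                Multiblock({"cs": Segment("cs", 1, 6), "s": Segment("s", 3, 8),
                            "t": Segment("t", 3, 11)}),
                Multiblock({"ct": Segment("ct", 1, 3), "t": Segment("t", 12, 12)}),
            ),
        )
        with pytest.raises(PredictionRejected, match="STOP"):
            predict_cds(mspa, "cs", "t", {"s": src, "t": tgt})

    def test_predict_all_collects_rejections(self, reference, models):
        accepted, rejected = predict_all(reference, "g", models)
        assert [p.sequence for p in accepted] == ["AAGCAGGTCTGGGGTGATTGA"]
        assert set(rejected) == {"c3"}
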