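import random

import pytest
from hypothesis import given, settings, strategies as st

from genesetnet.compounds import (
    ActivityRecord,
    CompoundRecord,
    InChIKeyError,
    build_pci_edges,
    filter_binding_activities,
    group_compounds,
    parse_inchikey,
)


class TestParseInchikey:
    def test_valid_key_returns_skeleton(self):
        assert parse_inchikey("AAAAAAAAAAAAAA-BBBBBBBBSA-N") == "AAAAAAAAAAAAAA"

    @pytest.mark.parametrize(
        "key,reason",
        [
            ("AAAA-BB-N", "block length"),
            ("aaaaaaaaaaaaaa-BBBBBBBBSA-N", "case"),
            ("AAAAAAAAAAAAAABBBBBBBBSAN", "missing hyphens"),
            ("AAAAAAAAAAAAA1-BBBBBBBBSA-N", "invalid characters"),
            ("AAAAAAAAAAAAAA-BBBBBBBBSA-NN-X", "missing hyphens"),
        ],
    )
    def test_rejections_carry_reason(self, key, reason):
        with pytest.raises(InChIKeyError, match=reason):
            parse_inchikey(key)


_skel = st.text(alphabet=st.characters(min_codepoint=65, max_codepoint=90),
                min_size=14, max_size=14)


class TestGrouping:
    def test_same_skeleton_different_suffix_is_one_group(self):
        recs = [
            CompoundRecord("c1", "chembl", "AAAAAAAAAAAAAA-BBBBBBBBSA-N"),
            CompoundRecord("c2", "pubchem", "AAAAAAAAAAAAAA-CCCCCCCCSA-M"),
        ]
        groups = group_compounds(recs)
        assert len(groups) == 1 and len(groups[0].members) == 2

    def test_distinct_skeletons_distinct_groups(self):
        keys = ["AAAAAAAAAAAAAA", "BBBBBBBBBBBBBB", "CCCCCCCCCCCCCC"]
        recs = [CompoundRecord(f"c{i}", "chembl", f"{k}-DDDDDDDDSA-N")
                for i, k in enumerate(keys)]
        assert len(group_compounds(recs)) == 3

    def test_empty_input(self):
        assert group_compounds([]) == []

    @given(st.lists(_skel, min_size=0, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_partition_property(self, skeletons):
        recs = [CompoundRecord(f"c{i}", "chembl", f"{sk}-DDDDDDDDSA-N")
                for i, sk in enumerate(skeletons)]
        groups = group_compounds(recs)
        assert sum(len(g.members) for g in groups) == len(recs)
        assert len(groups) == len(set(skeletons))
        ids = [m.compound_id for g in groups for m in g.members]
        assert len(ids) == len(set(ids))
        for g in groups:
            assert all(m.inchikey.startswith(g.skeleton) for m in g.members)


def _act(score=4, assay="B", target="SINGLE PROTEIN", stype="IC50", value=100.0,
         cid="c1", pid="p1"):
    return ActivityRecord(cid, pid, score, assay, target, stype, value)


class TestActivityFilter:
    @pytest.mark.parametrize(
        "rec,kept",
        [
            (_act(score=4, stype="IC50", value=5000.0), True),
            (_act(score=3, stype="Kd", value=10.0), False),
            (_act(score=5, stype="Ki", value=10000.0), True),   # inclusive boundary
            (_act(value=10001.0), False),
            (_act(assay="F"), False),
            (_act(target="PROTEIN COMPLEX"), False),
            (_act(stype="EC50"), False),
            (_act(stype="other"), False),
        ],
    )
    def test_boundary_semantics(self, rec, kept):
        out, _ = filter_binding_activities([rec])
        assert (len(out) == 1) is kept

    def test_rejection_reasons_counted(self):
        recs = [_act(score=3), _act(assay="F"), _act(value=20000.0), _act()]
        _, reasons = filter_binding_activities(recs)
        assert reasons == {"confidence_score": 1, "assay_type": 1, "standard_value": 1}

    def test_order_independence_and_idempotence(self):
        recs = [_act(score=s, value=v, cid=f"c{i}")
                for i, (s, v) in enumerate([(4, 10.0), (3, 10.0), (5, 10001.0), (6, 9999.0)])]
        kept, _ = filter_binding_activities(recs)
        shuffled = recs[::-1]
        kept2, _ = filter_binding_activities(shuffled)
        assert {k.compound_id for k in kept} == {k.compound_id for k in kept2}
        again, _ = filter_binding_activities(kept)
        assert again == kept


class TestPCIEdges:
    def _groups(self):
        return group_compounds([
            CompoundRecord("c1", "chembl", "AAAAAAAAAAAAAA-BBBBBBBBSA-N"),
            CompoundRecord("c2", "chembl", "AAAAAAAAAAAAAA-CCCCCCCCSA-N"),
            CompoundRecord("c3", "chembl", "BBBBBBBBBBBBBB-CCCCCCCCSA-N"),
        ])

    def test_best_activity_is_group_minimum(self):
        acts = [_act(cid="c1", pid="P", value=500.0), _act(cid="c2", pid="P", value=50.0)]
        edges, orphans = build_pci_edges(self._groups(), acts)
        assert orphans == []
        (e,) = edges
        assert e.best_activity_nM == 50.0 and e.protein_id == "P"

    def test_drug_annotation_edge_has_no_activity(self):
        edges, _ = build_pci_edges(self._groups(), [], [("c3", "P", "drugbank")])
        (e,) = edges
        assert e.best_activity_nM is None and e.drug_annotation
        assert e.source_dbs == {"drugbank"}

    def test_unresolvable_compound_reported(self):
        edges, orphans = build_pci_edges(self._groups(), [], [("zzz", "P", "drugbank")])
        assert edges == [] and orphans == ["zzz"]

    def test_dedup_one_edge_per_skeleton_protein(self):
        acts = [_act(cid="c1", pid="P"), _act(cid="c2", pid="P"), _act(cid="c1", pid="Q")]
        edges, _ = build_pci_edges(self._groups(), acts, [("c2", "P", "drugbank")])
        keys = {(e.skeleton, e.protein_id) for e in edges}
        assert len(edges) == len(keys) == 2
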