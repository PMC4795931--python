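import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genesetnet.enrich import (
    ContingencyCounts,
    adjust_pvalues,
    extend_with_partners,
    fisher_one_sided,
    run_enrichment,
)
from genesetnet.ppi import PPIClassified
from genesetnet.types import AnnotationSet, GeneList, GenesetnetError, Theme

from .oracles import bh_oracle, bonferroni_oracle, fisher_tail_exact, holm_oracle


class TestFisher:
    def test_worked_example_exact_fraction(self):
        # N=20, K=5, n=5, k=3: tail = 1126/15504 by direct enumeration
        c = ContingencyCounts(k=3, n=5, K=5, N=20)
        assert fisher_one_sided(c) == pytest.approx(1126 / 15504, abs=1e-14)
        assert fisher_tail_exact(3, 5, 5, 20) == pytest.approx(1126 / 15504, abs=0)

    def test_k_zero_is_one(self):
        assert fisher_one_sided(ContingencyCounts(0, 5, 5, 20)) == pytest.approx(1.0)

    def test_fully_annotated_background_forces_one(self):
        assert fisher_one_sided(ContingencyCounts(5, 5, 20, 20)) == pytest.approx(1.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyCounts(k=6, n=5, K=10, N=20)
        with pytest.raises(ValueError):
            ContingencyCounts(k=1, n=5, K=25, N=20)

    @given(st.integers(2, 30), st.data())
    @settings(max_examples=150, deadline=None)
    def test_matches_exact_rational_oracle(self, N, data):
        n = data.draw(st.integers(1, N))
        K = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(n, K)))
        p = fisher_one_sided(ContingencyCounts(k, n, K, N))
        assert p == pytest.approx(float(fisher_tail_exact(k, n, K, N)), abs=1e-12)


class TestAdjust:
    def test_bonferroni_caps_at_one(self):
        assert adjust_pvalues([0.01, 0.6], "bonferroni") == pytest.approx([0.02, 1.0])

    def test_holm_worked_example(self):
        assert adjust_pvalues([0.01, 0.04, 0.03], "holm") == pytest.approx(
            [0.03, 0.06, 0.06])

    def test_bh_worked_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh") == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_empty_input(self):
        assert adjust_pvalues([], "bh") == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bh")

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_matches_textbook_formulas_and_orderings(self, ps):
        bonf = adjust_pvalues(ps, "bonferroni")
        holm = adjust_pvalues(ps, "holm")
        bh = adjust_pvalues(ps, "bh")
        assert bonf == pytest.approx(bonferroni_oracle(ps), abs=1e-12)
        assert holm == pytest.approx(holm_oracle(ps), abs=1e-12)
        assert bh == pytest.approx(bh_oracle(ps), abs=1e-12)
        for adj in (bonf, holm, bh):
            assert all(0 <= a <= 1 for a in adj)
            assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        assert all(b >= h - 1e-15 for b, h in zip(bonf, holm))
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(np.asarray(bh)[order]) >= -1e-15)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.randoms())
    @settings(max_examples=50, deadline=None)
    def test_permutation_equivariance(self, ps, rnd):
        idx = list(range(len(ps)))
        rnd.shuffle(idx)
        permuted = [ps[i] for i in idx]
        adj_perm = adjust_pvalues(permuted, "holm")
        adj = adjust_pvalues(ps, "holm")
        assert [adj[i] for i in idx] == pytest.approx(adj_perm, abs=1e-15)


def _cls(a, b, hc=True, dp=False):
    return PPIClassified((a, b), 2, 1, hc, dp)


class TestExtend:
    def test_mode_none_is_identity(self):
        gl = GeneList("q", ["a"])
        out, prov = extend_with_partners(gl, [_cls("a", "b")], "none")
        assert out.members == ["a"] and prov == {"a": "seed"}

    def test_high_confidence_partner_added(self):
        out, prov = extend_with_partners(
            GeneList("q", ["a"]), [_cls("a", "b")], "high_confidence")
        assert out.members == ["a", "b"] and prov["b"] == "partner"

    def test_low_confidence_pair_ignored(self):
        out, _ = extend_with_partners(
            GeneList("q", ["a"]), [_cls("a", "b", hc=False)], "high_confidence")
        assert out.members == ["a"]

    def test_direct_physical_mode_filters_class(self):
        cls = [_cls("a", "b", hc=True, dp=False), _cls("a", "c", hc=True, dp=True)]
        out, _ = extend_with_partners(GeneList("q", ["a"]), cls, "direct_physical")
        assert out.members == ["a", "c"]


@pytest.fixture
def annotation():
    genes = [f"g{i}" for i in range(30)]
    return AnnotationSet([
        Theme("T1", "planted", "pathway", set(genes[:8])),
        Theme("T2", "noise-a", "pathway", set(genes[10:20])),
        Theme("T3", "noise-b", "go_slim", set(genes[5:25])),
    ])


class TestRunEnrichment:
    def test_planted_theme_first_and_significant(self, annotation):
        gl = GeneList("q", [f"g{i}" for i in range(6)])
        run = run_enrichment(gl, annotation)
        assert run.results[0].theme_id == "T1"
        assert run.results[0].significant

    def test_foreground_equals_background_all_p_one(self, annotation):
        gl = GeneList("q", sorted(annotation.universe))
        run = run_enrichment(gl, annotation)
        assert all(r.p_raw == pytest.approx(1.0) for r in run.results)

    def test_alpha_zero_nothing_significant(self, annotation):
        gl = GeneList("q", [f"g{i}" for i in range(6)])
        run = run_enrichment(gl, annotation, alpha=0.0)
        assert run.significant == []

    def test_unannotated_foreground_genes_dropped_and_reported(self, annotation):
        gl = GeneList("q", ["g0", "g1", "not-a-gene"])
        run = run_enrichment(gl, annotation)
        assert run.foreground_dropped == ["not-a-gene"]
        assert all(r.counts.n == 2 for r in run.results)

    def test_empty_foreground_errors(self, annotation):
        with pytest.raises(GenesetnetError):
            run_enrichment(GeneList("q", ["nope"]), annotation)

    def test_padj_never_below_praw(self, annotation):
        gl = GeneList("q", [f"g{i}" for i in range(0, 30, 3)])
        run = run_enrichment(gl, annotation, method="bonferroni")
        for r in run.results:
            assert r.p_adj >= r.p_raw - 1e-15

    def test_m_mode_all_inflates_correction(self, annotation):
        gl = GeneList("q", ["g0", "g1", "g2"])  # only T1/T3 can be hit
        tested = run_enrichment(gl, annotation, m_mode="tested")
        allm = run_enrichment(gl, annotation, m_mode="all")
        assert allm.m_tested >= tested.m_tested
        for rt, ra in zip(tested.results, allm.results):
            assert ra.p_adj >= rt.p_adj - 1e-15
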