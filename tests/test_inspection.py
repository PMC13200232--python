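"""Inspection view: spans, keyword triage, precedence, candidate extraction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgcworkbench import (
    ClusterRecord,
    GeneFeature,
    KeywordConfig,
    Workspace,
    build_report,
    compute_mapped_span,
    extract_candidates,
    inspect_cluster,
    map_to_clusters,
    report_to_html,
    report_to_tsv,
)
from bgcworkbench.inspection import FLAG_HIDDEN, FLAG_HIGHLIGHTED, FLAG_PLAIN
from bgcworkbench.mapping import GeneAssignment


def _gene(key, start, end, idx, product=""):
    return GeneFeature(
        start=start, end=end, strand=1, locus_tag=key, protein_id=None,
        product=product, protein_seq="MKTAYIAKQR", source_index=idx,
    )


def _assign(cluster_id, gene, group_id=1):
    return GeneAssignment(
        cluster_id=cluster_id, gene_key=gene.key, gene=gene,
        group_id=group_id, identity=0.8, score=100.0,
    )


@pytest.fixture
def cluster():
    genes = [
        _gene("g1", 100, 400, 0, "polyketide synthase"),
        _gene("g2", 900, 1500, 1, "cytochrome P450 hydroxylase"),
        _gene("g3", 2000, 2300, 2, "ABC transporter permease"),
        _gene("g4", 2500, 2800, 3, ""),
        _gene("far", 50_000, 50_300, 4, "FAD-dependent monooxygenase"),
    ]
    return ClusterRecord("c1", "org", "c1.gbk", 60_000, genes)


class TestMappedSpan:
    def test_hull_of_two_intervals(self, cluster):
        asg = [_assign("c1", cluster.gene_by_key("g1")),
               _assign("c1", cluster.gene_by_key("g2"), 2)]
        assert compute_mapped_span(cluster, asg) == (100, 1500)

    def test_single_gene(self, cluster):
        asg = [_assign("c1", cluster.gene_by_key("g1"))]
        assert compute_mapped_span(cluster, asg) == (100, 400)

    def test_absent_without_assignments(self, cluster):
        assert compute_mapped_span(cluster, []) is None

    def test_ignores_other_clusters(self, cluster):
        other = _assign("elsewhere", cluster.gene_by_key("g2"))
        assert compute_mapped_span(cluster, [other]) is None


class TestInspectCluster:
    def test_flags_and_window(self, cluster):
        asg = [_assign("c1", cluster.gene_by_key("g1"))]
        entry = inspect_cluster(cluster, asg, flank_bp=10_000)
        assert entry.mapped_span == (100, 400)
        assert [g.key for g in entry.mapped_genes] == ["g1"]
        flags = {g.key: f for g, f in entry.unmapped_in_view}
        # window [0, 10400): "far" at 50 kb is outside
        assert flags == {
            "g2": FLAG_HIGHLIGHTED,  # cytochrome P450
            "g3": FLAG_HIDDEN,       # transporter
            "g4": FLAG_PLAIN,        # empty product
        }
        assert entry.candidate_vstg_count == 1

    def test_whole_record_in_view_when_nothing_mapped(self, cluster):
        entry = inspect_cluster(cluster, [])
        assert entry.mapped_span is None
        assert len(entry.unmapped_in_view) == 5

    def test_negative_flank_rejected(self, cluster):
        with pytest.raises(ValueError, match="flank"):
            inspect_cluster(cluster, [], flank_bp=-1)

    def test_widening_flank_never_removes_candidates(self, cluster):
        asg = [_assign("c1", cluster.gene_by_key("g1"))]
        seen = set()
        for flank in (0, 1_000, 10_000, 60_000):
            entry = inspect_cluster(cluster, asg, flank_bp=flank)
            now = {g.key for g, f in entry.unmapped_in_view if f == FLAG_HIGHLIGHTED}
            assert seen <= now
            seen = now
        assert "far" in seen  # monooxygenase enters once the window reaches it


class TestKeywordConfig:
    def test_hide_beats_highlight(self):
        kw = KeywordConfig()
        assert kw.flag("transporter-associated monooxygenase regulator") == FLAG_HIDDEN

    def test_matching_is_case_insensitive_substring(self):
        kw = KeywordConfig()
        assert kw.flag("Cytochrome P450 Monooxygenase") == FLAG_HIGHLIGHTED
        assert kw.flag("putative GLYCOSYLTRANSFERASE family 2") == FLAG_HIGHLIGHTED

    def test_empty_highlight_list_flags_nothing(self, cluster):
        kw = KeywordConfig(highlight_terms=(), hide_terms=())
        entry = inspect_cluster(cluster, [], kw=kw)
        assert entry.candidate_vstg_count == 0
        assert all(f == FLAG_PLAIN for _, f in entry.unmapped_in_view)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(product=st.text(min_size=0, max_size=40))
    def test_flag_is_total_and_stable(self, product):
        kw = KeywordConfig()
        assert kw.flag(product) in (FLAG_HIDDEN, FLAG_HIGHLIGHTED, FLAG_PLAIN)
        assert kw.flag(product) == kw.flag(product.upper())


class TestCandidates:
    def _report(self, cluster):
        asg = [_assign("c1", cluster.gene_by_key("g1"))]
        ws = Workspace([cluster], "c1")
        return build_report(ws, asg, flank_bp=60_000), asg

    def test_candidates_are_highlighted_unmapped_genes_in_order(self, cluster):
        report, _ = self._report(cluster)
        assert [g.key for g in extract_candidates(report)] == ["g2", "far"]

    def test_mapped_gene_is_never_a_candidate(self, cluster):
        report, _ = self._report(cluster)
        mapped = {g.key for e in report.entries for g in e.mapped_genes}
        assert mapped.isdisjoint({g.key for g in extract_candidates(report)})

    def test_inspection_is_deterministic(self, cluster):
        r1, _ = self._report(cluster)
        r2, _ = self._report(cluster)
        assert r1 == r2

    def test_planted_vstgs_recovered_end_to_end(self, family_clusters):
        """Mapping + inspection on the synthetic family flags exactly the
        planted tailoring genes as candidates."""
        ws = Workspace(family_clusters, family_clusters[0].cluster_id)
        for key in [g.key for g in ws.reference.genes if g.product.startswith("core")]:
            ws.select_gene(key)
        _, assignments = map_to_clusters(ws)
        report = build_report(ws, assignments)
        candidates = extract_candidates(report)
        assert sorted(g.product for g in candidates) == sorted([
            "FAD-dependent monooxygenase",
            "cytochrome P450 hydroxylase",
            "O-methyltransferase",
            "flavin-dependent halogenase",
            "NDP-hexose glycosyltransferase",
        ])


class TestSerialisation:
    def test_tsv_layout(self, cluster):
        asg = [_assign("c1", cluster.gene_by_key("g1"))]
        tsv = report_to_tsv(
            build_report(Workspace([cluster], "c1"), asg), asg
        )
        lines = tsv.strip().split("\n")
        assert lines[0].split("\t") == [
            "cluster_id", "gene", "start", "end", "strand", "flag",
            "group_id", "identity", "product",
        ]
        g1_row = next(l for l in lines if "\tg1\t" in l).split("\t")
        assert g1_row[5] == "mapped" and g1_row[6] == "1"
        g4_row = next(l for l in lines if "\tg4\t" in l).split("\t")
        assert g4_row[5:8] == ["plain", "-", "-"]

    def test_html_is_standalone_and_escapes_markup(self, cluster):
        spicy = ClusterRecord("c1", "org", "c1.gbk", 60_000, [
            _gene("g1", 100, 400, 0, 'weird <product> & "quotes"'),
        ])
        html = report_to_html(build_report(Workspace([spicy], "c1"), []), [])
        assert html.startswith("<!DOCTYPE html>")
        assert "<product>" not in html
        assert "&lt;product&gt;" in html
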