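"""Inspection view: mapped spans, gene suppression, keyword triage.

After mapping, each cluster is reduced to a triage report: the genomic span
covering all mapped genes, the mapped genes themselves (suppressed from the
candidate list), and the unmapped genes inside a flanked view window, each
flagged by its product annotation.  Annotations matching a *hide* term
(transporters, regulators, ...) are dropped from view; annotations matching a
*highlight* term (transferases, cytochrome P450s, oxygenases, ...) are
surfaced in bold as candidate variant-specific tailoring genes (VSTGs).

Hide beats highlight when a product matches both lists: in a triage view a
false negative is cheaper than noise, and both term lists are overridable.

The built-in term lists extend the published examples ("transferase",
"cytochrome P450", "monooxygenase", ...; "transporter", "symporter",
"regulator") with the obvious members of the same families; they are
defaults, not a curated ontology, and callers are expected to tune them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .io_genbank import ClusterRecord, GeneFeature
from .mapping import GeneAssignment, Workspace

FLAG_HIGHLIGHTED = "highlighted"
FLAG_HIDDEN = "hidden"
FLAG_PLAIN = "plain"

DEFAULT_HIGHLIGHT_TERMS = (
    "transferase",
    "cytochrome p450",
    "monooxygenase",
    "oxidoreductase",
    "oxygenase",
    "halogenase",
    "synthase",
    "synthetase",
    "hydroxylase",
    "dehydrogenase",
    "reductase",
)

DEFAULT_HIDE_TERMS = (
    "transporter",
    "symporter",
    "regulator",
    "antiporter",
    "permease",
    "repressor",
)


@dataclass(frozen=True)
class KeywordConfig:
    """Case-insensitive substring term lists for annotation triage."""

    highlight_terms: tuple[str, ...] = DEFAULT_HIGHLIGHT_TERMS
    hide_terms: tuple[str, ...] = DEFAULT_HIDE_TERMS

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "highlight_terms", tuple(t.lower() for t in self.highlight_terms)
        )
        object.__setattr__(self, "hide_terms", tuple(t.lower() for t in self.hide_terms))

    def flag(self, product: str) -> str:
        """Classify a product annotation; hide takes precedence over highlight."""
        text = product.lower()
        if any(term in text for term in self.hide_terms):
            return FLAG_HIDDEN
        if any(term in text for term in self.highlight_terms):
            return FLAG_HIGHLIGHTED
        return FLAG_PLAIN


@dataclass(frozen=True)
class ClusterInspection:
    """Inspection-view entry for one cluster."""

    cluster_id: str
    mapped_span: tuple[int, int] | None
    mapped_genes: tuple[GeneFeature, ...]
    unmapped_in_view: tuple[tuple[GeneFeature, str], ...]

    @property
    def candidate_vstg_count(self) -> int:
        return sum(1 for _, flag in self.unmapped_in_view if flag == FLAG_HIGHLIGHTED)


@dataclass(frozen=True)
class InspectionReport:
    entries: tuple[ClusterInspection, ...] = field(default=())

    def entry(self, cluster_id: str) -> ClusterInspection:
        for e in self.entries:
            if e.cluster_id == cluster_id:
                return e
        raise LookupError(f"no inspection entry for cluster {cluster_id!r}")


def compute_mapped_span(
    cluster: ClusterRecord, assignments: Iterable[GeneAssignment]
) -> tuple[int, int] | None:
    """Half-open hull over all assigned genes of this cluster; None if none."""
    spans = [
        (a.gene.start, a.gene.end)
        for a in assignments
        if a.cluster_id == cluster.cluster_id
    ]
    if not spans:
        return None
    return min(s for s, _ in spans), max(e for _, e in spans)


def inspect_cluster(
    cluster: ClusterRecord,
    assignments: Iterable[GeneAssignment],
    kw: KeywordConfig | None = None,
    flank_bp: int = 10_000,
) -> ClusterInspection:
    """Build the inspection entry for one cluster.

    The view window is the mapped span expanded by ``flank_bp`` on each side
    (clamped to the record), or the whole record when nothing is mapped.
    Unmapped genes overlapping the window are flagged hidden / highlighted /
    plain from their product annotation; mapped genes are listed separately.
    """
    if flank_bp < 0:
        raise ValueError(f"flank_bp must be non-negative, got {flank_bp}")
    kw = kw or KeywordConfig()
    own = [a for a in assignments if a.cluster_id == cluster.cluster_id]
    span = compute_mapped_span(cluster, own)
    if span is None:
        window = (0, cluster.seq_length)
    else:
        window = (max(0, span[0] - flank_bp), min(cluster.seq_length, span[1] + flank_bp))

    mapped_keys = {a.gene_key for a in own}
    mapped = tuple(g for g in cluster.genes if g.key in mapped_keys)
    unmapped = tuple(
        (g, kw.flag(g.product))
        for g in cluster.genes
        if g.key not in mapped_keys and g.start < window[1] and g.end > window[0]
    )
    return ClusterInspection(
        cluster_id=cluster.cluster_id,
        mapped_span=span,
        mapped_genes=mapped,
        unmapped_in_view=unmapped,
    )


def build_report(
    ws: Workspace,
    assignments: Iterable[GeneAssignment],
    kw: KeywordConfig | None = None,
    flank_bp: int = 10_000,
) -> InspectionReport:
    assignments = list(assignments)
    return InspectionReport(
        entries=tuple(
            inspect_cluster(c, assignments, kw=kw, flank_bp=flank_bp) for c in ws.clusters
        )
    )


def extract_candidates(report: InspectionReport) -> list[GeneFeature]:
    """All highlighted unmapped genes, ordered by cluster then position —
    ready for FASTA export."""
    out: list[GeneFeature] = []
    for entry in report.entries:
        out.extend(
            g
            for g, flag in sorted(
                entry.unmapped_in_view, key=lambda t: (t[0].start, t[0].source_index)
            )
            if flag == FLAG_HIGHLIGHTED
        )
    return out


def report_to_tsv(
    report: InspectionReport, assignments: Iterable[GeneAssignment]
) -> str:
    """Tab-separated inspection table.

    One row per gene in view: cluster, gene id, 0-based half-open span,
    strand, flag ("mapped" for suppressed genes), group id and identity where
    assigned, and the verbatim product annotation.
    """
    by_gene = {(a.cluster_id, a.gene_key): a for a in assignments}
    lines = [
        "cluster_id\tgene\tstart\tend\tstrand\tflag\tgroup_id\tidentity\tproduct"
    ]
    for entry in report.entries:
        rows: list[tuple[GeneFeature, str]] = [
            (g, "mapped") for g in entry.mapped_genes
        ] + list(entry.unmapped_in_view)
        rows.sort(key=lambda t: (t[0].start, t[0].source_index))
        for gene, flag in rows:
            asg = by_gene.get((entry.cluster_id, gene.key))
            group = str(asg.group_id) if asg else "-"
            identity = f"{asg.identity:.3f}" if asg else "-"
            strand = "+" if gene.strand == 1 else "-"
            lines.append(
                f"{entry.cluster_id}\t{gene.display_id}\t{gene.start}\t{gene.end}"
                f"\t{strand}\t{flag}\t{group}\t{identity}\t{gene.product}"
            )
    return "\n".join(lines) + "\n"


def report_to_html(
    report: InspectionReport,
    assignments: Iterable[GeneAssignment],
    svg: str | None = None,
    title: str = "BGC inspection report",
) -> str:
    """Minimal standalone HTML summary, optionally embedding a comparison SVG."""
    tsv = report_to_tsv(report, assignments)
    rows = [line.split("\t") for line in tsv.strip().split("\n")]
    head, body = rows[0], rows[1:]

    def esc(s: str) -> str:
        return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")

    html = [
        "<!DOCTYPE html>",
        f"<html><head><meta charset='utf-8'><title>{esc(title)}</title>",
        "<style>body{font-family:sans-serif}table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:2px 6px;font-size:12px}"
        "tr.highlighted td{font-weight:bold}tr.hidden td{color:#bbb}</style>",
        f"</head><body><h1>{esc(title)}</h1>",
    ]
    if svg:
        html.append(svg)
    html.append("<table><tr>" + "".join(f"<th>{esc(h)}</th>" for h in head) + "</tr>")
    for row in body:
        flag = row[5]
        html.append(
            f"<tr class='{esc(flag)}'>"
            + "".join(f"<td>{esc(c)}</td>" for c in row)
            + "</tr>"
        )
    html.append("</table></body></html>")
    return "\n".join(html) + "\n"
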