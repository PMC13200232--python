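"""Static clinker-style SVG comparison figures.

One horizontal track per cluster; genes are strand-oriented arrows scaled in
px/bp; genes assigned to the same homology group share a fill colour from a
deterministic palette keyed by group id; ribbons connect homologous genes on
*adjacent* tracks whose pairwise protein identity is strictly above
``ribbon_min_identity`` (default 40%, matching the published figure rule).

In inspection mode, mapped genes are dimmed and highlighted candidate genes
carry bold product labels, mirroring the inspection view.

Rendering is a pure function of its inputs: identical workspaces, mappings
and options produce byte-identical SVG, so figures are reproducible across
runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alignment import AlignmentParams, align_local
from .inspection import FLAG_HIDDEN, FLAG_HIGHLIGHTED, InspectionReport
from .mapping import GeneAssignment, HomologyGroup, Workspace

#: deterministic categorical palette (12 colours), indexed by color_index
PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#17becf", "#bcbd22", "#aec7e8", "#ffbb78", "#98df8a",
)
UNMAPPED_FILL = "#cccccc"

_TRACK_HEIGHT = 70
_GENE_HEIGHT = 14
_HEAD_PX = 8.0
_MARGIN_X = 20
_LABEL_H = 14


@dataclass(frozen=True)
class RenderOptions:
    order: tuple[str, ...] = ()           # cluster ids, reference first by default
    px_per_bp: float = 0.02
    ribbon_min_identity: float = 0.40
    show_inspection: bool = False
    label_policy: str = "organism"        # organism | cluster_id | both

    def __post_init__(self) -> None:
        if self.px_per_bp <= 0:
            raise ValueError("px_per_bp must be > 0")
        if self.label_policy not in ("organism", "cluster_id", "both"):
            raise ValueError(f"unknown label_policy {self.label_policy!r}")


def group_color(group: HomologyGroup) -> str:
    return PALETTE[group.color_index % len(PALETTE)]


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def _arrow_points(x1: float, x2: float, y: float, strand: int) -> str:
    """Polygon points for a strand-oriented gene arrow in a lane centred at y."""
    h = _GENE_HEIGHT / 2
    head = min(_HEAD_PX, x2 - x1)
    if strand >= 0:
        xb = x2 - head
        pts = [(x1, y - h), (xb, y - h), (x2, y), (xb, y + h), (x1, y + h)]
    else:
        xb = x1 + head
        pts = [(x2, y - h), (xb, y - h), (x1, y), (xb, y + h), (x2, y + h)]
    return " ".join(f"{_fmt(px)},{_fmt(py)}" for px, py in pts)


def _resolve_order(ws: Workspace, opts: RenderOptions) -> list[str]:
    if opts.order:
        known = {c.cluster_id for c in ws.clusters}
        for cid in opts.order:
            if cid not in known:
                raise LookupError(f"unknown cluster id in render order: {cid!r}")
        return list(opts.order)
    rest = [c.cluster_id for c in ws.clusters if c.cluster_id != ws.reference_id]
    return [ws.reference_id] + rest


def _adjacent_ribbons(
    ws: Workspace,
    order: Sequence[str],
    assignments: Iterable[GeneAssignment],
    opts: RenderOptions,
    params: AlignmentParams,
) -> list[tuple[int, GeneAssignment, GeneAssignment]]:
    """Pairs to connect: for each adjacent track pair and group, each upper
    gene is paired with its best-identity partner below; kept when their
    pairwise identity is strictly above the ribbon cutoff."""
    by_cluster_group: dict[tuple[str, int], list[GeneAssignment]] = {}
    for a in assignments:
        by_cluster_group.setdefault((a.cluster_id, a.group_id), []).append(a)
    group_ids = sorted({a.group_id for a in assignments})

    ribbons = []
    for upper, lower in zip(order, order[1:]):
        for gid in group_ids:
            uppers = by_cluster_group.get((upper, gid), [])
            lowers = by_cluster_group.get((lower, gid), [])
            if not uppers or not lowers:
                continue
            for ua in uppers:
                best = None
                for la in lowers:
                    res = align_local(ua.gene.protein_seq, la.gene.protein_seq, params)
                    rank = (res.identity, -la.gene.start)
                    if best is None or rank > best[0]:
                        best = (rank, la, res.identity)
                assert best is not None
                if best[2] > opts.ribbon_min_identity:
                    ribbons.append((gid, ua, best[1]))
    return ribbons


def render_comparison(
    ws: Workspace,
    groups: Sequence[HomologyGroup],
    assignments: Iterable[GeneAssignment],
    report: InspectionReport | None = None,
    opts: RenderOptions | None = None,
    params: AlignmentParams | None = None,
) -> str:
    """Emit a standalone SVG 1.1 document comparing the workspace's clusters."""
    opts = opts or RenderOptions()
    params = params or AlignmentParams()
    assignments = list(assignments)
    if opts.show_inspection and report is None:
        raise ValueError("inspection rendering requires an inspection report")

    order = _resolve_order(ws, opts)
    clusters = {c.cluster_id: c for c in ws.clusters}
    group_by_id = {g.group_id: g for g in groups}
    assigned = {(a.cluster_id, a.gene_key): a for a in assignments}

    width = 2 * _MARGIN_X + max(
        (clusters[cid].seq_length * opts.px_per_bp for cid in order), default=0
    )
    height = _TRACK_HEIGHT * len(order) + _LABEL_H
    track_y = {cid: _LABEL_H + _TRACK_HEIGHT * i + _TRACK_HEIGHT / 2 for i, cid in enumerate(order)}

    def gx(cid: str, bp: int) -> float:
        return _MARGIN_X + bp * opts.px_per_bp

    out: list[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">'
    )

    # ribbons first (behind the arrows)
    for gid, ua, la in _adjacent_ribbons(ws, order, assignments, opts, params):
        color = group_color(group_by_id[gid]) if gid in group_by_id else UNMAPPED_FILL
        uy = track_y[ua.cluster_id] + _GENE_HEIGHT / 2
        ly = track_y[la.cluster_id] - _GENE_HEIGHT / 2
        pts = [
            (gx(ua.cluster_id, ua.gene.start), uy),
            (gx(ua.cluster_id, ua.gene.end), uy),
            (gx(la.cluster_id, la.gene.end), ly),
            (gx(la.cluster_id, la.gene.start), ly),
        ]
        out.append(
            '<polygon class="ribbon" points="'
            + " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts)
            + f'" fill="{color}" fill-opacity="0.35" stroke="none"/>'
        )

    # tracks
    for cid in order:
        cluster = clusters[cid]
        y = track_y[cid]
        if opts.label_policy == "organism":
            label = cluster.organism or cid
        elif opts.label_policy == "cluster_id":
            label = cid
        else:
            label = f"{cluster.organism} [{cid}]" if cluster.organism else cid
        out.append(
            f'<text class="track-label" x="{_fmt(_MARGIN_X)}" '
            f'y="{_fmt(y - _GENE_HEIGHT - 6)}" font-size="11" '
            f'font-family="sans-serif">{_esc(label)}</text>'
        )
        out.append(
            f'<line class="backbone" x1="{_fmt(gx(cid, 0))}" y1="{_fmt(y)}" '
            f'x2="{_fmt(gx(cid, cluster.seq_length))}" y2="{_fmt(y)}" '
            'stroke="#888" stroke-width="1"/>'
        )

        flags = {}
        if opts.show_inspection and report is not None:
            flags = {g.key: f for g, f in report.entry(cid).unmapped_in_view}

        for gene in cluster.genes:
            asg = assigned.get((cid, gene.key))
            if asg is not None and asg.group_id in group_by_id:
                fill = group_color(group_by_id[asg.group_id])
            else:
                fill = UNMAPPED_FILL
            attrs = ""
            if opts.show_inspection and asg is not None:
                attrs = ' opacity="0.25"'  # mapped genes dimmed in inspection mode
            out.append(
                '<polygon class="gene-arrow" points="'
                + _arrow_points(gx(cid, gene.start), gx(cid, gene.end), y, gene.strand)
                + f'" fill="{fill}" stroke="#333" stroke-width="0.5"{attrs}>'
                + f"<title>{_esc(gene.display_id)} {_esc(gene.product)}</title></polygon>"
            )
            if opts.show_inspection and asg is None:
                flag = flags.get(gene.key)
                if flag == FLAG_HIDDEN or flag is None:
                    continue
                weight = ' font-weight="bold"' if flag == FLAG_HIGHLIGHTED else ""
                out.append(
                    f'<text class="product-label" x="{_fmt(gx(cid, gene.start))}" '
                    f'y="{_fmt(y - _GENE_HEIGHT)}" font-size="9" '
                    f'font-family="sans-serif"{weight}>{_esc(gene.product)}</text>'
                )

    out.append("</svg>")
    return "\n".join(out) + "\n"
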