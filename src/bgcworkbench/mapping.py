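"""Workspace model, automatic core-gene selection, and homologue mapping.

A workspace holds an ordered set of parsed clusters, one of which is the
*reference*; clusters can be marked (used for automatic core-gene selection),
favourited, and annotated with free-text notes.  Genes from non-reference
clusters can be placed on the *gene bench* — e.g. known variant-specific
tailoring genes (VSTGs) of a second characterised congener — so they take part
in the mapping alongside the reference's selected genes.

Mapping is one-directional best-hit: every anchor gene (selected reference
gene or bench gene) becomes a homology group; each target gene that passes
the homology predicate against at least one anchor is assigned to exactly one
group — the anchor with the highest identity (ties: higher score, then lower
group id).  Reciprocal-best-hit filtering is deliberately not applied, and a
group may collect several paralogues from one cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import yaml

from .alignment import AlignmentParams, align_local, is_homologue
from .io_genbank import ClusterRecord, GeneFeature, parse_genbank

logger = logging.getLogger(__name__)

ROLE_CBG = "CBG"
ROLE_KNOWN_VSTG = "known-VSTG"
ROLE_BENCH = "bench"


@dataclass(frozen=True)
class BenchGene:
    """A gene imported to the bench, with provenance to its source cluster."""

    source_cluster_id: str
    gene_key: str


@dataclass(frozen=True)
class HomologyGroup:
    """An anchor gene and its colour slot in the comparison figure."""

    group_id: int
    anchor_cluster_id: str
    anchor_key: str
    anchor: GeneFeature
    role: str
    color_index: int


@dataclass(frozen=True)
class GeneAssignment:
    """One target gene assigned to one homology group."""

    cluster_id: str
    gene_key: str
    gene: GeneFeature
    group_id: int
    identity: float
    score: float


@dataclass
class Workspace:
    clusters: list[ClusterRecord]
    reference_id: str
    marked_ids: set[str] = field(default_factory=set)
    favorite_ids: set[str] = field(default_factory=set)
    selected_reference_genes: list[str] = field(default_factory=list)
    selected_gene_roles: dict[str, str] = field(default_factory=dict)
    bench_genes: list[BenchGene] = field(default_factory=list)
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.cluster_id for c in self.clusters]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cluster ids in workspace")
        self._by_id = {c.cluster_id: c for c in self.clusters}
        self._require(self.reference_id)
        for cid in sorted(self.marked_ids | self.favorite_ids):
            self._require(cid)

    # -- lookups ---------------------------------------------------------
    def _require(self, cluster_id: str) -> ClusterRecord:
        try:
            return self._by_id[cluster_id]
        except KeyError:
            raise LookupError(f"unknown cluster id {cluster_id!r}") from None

    def cluster(self, cluster_id: str) -> ClusterRecord:
        return self._require(cluster_id)

    @property
    def reference(self) -> ClusterRecord:
        return self._by_id[self.reference_id]

    # -- user annotations (idempotent) -----------------------------------
    def mark(self, cluster_id: str) -> "Workspace":
        self._require(cluster_id)
        self.marked_ids.add(cluster_id)
        return self

    def unmark(self, cluster_id: str) -> "Workspace":
        self._require(cluster_id)
        self.marked_ids.discard(cluster_id)
        return self

    def favorite(self, cluster_id: str) -> "Workspace":
        self._require(cluster_id)
        self.favorite_ids.add(cluster_id)
        return self

    def note(self, cluster_id: str, text: str) -> "Workspace":
        self._require(cluster_id)
        self.notes[cluster_id] = text
        return self

    def add_bench_gene(self, source_cluster_id: str, gene_key: str) -> "Workspace":
        cluster = self._require(source_cluster_id)
        cluster.gene_by_key(gene_key)  # raises KeyError if absent
        bench = BenchGene(source_cluster_id, gene_key)
        if bench not in self.bench_genes:
            self.bench_genes.append(bench)
        return self

    def select_gene(self, gene_key: str, role: str = ROLE_CBG) -> "Workspace":
        self.reference.gene_by_key(gene_key)
        if gene_key not in self.selected_reference_genes:
            self.selected_reference_genes.append(gene_key)
        self.selected_gene_roles[gene_key] = role
        return self


def select_core_auto(
    ws: Workspace, params: AlignmentParams | None = None, require_all: bool = True
) -> list[str]:
    """Automatically select core biosynthetic genes of the reference.

    A reference gene is selected when it has at least one homologue (gene as
    query) in every marked cluster (``require_all=True``, the default) or in
    at least one of them (``require_all=False``).  The selection replaces the
    workspace's selected genes with role CBG and is returned in reference
    genomic order.
    """
    params = params or AlignmentParams()
    if not ws.marked_ids:
        raise ValueError(
            "no marked clusters: mark clusters for automatic core-gene "
            "selection, or select reference genes manually"
        )
    if not ws.reference.genes:
        raise ValueError("reference cluster has no genes")

    selected: list[str] = []
    marked = [ws.cluster(cid) for cid in ws.marked_ids]
    for gene in ws.reference.genes:
        hits = []
        for cluster in marked:
            if cluster.cluster_id == ws.reference_id:
                hits.append(True)
                continue
            found = any(
                is_homologue(align_local(gene.protein_seq, tgt.protein_seq, params), params)
                for tgt in cluster.genes
            )
            hits.append(found)
        keep = all(hits) if require_all else any(hits)
        if keep:
            selected.append(gene.key)

    ws.selected_reference_genes = selected
    ws.selected_gene_roles = {k: ROLE_CBG for k in selected}
    return selected


def _build_groups(ws: Workspace) -> list[HomologyGroup]:
    groups: list[HomologyGroup] = []
    ref = ws.reference
    ordered = sorted(
        ws.selected_reference_genes,
        key=lambda k: (ref.gene_by_key(k).start, ref.gene_by_key(k).source_index),
    )
    gid = 0
    for key in ordered:
        gid += 1
        groups.append(
            HomologyGroup(
                group_id=gid,
                anchor_cluster_id=ref.cluster_id,
                anchor_key=key,
                anchor=ref.gene_by_key(key),
                role=ws.selected_gene_roles.get(key, ROLE_CBG),
                color_index=gid - 1,
            )
        )
    for bench in ws.bench_genes:
        gid += 1
        groups.append(
            HomologyGroup(
                group_id=gid,
                anchor_cluster_id=bench.source_cluster_id,
                anchor_key=bench.gene_key,
                anchor=ws.cluster(bench.source_cluster_id).gene_by_key(bench.gene_key),
                role=ROLE_BENCH,
                color_index=gid - 1,
            )
        )
    return groups


def map_to_clusters(
    ws: Workspace, params: AlignmentParams | None = None
) -> tuple[list[HomologyGroup], list[GeneAssignment]]:
    """Map every anchor gene onto every cluster of the workspace.

    Groups are numbered in reference genomic order, then bench order.  Each
    target gene joins at most one group: among anchors for which the homology
    predicate holds (anchor as query), the one with the highest identity wins
    (ties broken by higher score, then lower group id).  Anchor genes are
    self-assigned to their own groups.
    """
    params = params or AlignmentParams()
    if not ws.selected_reference_genes and not ws.bench_genes:
        raise ValueError(
            "nothing to map: select reference genes (or run automatic core-gene "
            "selection) and/or add bench genes first"
        )
    groups = _build_groups(ws)
    anchor_lookup = {(g.anchor_cluster_id, g.anchor_key): g for g in groups}

    assignments: list[GeneAssignment] = []
    for cluster in ws.clusters:
        for gene in cluster.genes:
            own = anchor_lookup.get((cluster.cluster_id, gene.key))
            if own is not None:
                self_res = align_local(gene.protein_seq, gene.protein_seq, params)
                assignments.append(
                    GeneAssignment(
                        cluster_id=cluster.cluster_id,
                        gene_key=gene.key,
                        gene=gene,
                        group_id=own.group_id,
                        identity=1.0,
                        score=self_res.score,
                    )
                )
                continue
            best: tuple[float, float, int] | None = None
            best_group: HomologyGroup | None = None
            for group in groups:
                res = align_local(group.anchor.protein_seq, gene.protein_seq, params)
                if not is_homologue(res, params):
                    continue
                rank = (res.identity, res.score, -group.group_id)
                if best is None or rank > best:
                    best = rank
                    best_group = group
            if best_group is not None and best is not None:
                assignments.append(
                    GeneAssignment(
                        cluster_id=cluster.cluster_id,
                        gene_key=gene.key,
                        gene=gene,
                        group_id=best_group.group_id,
                        identity=best[0],
                        score=best[1],
                    )
                )
    return groups, assignments


# -- workspace serialisation ---------------------------------------------

def workspace_to_dict(ws: Workspace) -> dict:
    return {
        "inputs": sorted({c.source_path for c in ws.clusters}),
        "reference": ws.reference_id,
        "marked": sorted(ws.marked_ids),
        "favorites": sorted(ws.favorite_ids),
        "selected_genes": [
            {"key": k, "role": ws.selected_gene_roles.get(k, ROLE_CBG)}
            for k in ws.selected_reference_genes
        ],
        "bench": [
            {"cluster": b.source_cluster_id, "gene": b.gene_key} for b in ws.bench_genes
        ],
        "notes": dict(sorted(ws.notes.items())),
    }


def save_workspace(ws: Workspace, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(workspace_to_dict(ws), fh, sort_keys=False)


def workspace_from_dict(doc: dict, clusters: list[ClusterRecord] | None = None) -> Workspace:
    """Rebuild a workspace from its serialised form.

    ``clusters`` may be supplied (e.g. already parsed); otherwise the files
    listed under ``inputs`` are parsed from disk.
    """
    if clusters is None:
        clusters = []
        for path in doc.get("inputs", []):
            clusters.extend(parse_genbank(path))
    ws = Workspace(
        clusters=clusters,
        reference_id=doc["reference"],
        marked_ids=set(doc.get("marked", [])),
        favorite_ids=set(doc.get("favorites", [])),
        notes=dict(doc.get("notes", {})),
    )
    for entry in doc.get("selected_genes", []):
        if isinstance(entry, str):
            ws.select_gene(entry)
        else:
            ws.select_gene(entry["key"], entry.get("role", ROLE_CBG))
    for entry in doc.get("bench", []):
        ws.add_bench_gene(entry["cluster"], entry["gene"])
    return ws


def load_workspace(path) -> Workspace:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return workspace_from_dict(doc)
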