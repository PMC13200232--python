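"""Synthetic BGC families with planted homology structure.

Generates GenBank-format cluster families that emulate what acquisition tools
return for a natural-product family: a set of clusters sharing core
biosynthetic genes at controlled protein identities, with unique
variant-specific tailoring genes (VSTGs) inserted into chosen clusters and
non-biosynthetic decoys (transporters, regulators) scattered throughout.
Every other module of the package is testable against these files without any
database download.

Source proteins are drawn uniformly over the 20 canonical amino acids under a
fixed seed; divergence is planted by point substitution only (no indels), so
the *ungapped* identity to the original is exact to within rounding.  Local-
alignment identity of a mutated pair can differ slightly from the planted
value (the optimal local alignment may trim noisy ends), which is why
recovery guarantees are stated with a margin around the homology threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: deterministic reverse-translation table (bacterial code, one codon per aa)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "X": "NNN",
}
_STOP = "TAA"

DECOY_PRODUCTS = (
    "ABC transporter permease",
    "MFS transporter",
    "TetR family transcriptional regulator",
    "Na+/H+ antiporter",
    "drug resistance MFS symporter",
    "LacI family transcriptional repressor",
)


class GenerationError(RuntimeError):
    """Raised when a family specification cannot be laid out."""


@dataclass(frozen=True)
class FamilySpec:
    """Blueprint of a synthetic cluster family.

    core_genes: per core gene, (protein length in aa, target identity) where
        the identity is either one fraction applied to every non-reference
        cluster or a per-cluster sequence of length ``n_clusters - 1``.
    vstg_insertions: (cluster index, product annotation, protein length).
    decoy_genes: product annotations (transport/regulatory vocabulary); each
        decoy appears once in every cluster with an unrelated random protein.
    """

    n_clusters: int
    core_genes: tuple[tuple[int, float | tuple[float, ...]], ...]
    vstg_insertions: tuple[tuple[int, str, int], ...] = ()
    decoy_genes: tuple[str, ...] = ()
    intergenic_bp: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        for length, ident in self.core_genes:
            idents = (ident,) if isinstance(ident, (int, float)) else tuple(ident)
            for x in idents:
                if not (0.0 <= x <= 1.0):
                    raise ValueError(f"target identity {x} outside [0, 1]")
            if not isinstance(ident, (int, float)) and len(idents) != self.n_clusters - 1:
                raise ValueError(
                    "per-cluster identity list must have n_clusters - 1 entries"
                )
        for ci, _, _ in self.vstg_insertions:
            if not (0 <= ci < self.n_clusters):
                raise GenerationError(f"VSTG cluster index {ci} out of range")


def random_protein(length: int, rng: np.random.Generator) -> str:
    if length < 1:
        raise ValueError("protein length must be >= 1")
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def ungapped_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("ungapped identity requires equal lengths")
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)


def mutate_to_identity(protein: str, target: float, seed: int) -> str:
    """Plant point substitutions until the ungapped identity to the original
    is within 0.05 of ``target``; deterministic for a given seed.

    Raises ValueError for infeasible requests (very low targets on very short
    proteins cannot be resolved at single-position granularity).
    """
    if not (0.0 <= target <= 1.0):
        raise ValueError(f"target identity {target} outside [0, 1]")
    if len(protein) < 10:
        raise ValueError("protein must be at least 10 residues")
    if target < 0.1 and len(protein) < 20:
        raise ValueError(
            "targets below 0.1 need proteins of at least 20 residues"
        )
    rng = np.random.default_rng(seed)
    n = len(protein)
    n_mut = int(round((1.0 - target) * n))
    positions = rng.choice(n, size=n_mut, replace=False)
    residues = list(protein)
    for pos in positions:
        alternatives = [aa for aa in AMINO_ACIDS if aa != residues[pos]]
        residues[pos] = alternatives[int(rng.integers(len(alternatives)))]
    mutated = "".join(residues)
    achieved = ungapped_identity(protein, mutated)
    if abs(achieved - target) > 0.05:
        raise ValueError(
            f"cannot reach identity {target} on length {n} "
            f"(achieved {achieved:.3f})"
        )
    return mutated


@dataclass(frozen=True)
class _PlannedGene:
    name: str
    protein: str
    product: str
    strand: int


def _plan_cluster(
    spec: FamilySpec,
    cluster_index: int,
    core_proteins: Sequence[str],
    rng: np.random.Generator,
) -> list[_PlannedGene]:
    genes: list[_PlannedGene] = []
    for k, ((length, ident), source) in enumerate(zip(spec.core_genes, core_proteins)):
        if cluster_index == 0:
            protein = source
        else:
            if isinstance(ident, (int, float)):
                target = float(ident)
            else:
                target = float(tuple(ident)[cluster_index - 1])
            protein = mutate_to_identity(
                source, target, seed=int(rng.integers(2**31 - 1))
            )
        genes.append(
            _PlannedGene(
                name=f"core{k:02d}",
                protein=protein,
                product=f"core biosynthetic protein {chr(ord('A') + (k % 26))}",
                strand=1 if rng.random() < 0.7 else -1,
            )
        )
    for vi, (ci, product, length) in enumerate(spec.vstg_insertions):
        if ci != cluster_index:
            continue
        pos = int(rng.integers(len(genes) + 1))
        genes.insert(
            pos,
            _PlannedGene(
                name=f"vstg{vi:02d}",
                protein=random_protein(length, rng),
                product=product,
                strand=1 if rng.random() < 0.7 else -1,
            ),
        )
    for di, product in enumerate(spec.decoy_genes):
        pos = int(rng.integers(len(genes) + 1))
        genes.insert(
            pos,
            _PlannedGene(
                name=f"decoy{di:02d}",
                protein=random_protein(int(rng.integers(120, 250)), rng),
                product=product,
                strand=1 if rng.random() < 0.7 else -1,
            ),
        )
    return genes


def _reverse_translate(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein) + _STOP


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _build_record(
    spec: FamilySpec, cluster_index: int, genes: list[_PlannedGene], rng: np.random.Generator
) -> SeqRecord:
    cluster_id = f"synfam{spec.seed}_c{cluster_index:02d}"
    organism = f"Streptomyces synfamiae {spec.seed}-{cluster_index}"
    nt_parts: list[str] = []
    features: list[SeqFeature] = []
    cursor = 0

    def spacer() -> str:
        return "".join(rng.choice(list("ACGT"), size=spec.intergenic_bp))

    nt_parts.append(spacer())
    cursor += spec.intergenic_bp
    for i, gene in enumerate(genes):
        cds = _reverse_translate(gene.protein)
        start, end = cursor, cursor + len(cds)
        if gene.strand == -1:
            nt_parts.append(cds.translate(_COMPLEMENT)[::-1])
        else:
            nt_parts.append(cds)
        cursor = end
        nt_parts.append(spacer())
        cursor += spec.intergenic_bp
        locus_tag = f"SYN{cluster_index:02d}_{i:04d}"
        features.append(
            SeqFeature(
                SimpleLocation(start, end, strand=gene.strand),
                type="CDS",
                qualifiers={
                    "locus_tag": [locus_tag],
                    "protein_id": [f"{locus_tag}.1"],
                    "product": [gene.product],
                    "transl_table": ["11"],
                    "translation": [gene.protein],
                    "note": [gene.name],
                },
            )
        )

    seq = Seq("".join(nt_parts))
    record = SeqRecord(
        seq,
        id=cluster_id,
        name=cluster_id[:16],
        description=f"synthetic BGC family member {cluster_index}",
        annotations={
            "molecule_type": "DNA",
            "organism": organism,
            "source": organism,
            "topology": "linear",
        },
    )
    record.features = [
        SeqFeature(
            SimpleLocation(0, len(seq), strand=1),
            type="source",
            qualifiers={"organism": [organism], "mol_type": ["genomic DNA"]},
        )
    ] + features
    return record


def generate_family(spec: FamilySpec, out_dir: str | Path) -> list[Path]:
    """Write one GenBank file per cluster and return the paths in cluster
    order; cluster 0 is the reference (it carries the unmutated core genes).

    The emitted files round-trip through :func:`bgcworkbench.parse_genbank`
    without warnings: every CDS carries /translation, /product and /locus_tag,
    and the nucleotide sequence agrees with the translation under the
    bacterial code.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    core_proteins = [random_protein(length, rng) for length, _ in spec.core_genes]

    paths: list[Path] = []
    for c in range(spec.n_clusters):
        genes = _plan_cluster(spec, c, core_proteins, rng)
        record = _build_record(spec, c, genes, rng)
        path = out_dir / f"{record.id}.gbk"
        SeqIO.write(record, str(path), "genbank")
        paths.append(path)
    return paths
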