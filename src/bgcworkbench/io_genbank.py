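"""GenBank input, CluSeek-dialect repair, and FASTA export.

Reads GenBank flat files (single- or multi-record) into :class:`ClusterRecord`
objects holding ordered CDS features with protein sequences.  Internal
coordinates are 0-based half-open; the 1-based inclusive GenBank convention is
converted at this boundary only, so a feature spanning GenBank ``a..b`` is
stored as ``[a-1, b)``.

Cluster exports produced by acquisition tools such as CluSeek frequently ship
with empty SOURCE/ORGANISM fields; :func:`repair_cluseek_record` recovers the
organism from the file-name stem, which is how those exports identify strains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Seq import Seq

from .alignment import PROTEIN_ALPHABET

logger = logging.getLogger(__name__)

#: NCBI translation table used for conceptual translation (bacterial code)
TRANSLATION_TABLE = 11

_ALPHABET_SET = frozenset(PROTEIN_ALPHABET)


class GenBankParseError(ValueError):
    """Raised when a file cannot be parsed as GenBank; names the path."""


@dataclass(frozen=True)
class GeneFeature:
    """One CDS feature of a cluster record.

    ``start``/``end`` are 0-based half-open base positions on the parent
    record; ``strand`` is +1 or -1.  ``source_index`` is the ordinal position
    of the CDS in file order and is unique within a record.
    """

    start: int
    end: int
    strand: int
    locus_tag: str | None
    protein_id: str | None
    product: str
    protein_seq: str
    source_index: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")
        bad = set(self.protein_seq) - _ALPHABET_SET
        if bad:
            raise ValueError(
                f"protein_seq must be drawn from {PROTEIN_ALPHABET}; "
                f"offending residues: {sorted(bad)!r}"
            )

    @property
    def key(self) -> str:
        """Stable identifier for workspace references: locus tag, else
        protein id, else a positional fallback."""
        return self.locus_tag or self.protein_id or f"cds{self.source_index}"

    @property
    def display_id(self) -> str:
        return self.protein_id or self.locus_tag or f"cds{self.source_index}"

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class ClusterRecord:
    """One parsed BGC region: ordered genes plus provenance."""

    cluster_id: str
    organism: str
    source_path: str
    seq_length: int
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cluster_id:
            raise ValueError("cluster_id must be non-empty")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.source_index))

    def gene_by_key(self, key: str) -> GeneFeature:
        for gene in self.genes:
            if gene.key == key:
                return gene
        raise KeyError(f"no gene {key!r} in cluster {self.cluster_id!r}")


def _sanitize_protein(raw: str) -> str:
    """Uppercase and map non-standard residues (B, Z, J, U, O, ...) to X."""
    return "".join(c if c in _ALPHABET_SET else "X" for c in raw.upper())


def _conceptual_translation(feature, parent_seq: Seq, label: str) -> str | None:
    """Translate a CDS span with the bacterial code, trimming the terminal stop.

    Returns None (and logs a warning) when no usable protein results, e.g.
    internal stop codons or a span shorter than one codon.
    """
    nt = feature.extract(parent_seq)
    if len(nt) < 3:
        logger.warning("%s: span shorter than one codon; feature skipped", label)
        return None
    trimmed = nt[: len(nt) - len(nt) % 3]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # partial-codon warnings already handled
        protein = str(trimmed.translate(table=TRANSLATION_TABLE))
    if protein.endswith("*"):
        protein = protein[:-1]
    if not protein:
        logger.warning("%s: empty conceptual translation; feature skipped", label)
        return None
    if "*" in protein:
        logger.warning("%s: internal stop codon; feature skipped", label)
        return None
    return _sanitize_protein(protein)


def _record_organism(annotations: dict) -> str:
    for key in ("organism", "source"):
        value = (annotations.get(key) or "").strip()
        if value and value != ".":
            return value
    return ""


def _filename_stem_to_organism(filename: str) -> str:
    # underscores separate words in export file names; dashes are kept since
    # they occur inside strain designations (e.g. "TP-A0274")
    stem = Path(filename).stem.replace("_", " ")
    return " ".join(stem.split())


def parse_genbank(path: str | Path, id_policy: str = "filename") -> list[ClusterRecord]:
    """Parse a GenBank flat file into one ClusterRecord per record.

    ``id_policy`` selects the cluster identifier: "filename" (stem, the
    CluSeek convention; multi-record files get a numeric suffix), "locus"
    (LOCUS name) or "accession" (VERSION/ACCESSION).

    Every CDS feature with a coordinate span becomes a GeneFeature.  The
    /translation qualifier is preferred; otherwise the span is conceptually
    translated with the bacterial genetic code and the terminal stop trimmed.
    Untranslatable features are skipped with a logged warning.  Records with
    zero CDS features are retained (with a warning) so provenance survives.
    """
    path = Path(path)
    if id_policy not in ("filename", "locus", "accession"):
        raise ValueError(f"unknown id_policy {id_policy!r}")
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise GenBankParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not seq_records:
        raise GenBankParseError(f"no GenBank records found in {path}")

    clusters: list[ClusterRecord] = []
    for rec_idx, rec in enumerate(seq_records):
        if id_policy == "filename":
            cluster_id = path.stem if rec_idx == 0 else f"{path.stem}_{rec_idx + 1}"
        elif id_policy == "locus":
            cluster_id = rec.name or rec.id
        else:
            cluster_id = rec.id or rec.name

        genes: list[GeneFeature] = []
        cds_index = 0
        for feature in rec.features:
            if feature.type != "CDS" or feature.location is None:
                continue
            source_index = cds_index
            cds_index += 1
            label = f"{path.name}:{cluster_id}:CDS#{source_index}"
            quals = feature.qualifiers
            raw_translation = (quals.get("translation") or [""])[0]
            if raw_translation:
                protein = _sanitize_protein(raw_translation.rstrip("*"))
            else:
                protein = _conceptual_translation(feature, rec.seq, label)
            if not protein:
                if raw_translation:
                    logger.warning("%s: unusable /translation qualifier; feature skipped", label)
                continue
            strand = feature.location.strand
            genes.append(
                GeneFeature(
                    start=int(feature.location.start),
                    end=int(feature.location.end),
                    strand=1 if strand in (1, None) else -1,
                    locus_tag=(quals.get("locus_tag") or [None])[0],
                    protein_id=(quals.get("protein_id") or [None])[0],
                    product=(quals.get("product") or [""])[0],
                    protein_seq=protein,
                    source_index=source_index,
                )
            )
        if cds_index == 0:
            logger.warning("%s: record %s has zero CDS features", path.name, cluster_id)

        cluster = ClusterRecord(
            cluster_id=cluster_id,
            organism=_record_organism(rec.annotations),
            source_path=str(path),
            seq_length=len(rec.seq),
            genes=genes,
        )
        clusters.append(repair_cluseek_record(cluster, path.name))
    return clusters


def repair_cluseek_record(record: ClusterRecord, filename: str) -> ClusterRecord:
    """Fill an empty organism from the file-name stem (CluSeek export repair).

    Underscores in the stem become spaces (dashes are preserved — they occur
    inside strain designations); a populated organism is left untouched.
    Always succeeds.
    """
    if record.organism.strip():
        return record
    return replace_organism(record, _filename_stem_to_organism(filename))


def replace_organism(record: ClusterRecord, organism: str) -> ClusterRecord:
    new = ClusterRecord(
        cluster_id=record.cluster_id,
        organism=organism,
        source_path=record.source_path,
        seq_length=record.seq_length,
        genes=list(record.genes),
    )
    return new


def export_fasta(genes: Iterable[GeneFeature], out: IO[str], width: int = 60) -> int:
    """Write protein FASTA (">{protein_id or locus_tag} {product}", 60-column
    wrap) and return the number of records written.  Genes with an empty
    protein sequence are skipped with a warning."""
    count = 0
    for gene in genes:
        if not gene.protein_seq:
            logger.warning("gene %s has empty protein sequence; skipped", gene.display_id)
            continue
        header = f">{gene.display_id} {gene.product}".rstrip()
        out.write(header + "\n")
        seq = gene.protein_seq
        for i in range(0, len(seq), width):
            out.write(seq[i : i + width] + "\n")
        count += 1
    return count


def to_genbank_span(gene: GeneFeature) -> tuple[int, int]:
    """Back-convert a half-open span to the 1-based inclusive GenBank span."""
    return gene.start + 1, gene.end
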