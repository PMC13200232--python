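"""Shared fixtures: hand-written GenBank text and a planted synthetic family."""

from __future__ import annotations

from pathlib import Path

import pytest

from bgcworkbench import FamilySpec, generate_family, parse_genbank


def genbank_text(
    locus: str,
    seq: str,
    features: list[str],
    organism: str | None = "Streptomyces tendae",
) -> str:
    """Assemble a minimal single-record GenBank flat file."""
    lines = [
        f"LOCUS       {locus:<16} {len(seq):>11} bp    DNA     linear   BCT 01-JAN-2024",
        f"DEFINITION  synthetic test record {locus}.",
        f"ACCESSION   {locus}",
        f"VERSION     {locus}.1",
    ]
    src = organism if organism is not None else "."
    lines += [f"SOURCE      {src}", f"  ORGANISM  {src}", "            Bacteria."]
    lines.append("FEATURES             Location/Qualifiers")
    lines.append(f"     source          1..{len(seq)}")
    for f in features:
        lines.append(f.strip("\n"))
    lines.append("ORIGIN")
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_genbank(tmp_path):
    def _write(name: str, text: str) -> Path:
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def simple_record_path(write_genbank):
    """One forward CDS with /translation MKT."""
    text = genbank_text(
        "TESTREC1",
        "ATGAAAACCTAA" + "GATTACA" * 4,
        [
            """
     CDS             1..12
                     /locus_tag="tst_0001"
                     /protein_id="TST00001.1"
                     /product="StaD-like chromopyrrolic acid synthase"
                     /translation="MKT"
            """
        ],
    )
    return write_genbank("simple.gbk", text)


FAMILY_SEED = 20240917

# study-condition family: 10 clusters, 6 core genes conserved at 0.60-0.90,
# 5 unique VSTGs with highlight-matching annotations, hidden decoys everywhere
FAMILY_SPEC = FamilySpec(
    n_clusters=10,
    core_genes=(
        (240, 0.90), (300, 0.85), (260, 0.80),
        (220, 0.72), (280, 0.66), (250, 0.60),
    ),
    vstg_insertions=(
        (2, "FAD-dependent monooxygenase", 210),
        (3, "cytochrome P450 hydroxylase", 230),
        (5, "O-methyltransferase", 190),
        (7, "flavin-dependent halogenase", 220),
        (9, "NDP-hexose glycosyltransferase", 260),
    ),
    decoy_genes=(
        "ABC transporter permease",
        "TetR family transcriptional regulator",
    ),
    intergenic_bp=150,
    seed=FAMILY_SEED,
)


@pytest.fixture(scope="session")
def family_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("family")
    return generate_family(FAMILY_SPEC, out)


@pytest.fixture(scope="session")
def family_clusters(family_paths):
    clusters = []
    for p in family_paths:
        clusters.extend(parse_genbank(p))
    return clusters
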