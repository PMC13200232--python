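# Methods

## Alignment model

Homology between two protein-coding genes is decided from a single optimal
local alignment (Smith–Waterman) of their protein sequences under affine gap
scoring: the first residue of a gap costs `open_gap_score` and each further
residue `extend_gap_score`, so a gap of length L costs `open + (L−1)·extend`.
A gap in one sequence immediately followed by a gap in the other re-opens
(costs `open`); with the default scores this never beats a mismatch, and the
convention matches Biopython's `PairwiseAligner`, against which the scores
are cross-checked in the test suite. Defaults: BLOSUM62, open −20,
extend −5. Ambiguous residues translate to `X` and score by the matrix's
`X` row, so unusual annotations degrade alignment quality instead of
crashing a run.

The aligner is implemented as a numba-compiled dynamic program returning the
score, the traceback, and two derived fractions:

- **identity** = identical columns / *all* alignment columns, gap columns
  included. The denominator choice is deliberate and centralised in
  `alignment.py`: counting gap columns penalises gappy matches, which is the
  conservative side for a homology cutoff.
- **query coverage** = query residues inside the local alignment / query
  length. The query is always the anchor gene (selected reference gene or
  bench gene), never the target, so coverage asks "how much of the known
  gene is accounted for".

The homology predicate is `identity ≥ identity_threshold` (inclusive,
default 0.40) **and** `query_coverage > coverage_threshold` (strict, default
0.50). Inclusive-vs-strict at the two boundaries is asymmetric on purpose:
the identity cutoff is described as "at least", the coverage bound as
"over"; both comparisons are in one function so the convention can be
changed in one place.

Tie-breaking is fully deterministic so runs are reproducible across
platforms: among equal-scoring alignments the end cell with the smallest
query index, then smallest target index, wins; within the traceback, match
columns are preferred over query-gap over target-gap columns, and a fresh
start is preferred when the running score ties zero. An all-negative scoring
landscape yields the empty alignment with identity and coverage defined
as 0.

Correctness is established by two independent oracles that share no code
with the production aligner: a literal enumeration of every local alignment
path (exponential, run on all pairs of length ≤ 3 over a 4-letter alphabet)
and a memoised top-down recursion over alignment end states (run on ~10⁴
pairs of length ≤ 6), plus the Biopython score cross-check on random
protein pairs.

## Workspace and mapping

- **Automatic CBG selection** uses intersection semantics: a reference gene
  is selected only if it has a homologue in *every* marked cluster. This is
  the stricter of the two readings of "has homologues in these clusters";
  union semantics ("at least one marked cluster") is available via
  `select_core_auto(..., require_all=False)`. Marking the reference itself
  is a no-op per gene (self-homology).
- **Assignment** is one-directional best-hit: each target gene joins the
  anchor group with the highest identity (ties: higher score, then lower
  group id). Reciprocal-best-hit filtering is not applied. Several
  paralogues in one cluster may join the same group if each independently
  passes the thresholds — tailoring-gene duplications are biologically real.
- Anchor genes are self-assigned to their own groups (identity 1.0), which
  also resolves the degenerate case of two identical anchors.
- Groups are numbered in reference genomic order, then bench order; the
  colour index is derived from the group number, so figures are stable.
- The workspace (reference, marked/favourite sets, selected genes, bench
  genes with provenance, notes) serialises to YAML; sessions are plain text
  and scriptable.

## Inspection view

The view window is the mapped span (half-open hull over assigned genes)
expanded by a configurable flank, default 10 kb per side — "direct
vicinity" is not a published number, and 10 kb spans a few genes in typical
actinomycete gene density. When nothing is mapped the whole record is in
view.

Keyword triage is case-insensitive plain substring matching (no regex —
predictable on free-text product lines). *Hide beats highlight* when a
product matches both lists; a "transporter-associated monooxygenase" is
dropped because a false negative is cheaper than noise in a triage view.
The default term lists extend the published examples with common members of
the same families; they are overridable in every entry point and an empty
highlight list yields zero candidates by construction.

## Rendering

SVG is emitted directly (no drawing library): one track per cluster, genes
as strand-oriented arrow polygons scaled by `px_per_bp`, group colours from
a fixed 12-colour categorical palette keyed by group id, unmapped genes
neutral grey. Ribbons connect *adjacent tracks only*, matching the usual
figure style: each assigned gene is paired with the best-identity
same-group gene on the next track, and the ribbon is drawn when that
pairwise identity is strictly above `ribbon_min_identity` (default 0.40).
Inspection mode dims mapped genes (opacity 0.25) and bolds candidate
product labels; hidden products get no label. Rendering is a pure function
of its inputs — identical inputs give byte-identical SVG. Interactive
re-anchoring is achieved by re-running with a different reference id rather
than by a GUI.

## Synthetic family generator

The generator emulates what an acquisition tool returns for one
natural-product family: `n_clusters` GenBank records sharing core genes at
controlled protein identities, with unique annotated tailoring genes
planted in chosen clusters and transporter/regulator decoys everywhere.
Source proteins are uniform over the 20 canonical amino acids under a fixed
seed; real proteins have biased composition and conserved domains, so
passing recovery tests here demonstrates the thresholding machinery, not
performance on real sequence divergence (real homologues diverge with
indels and domain shuffling that substitution-only mutation does not
model — hence no claim about sensitivity on real data).

Divergence is planted by point substitution only: `round((1−target)·L)`
distinct positions are changed to a different residue, so the ungapped
identity to the source is exact to within 0.5/L ≤ 0.05. Local-alignment
identity of such a pair can differ slightly from the planted value (the
optimal alignment may trim noisy ends), so recovery guarantees are stated
with margins: planted identities ≥ threshold + 0.10 must map 100 %,
≤ threshold − 0.15 must map 0 %. Proteins are reverse-translated with a
fixed one-codon-per-amino-acid table plus a TAA stop, placed on random
strands with fixed intergenic spacers, and written with `/translation`,
`/product`, `/locus_tag` and `/protein_id` qualifiers so the files
round-trip through the parser with zero warnings and exercise both the
qualifier and the conceptual-translation code paths.

Default study conditions used by the acceptance script and tests: 10
clusters, 6 core genes (220–300 aa) at identities 0.60–0.90, 5 unique VSTGs
with highlight-matching annotations, 2 hidden decoys per cluster. These
sizes keep a full map + inspect + render cycle around a second while every
core gene sits well above the 0.40 cutoff and every decoy well below.

## Input handling

Internal coordinates are 0-based half-open; GenBank's 1-based inclusive
convention is converted exactly once at the I/O boundary. Compound
(`join(...)`) CDS locations are translated across segments in order with the
strand of the compound location. `/translation` is preferred when present;
otherwise the span is translated with the bacterial code (table 11) and the
terminal stop trimmed. Features whose span yields no usable protein
(shorter than a codon, empty, or containing internal stops — likely
pseudogenes) are skipped with a logged warning. Non-standard residues
(B, Z, J, U, O) are normalised to `X`. Records with zero CDS features are
retained, with a warning, so provenance survives. Organism repair replaces
underscores in the file-name stem with spaces but keeps dashes, which occur
inside strain designations (`TP-A0274`).

## Limitations

- No heuristic seeding, E-values, or nucleotide alignment; all-vs-all
  pairwise alignment is quadratic in gene count and intended for families of
  tens to a few hundred clusters, not genome-scale sweeps.
- No BGC family clustering, phylogeny, or protein-family classification of
  candidates — candidates are exported as FASTA for downstream tools.
- Keyword triage is vocabulary-driven; genes with absent or uninformative
  product annotations are flagged `plain` and require manual review.
- The generator does not model rearrangements, inversions, indel evolution
  or nucleotide-level mutation.
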