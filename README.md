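# bgcworkbench

A headless comparison engine for **biosynthetic gene clusters (BGCs)**,
aimed at natural-product genome miners who have collected a family of
related clusters (from MIBiG, NCBI GenBank, or acquisition tools such as
CluSeek or cblaster) and want to find the genes that make one variant
different from the others.

The model behind the workflow: a BGC family shares a set of **core
biosynthetic genes (CBGs)** that build the common scaffold, while individual
variants carry **variant-specific tailoring genes (VSTGs)** — cytochrome
P450s, glycosyltransferases, halogenases, methyltransferases — that decorate
the scaffold into distinct congeners. Given one well-characterised
*reference* cluster, the engine:

1. **Parses** GenBank flat files into gene lists (repairing the empty
   SOURCE/ORGANISM fields common in CluSeek exports from the file name).
2. **Selects CBGs** automatically: reference genes with a homologue in every
   *marked* cluster, or a manual selection; known VSTGs from other clusters
   can be added via a *gene bench*.
3. **Maps** each selected gene onto every cluster. Homology is decided by
   pairwise Smith–Waterman local alignment with affine gaps
   (BLOSUM62, gap open −20, gap extend −5); a target gene *t* is a homologue
   of query *g* iff

   identity(g, t) ≥ 0.40  and  query-coverage(g, t) > 0.50

   where identity is counted over all alignment columns (gaps included) and
   coverage over the query. Each target gene joins at most one homology
   group — the anchor with the highest identity.
4. **Inspects**: per cluster, the span covering all mapped genes is computed,
   mapped genes are suppressed, and the remaining genes in a ±10 kb flank
   are triaged by their product annotation — *hidden* (transporter,
   regulator, …), **highlighted** (transferase, cytochrome P450,
   monooxygenase, …) or plain. Highlighted unmapped genes are the candidate
   VSTGs and can be exported as FASTA.
5. **Renders** a clinker-style SVG: one track per cluster, arrows coloured by
   homology group, ribbons between homologues on adjacent tracks sharing
   >40 % identity; inspection mode dims mapped genes and bolds candidate
   annotations.

A seeded synthetic-family generator (`bgcworkbench.synthetic`) emits
GenBank files with planted homology structure, so the whole pipeline is
testable offline.

## Worked example

Generate a 4-cluster synthetic family with 3 core genes (identities 0.85,
0.75, 0.65 to the reference), 2 planted tailoring genes and
transporter/regulator decoys, then map and inspect it:

```sh
cat > family.yaml <<'EOF'
family:
  n_clusters: 4
  core_genes: [[240, 0.85], [300, 0.75], [260, 0.65]]
  vstg_insertions:
    - [2, "FAD-dependent monooxygenase", 210]
    - [3, "NDP-hexose glycosyltransferase", 260]
  decoy_genes: ["ABC transporter permease", "TetR family transcriptional regulator"]
  seed: 11
EOF
bgcworkbench synth --config family.yaml --outdir demo

cat > run.yaml <<'EOF'
inputs: ["demo/*.gbk"]
marked: ["synfam11_c01"]
outdir: demo_out
EOF
bgcworkbench map --config run.yaml
bgcworkbench inspect --config run.yaml
bgcworkbench render --config run.yaml --inspection
```

`demo_out/assignments.tsv` shows the three core genes recovered in all four
clusters at identities matching the planted values (group 1 ≈ 0.85, group 2
= 0.75, group 3 ≈ 0.65; reference self-assignments at 1.000):

```
cluster_id	gene	group_id	identity	score	start	end	strand
synfam11_c00	SYN00_0001	1	1.000	1417	766	1489	+
synfam11_c01	SYN01_0000	1	0.854	1160	200	923	+
synfam11_c01	SYN01_0001	2	0.750	1206	1123	2026	+
synfam11_c01	SYN01_0004	3	0.653	839	3616	4399	-
...
```

The inspection table hides the decoys and flags exactly the two planted
tailoring genes, which also appear in `demo_out/candidates.fasta`:

```
synfam11_c02	SYN02_0004.1	3613	4246	+	highlighted	-	-	FAD-dependent monooxygenase
synfam11_c03	SYN03_0000.1	200	983	-	highlighted	-	-	NDP-hexose glycosyltransferase
```

`demo_out/run.log` records the parameters actually used
(`matrix=BLOSUM62`, `open_gap_score=-20.0`, `extend_gap_score=-5.0`,
`identity_threshold=0.4`, `coverage_threshold=0.5`), and
`demo_out/comparison.svg` is the ribbon figure.

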