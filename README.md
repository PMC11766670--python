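# rnaevo

Tools for studying the evolution of SSU rRNA V4 secondary structure in
ciliates of the genus *Euplotes* (and congeners): extraction of the V4
hypervariable region from full-length small-subunit rRNA genes, secondary
structure prediction with a consensus reference, Type I/Type II
classification of helix E23_8 topology, compensatory base change (CBC)
counting for cryptic-species delimitation, and Fitch parsimony ancestral
state reconstruction with detection of reversals ("reverse evolution").

It is written for molecular systematists who have a set of SSU rRNA
sequences and a phylogeny, and want the structural character analysis —
which helices are present, which lineages gained or lost them, and which
taxon pairs differ by bond-preserving compensatory changes — as a
scriptable, testable pipeline rather than a chain of GUI tools.

## The analysis

**V4 extraction.** The V4 expansion segment (163–261 nt in this group)
sits between strongly conserved flanks. Short consensus anchors are
derived from any reference alignment in which the V4 columns are known and
located in each full-length sequence by best-scoring ungapped match
(match +1, mismatch −1, N matches nothing); the region strictly between
the anchors is the V4.

**Folding.** Per-sequence structures maximize a total pair score over all
pseudoknot-free structures with hairpin loops of at least 3 nt
(Nussinov-style dynamic programming):

    M(i,j) = max[ M(i+1,j),  max_{k: i+4≤k≤j} s(i,k) + M(i+1,k−1) + M(k+1,j) ]

with pair scores s(G:C) = 3, s(A:U) = 2, s(G:U) = 1. Consensus folding
runs the same recursion on alignment columns, scoring a column pair as the
sum of per-row pair scores, plus a covariance bonus for every distinct
pair type beyond the first (compensatory variation is positive evidence
for pairing), minus a penalty for rows that cannot pair. Predicted
structures are curated by two rules: 1×1 internal loops whose unpaired
residues are G and C are closed, and helices carrying two or more
non-canonical pairs are removed. When several candidate structures exist,
the one with the best score — ties broken by base-pair F1 against the
consensus reference — is kept. The pair-score model deliberately replaces
a full thermodynamic energy model; helix topology, not free energy, is the
quantity the downstream analysis consumes (see `docs/methods.md`).

**Topology.** The structure is decomposed into stacked helices, helices
separated by small internal loops are grouped into stems, and the largest
top-level stem is designated E23_8. Walking distally along E23_8: a
terminal hairpin loop means **Type I**; a multiloop carrying two or more
sub-helices (E23_11/E23_12) means **Type II**.

**CBC.** At a paired column (k,l) of a shared consensus structure, two
taxa show a CBC when both partner residues differ while each taxon still
pairs canonically (G:C, A:U) or by G:U wobble; a hemi-CBC changes one
partner with pairing preserved. Even a single CBC between taxa is evidence
for separate (possibly cryptic) species.

**Ancestral states.** The Type I/II character is mapped on a rooted tree
by Fitch parsimony (unordered, equal costs; polytomies supported).
Ambiguous nodes are resolved under ACCTRAN, DELTRAN or a prefer-ancestral
rule via min-cost backtracking, so every resolved history attains the
parsimony minimum. Reversals — edges whose derived state equals the root
state, i.e. Type II → Type I losses of the extra helices — are reported
with the clades they subtend. Note that the choice of rule matters:
DELTRAN reads the same data as parallel gains, which is why the pipeline
reports the rule alongside the counts.

A synthetic-data generator (`rnaevo.synthetic_data`) produces cohorts with
known ground truth — Yule trees, template V4s with four stems, block
insertions/deletions toggling the Type II helices, compensatory stem
evolution, and planted CBC/reversal events — so every stage is testable
without downloading anything.

## Worked example

Run the whole pipeline on the shipped 12-taxon synthetic cohort, which
carries one Type I → Type II gain, two reversals back to Type I, and one
planted CBC on taxon t9:

```python
from rnaevo import synthetic_data as sd
from rnaevo.pipeline import RunConfig, run

cohort = sd.fixture_suite()
report = run(RunConfig(
    sequences=cohort.sequences, tree=cohort.tree,
    alignment=cohort.alignment, profile=sd.default_anchor_profile(),
    cbc_taxa=["t8", "t9", "t10"]))

print(report.per_taxon[["taxon", "v4_length", "struct_type",
                        "terminal_hairpin_size", "n_distal_subhelices"]]
      .to_string(index=False))
print(report.cbc.to_string())
print(f"parsimony: {report.n_steps} steps, {report.n_gains} gain(s), "
      f"{report.n_reversals} reversal(s); root state {report.root_state}")
```

prints

```
taxon  v4_length struct_type  terminal_hairpin_size  n_distal_subhelices
   t1        167      TYPE_I                   21.0                    0
   t2        167      TYPE_I                   21.0                    0
   t3        167      TYPE_I                   21.0                    0
   t4        167      TYPE_I                   21.0                    0
   t5        188     TYPE_II                    NaN                    2
   t6        188     TYPE_II                    NaN                    2
   t7        167      TYPE_I                   21.0                    0
   t8        188     TYPE_II                    NaN                    2
   t9        188     TYPE_II                    NaN                    2
  t10        188     TYPE_II                    NaN                    2
  t11        167      TYPE_I                   21.0                    0
  t12        167      TYPE_I                   21.0                    0
     t8  t9  t10
t8    0   1    0
t9    1   0    1
t10   0   1    0
parsimony: 3 steps, 1 gain(s), 2 reversal(s); root state TYPE_I
```

Reading it: every Type I taxon ends E23_8 in a 21-nt terminal hairpin and
every Type II taxon carries the two extra sub-helices; V4 lengths (167 and
188 nt) fall inside the 163–261 nt range typical of the group. In the
clade-VI-like trio t8/t9/t10, taxon t9 — the planted analogue of a cryptic
species — differs from both neighbours by exactly one CBC while t8 and t10
show none. The reconstruction places a single gain of the extra helices at
the base of the derived clade and two independent reversals to Type I (on
t7 and on the t11+t12 clade), i.e. reverse evolution of the structural
character.

The same stages are available from the shell: `rnaevo simulate`,
`rnaevo extract-v4`, `rnaevo fold`, `rnaevo classify`, `rnaevo cbc`,
`rnaevo asr` and `rnaevo run` (see `--help` on each).

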