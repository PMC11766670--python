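# Methods

This note records the models behind `rnaevo`, the parameters that matter,
the design choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Coordinate and alphabet conventions

All coordinates are 0-based with half-open intervals `[start, end)`.
Sequences are normalized on input to {A, C, G, U, N}: T→U (the gene is
sequenced as DNA and folded as RNA), lowercase uppercased, and IUPAC
degenerate codes other than N collapsed to N; the conversion is logged
once per file. N never pairs anywhere downstream. Dot-bracket is the
canonical structure interchange; CT files are read-only. Trees may lack
branch lengths (parsimony uses topology only).

## V4 extraction

Anchors are majority-rule consensi (ties broken alphabetically,
gap-majority columns dropped) of the alignment columns flanking the known
V4 interval; default anchor length 20 nt, chosen so that at the ~5%
per-site flank divergence seen within the genus a true placement still
wins by a wide margin while the admissibility ceiling
(`max_mismatch_fraction`, default 0.2) rejects spurious hits. The search
is ungapped by design: the flanks of V4 are strongly conserved, and an
ungapped scorer is dependency-free and exactly testable. Equal-scoring
placements resolve to the leftmost; among admissible right-anchor
placements the nearest downstream one wins (shortest V4), which prevents
run-on regions in partial sequences. Anchors ship as code-buildable
profiles, not hard-coded database extracts.

The boundary columns of V4 are profile-dependent: different reference
alignments give slightly different anchors and hence slightly different
excised intervals. Only the 163–261 nt length range is treated as a
constraint.

## Folding model

Per-sequence folding maximizes total pair score over pseudoknot-free
structures with a minimum hairpin of 3 unpaired nt (steric minimum), by
Nussinov-style dynamic programming. Pair scores are dimensionless weights
G:C = 3, A:U = 2, G:U = 1, reflecting relative pair stability.

This is the package's central declared approximation: it replaces a
nearest-neighbour thermodynamic model. The quantities consumed downstream
— helix topology (Type I/II), paired columns for CBC counting — depend on
*which positions pair*, and on designed templates the score optimum
coincides with the thermodynamic optimum (the optional RNAfold
cross-check reports base-pair F1 = 1.0 on the fixture cohort). On real,
mutation-rich sequences the two models diverge, and per-species structures
from this package are model-dependent; the algorithmic properties (DP
optimality, determinism, curation idempotence) are exact regardless.

Determinism: the traceback prefers leaving the 5' residue unpaired over
pairing it, and among pairing branches takes the smallest 3' partner, so
there is exactly one canonical optimum structure per input. Sequences too
short to pair return the empty structure with score 0 rather than erroring.

### Consensus folding

The same DP runs on alignment columns with

    score(k,l) = Σ_rows s(row_k, row_l)
               + covariance_bonus × (distinct valid pair types − 1)
               − inconsistency_penalty × (# rows that cannot pair)

Gaps count as cannot-pair (the convention of covariance folding: a
non-supporting row is evidence against the column pair). Non-positive
column scores forbid the pair. Defaults: bonus 1.0, penalty 0.5 — the
bonus rewards each observed compensatory pair type with about a third of
a G:C pair, enough to favour covarying columns without overriding the
sum of per-row scores. Projection onto a row drops pairs with a gap or a
non-pairing duo; it can never introduce crossing pairs.

### Curation

Two total, idempotent rules, applied to a fixed point (a bound of one
iteration per residue guards termination):

1. a 1×1 internal loop whose two unpaired residues are G and C (either
   orientation) is closed, extending the helix;
2. a helix (maximal stacked run) containing ≥ 2 non-canonical pairs is
   removed entirely. "Two or more" is the reading of "multiple"; one
   non-canonical pair inside an otherwise supported helix is tolerated.

Candidate selection orders structures by (score, base-pair F1 against the
consensus reference, lexicographically smallest dot-bracket) — a total
deterministic order. The F1 criterion operationalizes "best compatibility
with similar sequences", which has no standard quantitative definition;
it is flagged as this package's choice.

## Helix topology and Type I/II classification

Helices are maximal stacked runs; every pair belongs to exactly one
helix. Stems group nested helices separated by internal loops/bulges of
at most `bulge_tol` (default 3) unpaired nt per side; multiloops always
break stems. The default tolerance matches the drawn continuity of E23_8
stems in published V4 diagrams while keeping multiloops hard breaks.

E23_8 is identified as the top-level stem with the greatest total pair
count (ties to the 3'-most). Published helix nomenclature does not define
the drawn-label → coordinate mapping, so the rule is explicit and
configurable (`largest | last | index:k`). Classification then walks
distally from E23_8 through internal loops of *any* size (the tolerance
only affects stem labelling, making classification robust to odd bulges):
ending at a hairpin gives Type I with the loop size in nt; ending at a
multiloop with ≥ 2 enclosed sub-helices gives Type II, with the first two
children labelled E23_11/E23_12. Structures with no pairs are
UNCLASSIFIED and are excluded (with a warning) from the character matrix.

## CBC counting

For each paired column (k,l) of the shared consensus structure and taxon
pair (A,B): columns with a gap or N in any of the four residues are
skipped (`skipped-gap`), columns where either taxon's duo is not
canonical/wobble are skipped (`skipped-nonpairing`) — the statistic is
about changes in *bonds*, so non-pairing duos are excluded rather than
counted. Otherwise: both sides differ → CBC; exactly one side → hemi-CBC.
The verdict table is checked exhaustively (4⁴ residue combinations)
against an independently coded restatement of the definition. hCBC is
reported alongside CBC as a standard companion statistic at zero cost.

By default the whole V4 is compared; counting can be restricted to a
column window (e.g. helix E23_8 only) via `restrict_to_stem`. The pair
columns come from the consensus of the taxa actually under comparison
(e.g. the clade VI subset), not the genus-wide consensus.

## Ancestral reconstruction

The character is unordered binary with equal costs (the Mesquite-style
default; no step matrix is assumed). The Fitch downpass generalizes to
polytomies by folding intersection-else-union across children; the step
count equals the number of union events and is verified against the
Sankoff minimum internally (assertion) and against exhaustive enumeration
in tests. Outgroups are ordinary tips; rooting comes from the input tree.

Resolution of ambiguous nodes backtracks through the min-cost table, so
**every** rule yields a labelling attaining the parsimony minimum:

* **DELTRAN** (library default): keep the parent's state when admissible —
  delays changes tipward;
* **ACCTRAN**: prefer an admissible state different from the parent —
  accelerates changes rootward;
* **prefer-ancestral**: prefer a nominated state (default the
  alphabetically first, TYPE_I) when admissible.

Ambiguous roots resolve to the preferred state when admissible. A
reversal is a change whose derived state equals the resolved root state
(Type II → Type I under a Type I root).

The rule choice is not neutral: a planted gain-plus-reversal history is
reconstructed as such under ACCTRAN but as parallel independent gains
under DELTRAN at identical parsimony cost. Because the pipeline's purpose
is to surface reversals when the data support them, the *pipeline* default
is ACCTRAN, the library default stays DELTRAN, and reports always carry
the rule used so the dependence is visible rather than silently chosen.

## Synthetic data: what it emulates, and what it does not

The generator produces: Yule (pure-birth) trees with branch lengths in
substitutions/site so rates compose directly; a hand-designed V4 template
with four top-level stems (7, 6, 22 and 7 pairs — the 22-pair stem is
E23_8) embedded in fixed pseudo-random conserved flanks at ~1.8 kb total
scale; a Type I variant (167 nt, 21-nt terminal hairpin) and a Type II
variant (188 nt, two distal 6-bp sub-helices), both inside the empirical
163–261 nt range. The Type II block is a fixed literal insertion whose
removal/insertion toggles the type, mirroring the inferred indel origin
of the extra helices. Stems use only G/C and loops only A, so under the
default pair scores the designed pairing is the unique score optimum and
folding-based classification is exact on unmutated sequences.

Stem evolution is compensatory: a configurable fraction (default 0.9) of
stem substitutions instantly rewrites the partner to a different canonical
pair — a clean CBC — and the remainder mutate one side only. Compensation
is instantaneous by design: it matches the CBC concept being tested,
not a full covarion model. Planted events (forced type toggles on named
edges, forced CBCs on terminal branches) use orientation swaps (G:C→C:G)
so they never change the stem alphabet. A single numpy Generator seeded
from the config drives every draw; identical configs give byte-identical
output, and every tip is reproducible by replaying its event log.

Deliberately not emulated: realistic SSU covariance structure, indels
other than the single block and none in flanks, rate heterogeneity across
sites, and base-composition bias. Consequently, passing the planted-event
tests shows the *algorithms* are correct under the stated model; it does
not show that the pair-score folder recovers MFOLD-quality structures on
GenBank sequences. That step is checked only best-effort via the optional
RNAfold cross-check, and under realistic loop-mutation loads (≥ 3% per
site per branch) fold-based classification degrades noticeably — a known
limitation of the simplified energy model.

## Study conditions and problem sizes

Chosen once as this package's test conditions: oracle checks use 300
random 8–16-mers (folding), the full 256-entry residue table (CBC), 200
random 4–8-tip trees (Fitch) and 200 random structure/sequence pairs
(curation idempotence) — sizes at which exhaustive enumeration is exact
yet fast. The fixture cohort has 12 taxa on a fixed tree with one gain,
two reversals and one planted CBC, no stem noise, and 5% flank
divergence. Planted-reversal recovery uses 100 replicates of 16-taxon
Yule trees with stray-toggle probability 0.003/branch (~0.09 stray events
per replicate): recovery of a *specific* planted edge is only well-posed
when stray events are an order of magnitude rarer than the planted
signal, since a stray toggle on the relevant lineages rewrites the very
history being recovered. The planted reversal edge is placed at least two
edges below the gain edge; otherwise the surviving Type II tips form a
single clade and one independent gain is more parsimonious than
gain-plus-reversal, making the reversal unidentifiable in principle.
Extraction accuracy uses 100 replicates at 5% per-site flank divergence.

## Degenerate inputs and edge cases

Empty or too-short sequences fold to the empty structure (score 0); empty
alignments are errors; unpaired structures classify UNCLASSIFIED; tips
without character states are pruned with a warning while matrix taxa
missing from the tree are errors; a taxon whose V4 cannot be located is
dropped from the run with reason code `v4_not_found` and listed exactly
once in the exclusion log. Score comparisons in the folding traceback use
exact float equality on sums of small integers and `math.isclose` where a
recomputed sum is compared, which is safe at these magnitudes.

## Known limitations

* No thermodynamic energies, pseudoknots, suboptimal ensembles or
  temperature dependence; printed loop sizes on real accessions are
  model-dependent and only the template-level 21-nt Type I hairpin is
  exactly reproduced here.
* No de novo multiple alignment: an alignment is an input (or synthetic).
* CBC counting assumes the consensus pair columns apply to both taxa;
  columns where either taxon deviates are skipped, not re-folded.
* ACCTRAN/DELTRAN selection among equally parsimonious histories is a
  genuine epistemic limit of parsimony, surfaced but not resolved.
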