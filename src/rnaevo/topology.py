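"""Helix decomposition and Type I/II classification of V4 structures.

In the eukaryotic SSU rRNA, the V4 expansion segment carries four major
stems; the largest, helix E23_8, is the variable one.  Its distal end
either closes in a single terminal hairpin loop (Type I) or opens into a
multiloop carrying two extra sub-helices, E23_11 and E23_12 (Type II).
This module decomposes a nested pair set into stacked helices, groups
helices separated by small internal loops into drawn "stems", labels the
top-level stems, and classifies the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structure import SecondaryStructure

TYPE_I = "TYPE_I"
TYPE_II = "TYPE_II"
UNCLASSIFIED = "UNCLASSIFIED"

DEFAULT_BULGE_TOL = 3


@dataclass
class Helix:
    """A maximal run of stacked pairs (i,j),(i+1,j-1),...; >= 1 pair."""

    pairs: list
    parent: "Helix | None" = None
    children: list = field(default_factory=list)
    label: str | None = None

    @property
    def outer(self) -> tuple:
        return self.pairs[0]

    @property
    def inner(self) -> tuple:
        return self.pairs[-1]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def __repr__(self):
        return f"Helix({self.outer}..{self.inner}, {self.n_pairs}bp)"


@dataclass
class Stem:
    """Consecutive nested helices separated only by small internal loops.

    A drawn "helix" in secondary-structure figures is a Stem here; a
    multiloop always terminates a stem.
    """

    helices: list
    label: str | None = None

    @property
    def n_pairs(self) -> int:
        return sum(h.n_pairs for h in self.helices)

    @property
    def outer(self) -> tuple:
        return self.helices[0].outer

    @property
    def terminal(self) -> Helix:
        return self.helices[-1]


@dataclass
class TopologyReport:
    """Classification of one V4 structure."""

    taxon_id: str
    struct_type: str
    n_top_stems: int = 0
    e23_8_pairs: int = 0
    terminal_hairpin_size: int | None = None
    n_distal_subhelices: int = 0
    stems: list = field(default_factory=list)

    def __post_init__(self):
        if self.struct_type == TYPE_I and self.terminal_hairpin_size is None:
            raise ValueError("TYPE_I requires a terminal hairpin size")
        if self.struct_type == TYPE_II and self.n_distal_subhelices < 2:
            raise ValueError("TYPE_II requires >= 2 distal sub-helices")


def find_helices(structure: SecondaryStructure) -> list:
    """Decompose pairs into maximal stacked helices, as a nesting forest.

    Every pair belongs to exactly one helix; the returned list is ordered
    5'->3' by the helix's outermost pair, with parent/children links set.
    """
    pairset = set(structure.pairs)
    helices = []
    for i, j in sorted(pairset):
        if (i - 1, j + 1) in pairset:
            continue  # not the outermost pair of its helix
        run = [(i, j)]
        while (run[-1][0] + 1, run[-1][1] - 1) in pairset:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        helices.append(Helix(pairs=run))

    # tightest-enclosure nesting; helix intervals are nested or disjoint
    stack: list[Helix] = []
    for h in helices:  # already sorted by outer i
        oi, oj = h.outer
        while stack and not (stack[-1].outer[0] < oi and oj < stack[-1].outer[1]):
            stack.pop()
        if stack:
            h.parent = stack[-1]
            stack[-1].children.append(h)
        stack.append(h)
    return helices


def group_stems(forest: list, bulge_tol: int = DEFAULT_BULGE_TOL) -> list:
    """Merge helices separated by internal loops/bulges <= bulge_tol per side.

    A helix extends its stem into its child only when it has exactly one
    child (an internal loop, not a multiloop) and the unpaired gap on each
    side is at most *bulge_tol*.  Grouping is idempotent and deterministic.
    """
    stems = []
    in_stem = set()
    for h in forest:
        if id(h) in in_stem:
            continue
        # h starts a stem only if it cannot be absorbed by its parent
        if h.parent is not None and _extends(h.parent, h, bulge_tol):
            continue
        chain = [h]
        cur = h
        while len(cur.children) == 1 and _extends(cur, cur.children[0], bulge_tol):
            cur = cur.children[0]
            chain.append(cur)
        in_stem.update(id(x) for x in chain)
        stems.append(Stem(helices=chain))
    return stems


def _extends(parent: Helix, child: Helix, bulge_tol: int) -> bool:
    if len(parent.children) != 1:
        return False
    left = child.outer[0] - parent.inner[0] - 1
    right = parent.inner[1] - child.outer[1] - 1
    return left <= bulge_tol and right <= bulge_tol


def hairpin_size(stem: Stem) -> int:
    """Unpaired residues enclosed by the stem's innermost pair.

    Raises ValueError when the stem does not terminate in a hairpin.
    """
    term = stem.terminal
    if term.children:
        raise ValueError("not a hairpin: stem terminates in a multiloop or "
                         "continues past a large internal loop")
    i, j = term.inner
    return j - i - 1


def label_e23(stems: list, rule: str = "largest") -> Stem | None:
    """Label top-level stems and designate helix E23_8.

    Top-level stems (whose outer helix has no parent) are labelled
    ``H1..Hk`` 5'->3'.  E23_8 is chosen by *rule*:

    * ``largest`` (default): greatest total pair count, ties to the 3'-most;
    * ``last``: the 3'-most top-level stem;
    * ``index:k``: the k-th (0-based, 5'->3') top-level stem.

    Returns the E23_8 stem (relabelled), or None when there are no stems.
    """
    top = sorted((s for s in stems if s.helices[0].parent is None),
                 key=lambda s: s.outer[0])
    for idx, s in enumerate(top):
        s.label = f"H{idx + 1}"
    if not top:
        return None
    if rule == "largest":
        e23_8 = max(top, key=lambda s: (s.n_pairs, s.outer[0]))
    elif rule == "last":
        e23_8 = top[-1]
    elif rule.startswith("index:"):
        k = int(rule.split(":", 1)[1])
        if not 0 <= k < len(top):
            raise ValueError(f"e23-8 rule index {k} out of range ({len(top)} stems)")
        e23_8 = top[k]
    else:
        raise ValueError(f"unknown E23_8 rule {rule!r}")
    e23_8.label = "E23_8"
    return e23_8


def classify(structure: SecondaryStructure, bulge_tol: int = DEFAULT_BULGE_TOL,
             e23_rule: str = "largest") -> TopologyReport:
    """Classify a V4 structure as Type I or Type II.

    The walk proceeds distally from the E23_8 stem through internal loops
    and bulges of any size; if it ends at a hairpin the structure is Type I
    (with the hairpin-loop size in nt), if it ends at a multiloop with >= 2
    enclosed sub-helices it is Type II.  Structures with no pairs are
    UNCLASSIFIED.  Total function: never raises on valid structures.
    """
    if not structure.pairs:
        return TopologyReport(taxon_id=structure.seq_id, struct_type=UNCLASSIFIED)
    forest = find_helices(structure)
    stems = group_stems(forest, bulge_tol)
    e23_8 = label_e23(stems, rule=e23_rule)
    n_top = sum(1 for s in stems if s.helices[0].parent is None)

    cur = e23_8.terminal
    while len(cur.children) == 1:
        cur = cur.children[0]
    if not cur.children:
        i, j = cur.inner
        return TopologyReport(
            taxon_id=structure.seq_id, struct_type=TYPE_I, n_top_stems=n_top,
            e23_8_pairs=e23_8.n_pairs, terminal_hairpin_size=j - i - 1,
            stems=stems,
        )
    # multiloop: label the first two distal sub-helices E23_11 / E23_12
    kids = sorted(cur.children, key=lambda h: h.outer[0])
    for sub_label, kid in zip(("E23_11", "E23_12"), kids):
        for s in stems:
            if s.helices[0] is kid:
                s.label = sub_label
    return TopologyReport(
        taxon_id=structure.seq_id, struct_type=TYPE_II, n_top_stems=n_top,
        e23_8_pairs=e23_8.n_pairs, n_distal_subhelices=len(kids), stems=stems,
    )
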