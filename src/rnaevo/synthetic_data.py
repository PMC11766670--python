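"""Synthetic SSU rRNA V4 evolution with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a clocklike Yule tree over a configurable number of taxa;
* a V4-like region embedded between conserved flanks, built from a
  hand-designed template with four top-level stems, the largest being
  helix E23_8 (167 nt in the Type I template, 188 nt in Type II, inside
  the empirical 163-261 nt range);
* a binary structural character evolving by insertion/deletion of a fixed
  helix-forming block: Type I ends E23_8 in a 21-nt terminal hairpin,
  Type II carries the two extra sub-helices E23_11/E23_12 in its place;
* stem positions evolving under a compensatory model (a configurable
  fraction of stem substitutions instantly rewrites the partner base to a
  different canonical pair — a clean CBC), the rest hemi- or
  non-compensatory;
* optional forced events: planted type changes on named edges and planted
  CBCs on terminal branches.

Stems in the templates use only G/C and loops only A, so the designed
pairing is the unique score-optimal assignment under the default fold
parameters and folding-based classification can succeed on unmutated
sequences.  Every stochastic draw comes from a single numpy Generator
seeded from the config, so outputs are byte-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .cbc import PairColumns
from .region_extract import AnchorProfile
from .seqio import Alignment, RnaSequence, read_newick_string
from .structure import SecondaryStructure
from .topology import TYPE_I, TYPE_II

_COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A"}
_CANONICAL_DUOS = (("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"))
_BASES = "ACGU"


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


# --- V4 template -----------------------------------------------------------
# 5' strands of the six stems; 3' strands are exact reverse complements.
_STEM5 = {
    "s1": "GGCGGCC",          # first top-level stem, 7 bp
    "s2": "GCCGCG",           # second top-level stem, 6 bp
    "e23a": "GGCGCCGGGCGGCG",  # E23_8 proximal helix, 14 bp
    "e23b": "GCGGGCCG",       # E23_8 distal helix, 8 bp
    "e11": "GGGCGC",          # E23_11, 6 bp (Type II only)
    "e12": "GCGGCG",          # E23_12, 6 bp (Type II only)
    "s4": "GCCGGGC",          # last top-level stem, 7 bp
}

#: segment name -> literal residues at the root (loops are inert poly-A)
TEMPLATE_SEGMENTS = {
    "tail5": "A" * 8,
    "s1_5": _STEM5["s1"], "loop1": "A" * 12, "s1_3": _revcomp(_STEM5["s1"]),
    "link1": "A" * 4,
    "s2_5": _STEM5["s2"], "loop2": "A" * 9, "s2_3": _revcomp(_STEM5["s2"]),
    "link2": "A" * 4,
    "e23a_5": _STEM5["e23a"], "il1_5": "A" * 3,
    "e23b_5": _STEM5["e23b"],
    "loopI": "A" * 21,        # Type I terminal hairpin loop
    "ml1": "A" * 3,           # Type II block starts here
    "e11_5": _STEM5["e11"], "loop11": "A" * 5, "e11_3": _revcomp(_STEM5["e11"]),
    "ml2": "A" * 3,
    "e12_5": _STEM5["e12"], "loop12": "A" * 5, "e12_3": _revcomp(_STEM5["e12"]),
    "ml3": "A" * 2,           # Type II block ends here
    "e23b_3": _revcomp(_STEM5["e23b"]), "il1_3": "A" * 2,
    "e23a_3": _revcomp(_STEM5["e23a"]),
    "link3": "A" * 4,
    "s4_5": _STEM5["s4"], "loop4": "A" * 8, "s4_3": _revcomp(_STEM5["s4"]),
    "tail3": "A" * 8,
}

#: alignment column order (both the Type I loop and the Type II block get columns)
SEGMENT_ORDER = tuple(TEMPLATE_SEGMENTS)

_BLOCK_SEGMENTS = ("ml1", "e11_5", "loop11", "e11_3", "ml2",
                   "e12_5", "loop12", "e12_3", "ml3")
_LOOP_I_SEGMENTS = ("loopI",)

_STEM_COUPLES = (("s1_5", "s1_3"), ("s2_5", "s2_3"),
                 ("e23a_5", "e23a_3"), ("e23b_5", "e23b_3"),
                 ("e11_5", "e11_3"), ("e12_5", "e12_3"),
                 ("s4_5", "s4_3"))


def segments_for_type(struct_type: str) -> tuple:
    """Segment names present in a genome of the given type, 5'->3'."""
    if struct_type == TYPE_I:
        absent = set(_BLOCK_SEGMENTS)
    elif struct_type == TYPE_II:
        absent = set(_LOOP_I_SEGMENTS)
    else:
        raise ValueError(f"unknown type {struct_type!r}")
    return tuple(n for n in SEGMENT_ORDER if n not in absent)


def template_v4(struct_type: str) -> str:
    return "".join(TEMPLATE_SEGMENTS[n] for n in segments_for_type(struct_type))


def template_structure(struct_type: str) -> SecondaryStructure:
    """The designed pair set of a template V4 (ground-truth structure)."""
    present = segments_for_type(struct_type)
    offsets, pos = {}, 0
    for name in present:
        offsets[name] = pos
        pos += len(TEMPLATE_SEGMENTS[name])
    pairs = set()
    for five, three in _STEM_COUPLES:
        if five not in offsets:
            continue
        L = len(TEMPLATE_SEGMENTS[five])
        for k in range(L):
            pairs.add((offsets[five] + k, offsets[three] + L - 1 - k))
    return SecondaryStructure(seq_id=f"template-{struct_type}", length=pos,
                              pairs=frozenset(pairs), provenance="template")


# conserved flanks: fixed pseudo-random literals, long enough to embed the
# V4 at real SSU scale (~1.8 kb total)
_flank_rng = np.random.default_rng(932024)
FLANK_LEFT = "".join(_flank_rng.choice(list(_BASES), size=800))
FLANK_RIGHT = "".join(_flank_rng.choice(list(_BASES), size=800))
ANCHOR_LENGTH = 20


def default_anchor_profile(max_mismatch_fraction: float = 0.2) -> AnchorProfile:
    """Anchors flanking the synthetic V4 (20 nt each side)."""
    return AnchorProfile(left_anchor=FLANK_LEFT[-ANCHOR_LENGTH:],
                         right_anchor=FLANK_RIGHT[:ANCHOR_LENGTH],
                         max_mismatch_fraction=max_mismatch_fraction)


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation run.

    Rates are per site per unit branch length except
    ``helix_block_indel_rate``, which is a per-branch event probability.
    ``stem_substitution_rate`` defaults to ``substitution_rate``; set it to
    0 to plant CBC events on an otherwise noiseless stem background.
    """

    n_taxa: int = 12
    birth_rate: float = 1.0
    substitution_rate: float = 0.03
    stem_substitution_rate: float | None = None
    compensatory_fraction: float = 0.9
    cbc_plant: tuple = ()            # ((tip_label, count), ...)
    helix_block_indel_rate: float = 0.05
    plant_toggles: tuple = ()        # (frozenset of tip labels per forced edge, ...)
    flank_length: int = 80
    flank_mutation_rate: float = 0.01
    root_type: str = TYPE_I
    seed: int = 0
    tree: str | None = None          # optional fixed Newick (overrides Yule)

    def __post_init__(self):
        for name in ("substitution_rate", "compensatory_fraction",
                     "helix_block_indel_rate", "flank_mutation_rate",
                     "birth_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.flank_length <= len(FLANK_LEFT):
            raise ValueError(f"flank_length must be in (0, {len(FLANK_LEFT)}]")
        if self.root_type not in (TYPE_I, TYPE_II):
            raise ValueError("root_type must be TYPE_I or TYPE_II")

    @property
    def stem_rate(self) -> float:
        return (self.substitution_rate if self.stem_substitution_rate is None
                else self.stem_substitution_rate)


@dataclass(frozen=True)
class Event:
    """One atomic heritable change on a branch."""

    kind: str        # sub | comp_sub | planted_cbc | block_insert | block_delete
    segment: str | None = None
    pos: int | None = None
    frm: str | None = None
    to: str | None = None


@dataclass
class SimTruth:
    """Ground truth: everything needed to score recovery."""

    config: SimConfig
    tree: dendropy.Tree
    node_types: dict                 # node label -> TYPE_I/TYPE_II
    events: dict                     # child node label -> ordered list of Event
    v4_coords: dict                  # tip label -> (start, end) on the full sequence
    pair_columns: PairColumns        # designed pairs on V4 alignment columns
    v4_column_interval: tuple        # [start, end) of V4 columns in the full alignment

    def replay_tip(self, tip_label: str) -> str:
        """Rebuild a tip's full-length sequence by replaying its event log."""
        node = None
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == tip_label:
                node = leaf
        if node is None:
            raise ValueError(f"tip {tip_label!r} not in tree")
        path = []
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        state = _root_state(self.config)
        for child in reversed(path):
            for ev in self.events[_node_label(child)]:
                _apply_event(state, ev)
        return _full_sequence(state)


@dataclass
class SimResult:
    sequences: list                  # full-length RnaSequence per tip
    alignment: Alignment             # V4-only alignment
    tree: dendropy.Tree
    truth: SimTruth


# ---------------------------------------------------------------------------
# Lineage state
# ---------------------------------------------------------------------------

def _root_state(config: SimConfig) -> dict:
    segs = {n: list(TEMPLATE_SEGMENTS[n])
            for n in segments_for_type(config.root_type)}
    return {"type": config.root_type, "segs": segs,
            "flank_l": list(FLANK_LEFT[-config.flank_length:]),
            "flank_r": list(FLANK_RIGHT[:config.flank_length])}


def _copy_state(state: dict) -> dict:
    return {"type": state["type"],
            "segs": {n: list(s) for n, s in state["segs"].items()},
            "flank_l": list(state["flank_l"]),
            "flank_r": list(state["flank_r"])}


def _v4_sequence(state: dict) -> str:
    return "".join("".join(state["segs"][n])
                   for n in segments_for_type(state["type"]))


def _full_sequence(state: dict) -> str:
    return ("".join(state["flank_l"]) + _v4_sequence(state)
            + "".join(state["flank_r"]))


def _stem_pair_sites(state: dict) -> list:
    """[(seg5, k, seg3, l), ...] for every designed pair in present stems."""
    sites = []
    for five, three in _STEM_COUPLES:
        if five not in state["segs"]:
            continue
        L = len(TEMPLATE_SEGMENTS[five])
        for k in range(L):
            sites.append((five, k, three, L - 1 - k))
    return sites


def _unpaired_segments(state: dict) -> list:
    stem_names = {n for c in _STEM_COUPLES for n in c}
    return [n for n in segments_for_type(state["type"]) if n not in stem_names]


def _apply_event(state: dict, ev: Event) -> None:
    if ev.kind == "block_insert":
        for n in _LOOP_I_SEGMENTS:
            state["segs"].pop(n, None)
        for n in _BLOCK_SEGMENTS:
            state["segs"][n] = list(TEMPLATE_SEGMENTS[n])
        state["type"] = TYPE_II
    elif ev.kind == "block_delete":
        for n in _BLOCK_SEGMENTS:
            state["segs"].pop(n, None)
        for n in _LOOP_I_SEGMENTS:
            state["segs"][n] = list(TEMPLATE_SEGMENTS[n])
        state["type"] = TYPE_I
    else:
        target = (state["segs"][ev.segment] if ev.segment in state["segs"]
                  else state[ev.segment])
        if target[ev.pos] != ev.frm:
            raise ValueError(
                f"event log inconsistent at {ev.segment}[{ev.pos}]: "
                f"expected {ev.frm}, found {target[ev.pos]}")
        target[ev.pos] = ev.to


# ---------------------------------------------------------------------------
# Branch evolution
# ---------------------------------------------------------------------------

def _mutate_site(target: list, segment: str, pos: int,
                 rng: np.random.Generator, events: list, kind: str = "sub") -> None:
    old = target[pos]
    choices = [b for b in _BASES if b != old]
    new = choices[int(rng.integers(len(choices)))]
    target[pos] = new
    events.append(Event(kind=kind, segment=segment, pos=pos, frm=old, to=new))


def _evolve_branch(state: dict, edge_len: float, config: SimConfig,
                   rng: np.random.Generator, forced_toggle: bool,
                   n_planted_cbc: int) -> list:
    """Mutate *state* in place along one branch; returns the event list."""
    events: list[Event] = []

    toggle = forced_toggle or (config.helix_block_indel_rate > 0
                               and rng.random() < config.helix_block_indel_rate)
    if toggle:
        kind = "block_delete" if state["type"] == TYPE_II else "block_insert"
        ev = Event(kind=kind)
        _apply_event(state, ev)
        events.append(ev)

    # conserved flanks
    p_flank = min(1.0, config.flank_mutation_rate * edge_len)
    for name in ("flank_l", "flank_r"):
        if p_flank <= 0:
            continue
        hits = np.nonzero(rng.random(len(state[name])) < p_flank)[0]
        for pos in hits:
            _mutate_site(state[name], name, int(pos), rng, events)

    # unpaired V4 sites
    p_loop = min(1.0, config.substitution_rate * edge_len)
    if p_loop > 0:
        for seg in _unpaired_segments(state):
            hits = np.nonzero(rng.random(len(state["segs"][seg])) < p_loop)[0]
            for pos in hits:
                _mutate_site(state["segs"][seg], seg, int(pos), rng, events)

    # stem sites: at most one event per designed pair per branch
    p_stem = min(1.0, config.stem_rate * edge_len)
    pair_sites = _stem_pair_sites(state)
    if p_stem > 0:
        p_pair = 1.0 - (1.0 - p_stem) ** 2
        for five, k, three, l in pair_sites:
            if rng.random() >= p_pair:
                continue
            if rng.random() < config.compensatory_fraction:
                _compensatory_switch(state, five, k, three, l, rng, events,
                                     kind="comp_sub")
            else:
                seg, pos = (five, k) if rng.random() < 0.5 else (three, l)
                _mutate_site(state["segs"][seg], seg, pos, rng, events)

    # forced compensatory double substitutions (orientation swaps keep the
    # stem alphabet unchanged, so folding is unaffected)
    if n_planted_cbc > 0:
        if n_planted_cbc > len(pair_sites):
            raise ValueError("more planted CBCs than stem pairs")
        idx = rng.choice(len(pair_sites), size=n_planted_cbc, replace=False)
        for i in sorted(int(x) for x in idx):
            five, k, three, l = pair_sites[i]
            a = state["segs"][five][k]
            b = state["segs"][three][l]
            _planted_swap(state, five, k, three, l, a, b, events)
    return events


def _compensatory_switch(state, five, k, three, l, rng, events, kind):
    a = state["segs"][five][k]
    b = state["segs"][three][l]
    options = [d for d in _CANONICAL_DUOS if d != (a, b)]
    na, nb = options[int(rng.integers(len(options)))]
    state["segs"][five][k] = na
    state["segs"][three][l] = nb
    events.append(Event(kind=kind, segment=five, pos=k, frm=a, to=na))
    events.append(Event(kind=kind, segment=three, pos=l, frm=b, to=nb))


def _planted_swap(state, five, k, three, l, a, b, events):
    if a == b:  # cannot swap identical residues into a double change
        raise ValueError("planted CBC site is not a canonical pair")
    state["segs"][five][k] = b
    state["segs"][three][l] = a
    events.append(Event(kind="planted_cbc", segment=five, pos=k, frm=a, to=b))
    events.append(Event(kind="planted_cbc", segment=three, pos=l, frm=b, to=a))


# ---------------------------------------------------------------------------
# Tree generation and the simulator
# ---------------------------------------------------------------------------

def _node_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def random_yule_tree(n_taxa: int, seed: int, birth_rate: float = 1.0
                     ) -> dendropy.Tree:
    """A clocklike pure-birth tree with tips labelled t1..tn."""
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_taxa,
        rng=random.Random(int(seed)))
    tree.is_rooted = True
    for idx, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{idx}"
    return tree


def _prepare_tree(config: SimConfig) -> dendropy.Tree:
    if config.tree is not None:
        tree = read_newick_string(config.tree)
    else:
        tree = random_yule_tree(config.n_taxa, config.seed, config.birth_rate)
    counter = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None and not node.label:
            node.label = f"N{counter}"
            counter += 1
    return tree


def _alignment_row(state: dict) -> str:
    present = set(segments_for_type(state["type"]))
    out = []
    for name in SEGMENT_ORDER:
        if name in present:
            out.append("".join(state["segs"][name]))
        else:
            out.append("-" * len(TEMPLATE_SEGMENTS[name]))
    return "".join(out)


def designed_pair_columns() -> PairColumns:
    """Designed stem pairs on V4 alignment columns (all couples, both types)."""
    offsets, pos = {}, 0
    for name in SEGMENT_ORDER:
        offsets[name] = pos
        pos += len(TEMPLATE_SEGMENTS[name])
    pairs = []
    for five, three in _STEM_COUPLES:
        L = len(TEMPLATE_SEGMENTS[five])
        for k in range(L):
            pairs.append((offsets[five] + k, offsets[three] + L - 1 - k))
    return PairColumns(pairs=tuple(pairs))


def simulate(config: SimConfig) -> SimResult:
    """Evolve the template down a tree; returns sequences, alignment, tree
    and the full ground truth.

    Same config (including seed) gives byte-identical output.  Forced
    toggles are addressed by the tip set of the edge's child clade; planted
    CBCs apply to terminal branches.  Contradictory plants (unknown tip,
    clade not on the tree) are errors.
    """
    rng = np.random.default_rng(config.seed)
    tree = _prepare_tree(config)
    tip_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]

    cbc_plant = dict()
    for tip, count in config.cbc_plant:
        if tip not in tip_labels:
            raise ValueError(f"cbc_plant lineage {tip!r} not a tip of the tree")
        cbc_plant[tip] = cbc_plant.get(tip, 0) + int(count)

    toggle_nodes = set()
    for tipset in config.plant_toggles:
        want = frozenset(tipset)
        hit = None
        for node in tree.preorder_node_iter():
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            if leaves == want:
                hit = node
                break
        if hit is None or hit.parent_node is None:
            raise ValueError(f"no edge subtends exactly {sorted(want)}")
        toggle_nodes.add(id(hit))

    states = {id(tree.seed_node): _root_state(config)}
    node_types = {_node_label(tree.seed_node): config.root_type}
    events: dict[str, list] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        state = _copy_state(states[id(node.parent_node)])
        label = _node_label(node)
        edge_len = node.edge.length or 0.0
        n_cbc = cbc_plant.get(label, 0) if node.is_leaf() else 0
        events[label] = _evolve_branch(state, edge_len, config, rng,
                                       forced_toggle=id(node) in toggle_nodes,
                                       n_planted_cbc=n_cbc)
        states[id(node)] = state
        node_types[label] = state["type"]

    sequences, rows, v4_coords = [], [], {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        state = states[id(leaf)]
        full = _full_sequence(state)
        sequences.append(RnaSequence(id=label, residues=full, source="synthetic"))
        rows.append((label, _alignment_row(state)))
        start = len(state["flank_l"])
        v4_coords[label] = (start, start + len(_v4_sequence(state)))

    # drop columns gapped in every row (uniform-type cohorts are gap-free)
    all_gap = [all(row[k] == "-" for _, row in rows)
               for k in range(len(rows[0][1]))]
    pair_cols = designed_pair_columns()
    if any(all_gap):
        keep = [k for k, gapped in enumerate(all_gap) if not gapped]
        remap = {old: new for new, old in enumerate(keep)}
        rows = [(rid, "".join(row[k] for k in keep)) for rid, row in rows]
        pair_cols = PairColumns(pairs=tuple(
            (remap[k], remap[l]) for k, l in pair_cols.pairs
            if k in remap and l in remap))

    alignment = Alignment(rows=rows)
    truth = SimTruth(config=config, tree=tree, node_types=node_types,
                     events=events, v4_coords=v4_coords,
                     pair_columns=pair_cols,
                     v4_column_interval=(config.flank_length,
                                         config.flank_length + alignment.length))
    return SimResult(sequences=sequences, alignment=alignment, tree=tree,
                     truth=truth)


def full_alignment(result: SimResult) -> Alignment:
    """Flanks + V4 columns, for deriving anchor profiles from a reference."""
    rows = []
    v4_rows = dict(result.alignment.rows)
    flanks = {}
    for seq in result.sequences:
        start, end = result.truth.v4_coords[seq.id]
        flanks[seq.id] = (seq.residues[:start], seq.residues[end:])
    for seq in result.sequences:
        left, right = flanks[seq.id]
        rows.append((seq.id, left + v4_rows[seq.id] + right))
    return Alignment(rows=rows)


# ---------------------------------------------------------------------------
# Canned scenarios
# ---------------------------------------------------------------------------

FIXTURE_NEWICK = (
    "(((t1:0.05,t2:0.05):0.05,(t3:0.05,t4:0.05):0.05):0.05,"
    "((t5:0.05,(t6:0.05,t7:0.05):0.05):0.05,"
    "((t8:0.05,(t9:0.05,t10:0.05):0.05):0.05,"
    "(t11:0.05,t12:0.05):0.05):0.05):0.05);"
)

#: planted history of the 12-taxon fixture: one Type I -> Type II gain and
#: two reversals back to Type I
FIXTURE_GAIN_CLADE = frozenset({"t5", "t6", "t7", "t8", "t9", "t10", "t11", "t12"})
FIXTURE_REVERSAL_CLADES = (frozenset({"t7"}), frozenset({"t11", "t12"}))
FIXTURE_CBC_TIP = "t9"

FIXTURE_CONFIG = SimConfig(
    n_taxa=12,
    substitution_rate=0.0,
    stem_substitution_rate=0.0,
    compensatory_fraction=1.0,
    helix_block_indel_rate=0.0,
    plant_toggles=(FIXTURE_GAIN_CLADE,) + FIXTURE_REVERSAL_CLADES,
    cbc_plant=((FIXTURE_CBC_TIP, 1),),
    flank_length=80,
    flank_mutation_rate=0.05,
    root_type=TYPE_I,
    seed=424242,
    tree=FIXTURE_NEWICK,
)

#: expected tip types implied by the fixture's planted history
FIXTURE_TIP_TYPES = {
    **{t: TYPE_I for t in ("t1", "t2", "t3", "t4", "t7", "t11", "t12")},
    **{t: TYPE_II for t in ("t5", "t6", "t8", "t9", "t10")},
}


def fixture_suite() -> SimResult:
    """The 12-taxon mini-*Euplotes* fixture: 2 planted reversals, 1 planted
    CBC (on t9, mirroring *E. minuta* in its clade), no stem noise."""
    return simulate(FIXTURE_CONFIG)


def single_reversal_scenario(seed: int, n_taxa: int = 16,
                             noise: float = 0.003) -> tuple:
    """Random Yule tree with a planted gain and one later reversal.

    *noise* is the per-branch probability of additional stray block
    toggles.  The default keeps the expected number of stray character
    events per replicate around 0.1 — an order of magnitude below the
    planted signal, which is the regime in which recovering a specific
    planted edge is well-posed at all (stray events on the relevant
    lineages rewrite the very history being recovered).
    Returns ``(SimResult, reversal_tipset)``, where
    the tip set identifies the planted reversal edge.  The reversal edge is
    placed at least two edges below the gain edge so that the surviving
    Type II tips form two or more clades — otherwise a single independent
    gain would be more parsimonious and the planted reversal would be
    unidentifiable in principle.  Trees without a suitable nested pair of
    internal edges are resampled deterministically.
    """
    for attempt in range(100):
        tree_seed = seed + 1_000_003 * attempt
        tree = random_yule_tree(n_taxa, tree_seed)
        gain_node = None
        rev_node = None
        internals = [n for n in tree.preorder_node_iter()
                     if not n.is_leaf() and n.parent_node is not None]
        for node in internals:
            clade = [l.taxon.label for l in node.leaf_iter()]
            if len(clade) < 4:
                continue
            for sub in node.preorder_iter():
                if sub is node or sub.is_leaf() or sub.parent_node is node:
                    continue
                subclade = [l.taxon.label for l in sub.leaf_iter()]
                if 2 <= len(subclade) <= len(clade) - 2:
                    gain_node, rev_node = node, sub
                    break
            if gain_node is not None:
                break
        if gain_node is None:
            continue
        gain_set = frozenset(l.taxon.label for l in gain_node.leaf_iter())
        rev_set = frozenset(l.taxon.label for l in rev_node.leaf_iter())
        config = SimConfig(
            n_taxa=n_taxa,
            substitution_rate=0.0,
            stem_substitution_rate=0.0,
            helix_block_indel_rate=noise,
            plant_toggles=(gain_set, rev_set),
            flank_mutation_rate=0.0,
            root_type=TYPE_I,
            seed=seed,
            tree=tree.as_string(schema="newick").strip(),
        )
        return simulate(config), rev_set
    raise RuntimeError("could not find a plantable tree")


def flank_mutation_replicate(seed: int, struct_type: str = TYPE_I,
                             flank_mutation: float = 0.05,
                             flank_length: int = 800) -> tuple:
    """One full-length sequence with independently mutated flanks.

    Returns ``(RnaSequence, (start, end))`` with the true V4 interval;
    used to measure anchor-based extraction accuracy at a given flank
    divergence (default 5% per site).
    """
    rng = np.random.default_rng(seed)
    left = list(FLANK_LEFT[-flank_length:])
    right = list(FLANK_RIGHT[:flank_length])
    for flank in (left, right):
        hits = np.nonzero(rng.random(len(flank)) < flank_mutation)[0]
        for pos in hits:
            old = flank[pos]
            choices = [b for b in _BASES if b != old]
            flank[pos] = choices[int(rng.integers(3))]
    v4 = template_v4(struct_type)
    full = "".join(left) + v4 + "".join(right)
    seq = RnaSequence(id=f"rep{seed}", residues=full, source="synthetic")
    return seq, (flank_length, flank_length + len(v4))
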