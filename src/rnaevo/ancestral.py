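"""Fitch parsimony ancestral-state reconstruction and reversal detection.

The Type I/II structural character is treated as unordered binary with
equal change costs.  The downpass takes intersections where possible and
unions (one step each) otherwise, generalized over polytomies by folding
across children.  Ambiguous nodes are resolved under an explicit rule —
DELTRAN (delay changes toward the tips, the default), ACCTRAN (accelerate
changes toward the root) or prefer-ancestral — implemented by min-cost
(Sankoff) backtracking, so every resolved labelling attains the parsimony
minimum regardless of rule.

A "reversal" (reverse evolution) is a change on an edge whose derived
state equals the resolved root state — for the V4 character with a Type I
root, the Type II -> Type I losses of the E23_11/E23_12 helices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

RULES = ("deltran", "acctran", "prefer-ancestral")


@dataclass
class Reconstruction:
    """Per-node state sets and (after resolution) one state per node."""

    tree: dendropy.Tree
    states: tuple                      # ordered state alphabet
    downpass: dict                     # node label -> frozenset of states
    mpr_sets: dict                     # node label -> states in >=1 MPR
    n_steps: int
    resolved: dict = field(default_factory=dict)   # node label -> state
    changes: list = field(default_factory=list)    # (parent_label, child_label, from, to)
    reversals: list = field(default_factory=list)
    rule: str | None = None

    @property
    def root_state(self):
        return self.resolved.get(_label(self.tree.seed_node))


def _label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def _prepare_tree(tree: dendropy.Tree, matrix: dict) -> dendropy.Tree:
    """Clone, prune stateless tips (logged) and label internal nodes."""
    work = tree.clone(depth=1)
    tips = {leaf.taxon.label for leaf in work.leaf_node_iter()}
    missing_on_tree = set(matrix) - tips
    if missing_on_tree:
        raise ValueError(f"character matrix taxa not on tree: {sorted(missing_on_tree)}")
    stateless = tips - set(matrix)
    if stateless:
        logger.warning("pruning %d tips without a character state: %s",
                       len(stateless), sorted(stateless))
        work.retain_taxa_with_labels(sorted(tips - stateless))
    counter = 0
    for node in work.preorder_node_iter():
        if node.taxon is None and not node.label:
            node.label = f"N{counter}"
            counter += 1
    return work


def fitch(tree: dendropy.Tree, matrix: dict) -> Reconstruction:
    """Fitch downpass plus MPR state sets; n_steps = number of union events.

    *matrix* maps tip label -> state.  Tips missing from the matrix are
    pruned with a warning; matrix taxa absent from the tree are an error.
    """
    work = _prepare_tree(tree, matrix)
    states = tuple(sorted(set(matrix.values())))
    downpass: dict[str, frozenset] = {}
    n_steps = 0
    INF = float("inf")
    below: dict[str, dict] = {}  # node label -> {state: min changes in subtree}

    for node in work.postorder_node_iter():
        lab = _label(node)
        if node.is_leaf():
            s = matrix[node.taxon.label]
            downpass[lab] = frozenset([s])
            below[lab] = {x: (0 if x == s else INF) for x in states}
            continue
        kids = node.child_nodes()
        acc = downpass[_label(kids[0])]
        for kid in kids[1:]:
            nxt = downpass[_label(kid)]
            inter = acc & nxt
            if inter:
                acc = inter
            else:
                acc = acc | nxt
                n_steps += 1
        downpass[lab] = acc
        below[lab] = {
            x: sum(min(below[_label(k)][y] + (x != y) for y in states)
                   for k in kids)
            for x in states
        }

    # min changes outside each node's subtree, conditional on node state
    above: dict[str, dict] = {}
    root = work.seed_node
    above[_label(root)] = {x: 0 for x in states}
    for node in work.preorder_node_iter():
        lab = _label(node)
        for kid in node.child_nodes():
            sib_cost = {
                x: above[lab][x] + sum(
                    min(below[_label(s)][y] + (x != y) for y in states)
                    for s in node.child_nodes() if s is not kid)
                for x in states
            }
            above[_label(kid)] = {
                y: min(sib_cost[x] + (x != y) for x in states) for y in states
            }

    optimum = min(below[_label(root)].values())
    mpr = {
        lab: frozenset(x for x in states
                       if below[lab][x] + above[lab][x] == optimum)
        for lab in below
    }
    assert optimum == n_steps, "Sankoff optimum disagrees with Fitch union count"
    recon = Reconstruction(tree=work, states=states, downpass=downpass,
                           mpr_sets=mpr, n_steps=n_steps)
    recon._below = below  # kept for resolution backtracking
    return recon


def resolve_and_map(recon: Reconstruction, rule: str = "deltran",
                    prefer_state: str | None = None) -> Reconstruction:
    """Resolve ambiguous nodes under *rule* and enumerate state changes.

    Every rule backtracks through the min-cost table, so the resolved
    labelling always attains ``n_steps`` changes.  *prefer_state* breaks
    root ties (and drives ``prefer-ancestral``); default is the first
    state alphabetically (TYPE_I for the V4 character).
    """
    if rule not in RULES:
        raise ValueError(f"unknown resolution rule {rule!r}; choose from {RULES}")
    states = recon.states
    below = recon._below
    prefer = prefer_state if prefer_state is not None else states[0]
    resolved: dict[str, str] = {}
    changes = []

    work = recon.tree
    root = work.seed_node
    root_lab = _label(root)
    root_adm = sorted(x for x in states
                      if below[root_lab][x] == min(below[root_lab].values()))
    resolved[root_lab] = prefer if prefer in root_adm else root_adm[0]

    for node in work.preorder_node_iter():
        lab = _label(node)
        p = resolved[lab]
        for kid in node.child_nodes():
            klab = _label(kid)
            costs = {y: below[klab][y] + (y != p) for y in states}
            adm = sorted(y for y in states if costs[y] == min(costs.values()))
            if rule == "deltran":
                choice = p if p in adm else (prefer if prefer in adm else adm[0])
            elif rule == "acctran":
                changed = [y for y in adm if y != p]
                choice = changed[0] if changed else p
            else:  # prefer-ancestral
                choice = prefer if prefer in adm else (p if p in adm else adm[0])
            resolved[klab] = choice
            if choice != p:
                changes.append((lab, klab, p, choice))

    root_state = resolved[root_lab]
    reversals = [c for c in changes if c[3] == root_state]
    out = Reconstruction(tree=work, states=states, downpass=recon.downpass,
                         mpr_sets=recon.mpr_sets, n_steps=recon.n_steps,
                         resolved=resolved, changes=changes,
                         reversals=reversals, rule=rule)
    out._below = below
    assert len(changes) == recon.n_steps, \
        "resolved labelling does not attain the parsimony minimum"
    return out


def reversal_report(recon: Reconstruction) -> pd.DataFrame:
    """One row per reversal edge with the tip set it subtends."""
    if not recon.resolved:
        raise ValueError("call resolve_and_map before reversal_report")
    nodes = {_label(n): n for n in recon.tree.preorder_node_iter()}
    rows = []
    for parent, child, frm, to in recon.reversals:
        tips = sorted(leaf.taxon.label
                      for leaf in nodes[child].leaf_iter())
        rows.append({"parent": parent, "child": child,
                     "from_state": frm, "to_state": to,
                     "n_tips": len(tips), "tips": ",".join(tips)})
    return pd.DataFrame(rows, columns=["parent", "child", "from_state",
                                       "to_state", "n_tips", "tips"])


def changes_table(recon: Reconstruction) -> pd.DataFrame:
    rows = [{"parent": p, "child": c, "from_state": f, "to_state": t,
             "is_reversal": (p, c, f, t) in set(recon.reversals)}
            for p, c, f, t in recon.changes]
    return pd.DataFrame(rows, columns=["parent", "child", "from_state",
                                       "to_state", "is_reversal"])
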