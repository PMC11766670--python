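"""Independent oracles for the test suite.

Each function here re-derives an expected result from first principles —
exhaustive enumeration or an explicit restatement of a definition — and is
deliberately written without reference to the package's implementation
paths, so agreement between the two is evidence, not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np

# pairing rules restated independently: Watson-Crick plus G:U wobble
_PAIRING = {"GC", "CG", "AU", "UA", "GU", "UG"}
_SCORES = {"GC": 3, "CG": 3, "AU": 2, "UA": 2, "GU": 1, "UG": 1}


def enumerate_nested_structures(seq: str, min_hairpin: int = 3):
    """Yield every properly nested set of scoreable pairs of *seq*.

    Only pairs with positive score are enumerated; structures containing
    zero-score pairs cannot exceed the optimum, so the maximum over this
    family equals the maximum over all nested pair sets.
    """
    n = len(seq)

    def gen(i, j):
        if i > j:
            yield []
            return
        yield from gen(i + 1, j)
        for k in range(i + min_hairpin + 1, j + 1):
            if seq[i] + seq[k] not in _PAIRING:
                continue
            for inner in gen(i + 1, k - 1):
                for outer in gen(k + 1, j):
                    yield [(i, k)] + inner + outer

    yield from gen(0, n - 1)


def bruteforce_fold_optimum(seq: str, min_hairpin: int = 3) -> float:
    """Maximum total pair score over all nested structures, by enumeration."""
    best = 0.0
    for pairs in enumerate_nested_structures(seq, min_hairpin):
        score = sum(_SCORES[seq[i] + seq[j]] for i, j in pairs)
        best = max(best, score)
    return best


def cbc_verdict_oracle(a1: str, a2: str, b1: str, b2: str) -> str:
    """Restatement of the CBC verdict definition as a flat decision chain."""
    residues = (a1, a2, b1, b2)
    if "-" in residues or "N" in residues:
        return "skipped-gap"
    a_pairs = (a1 + a2) in _PAIRING
    b_pairs = (b1 + b2) in _PAIRING
    if not a_pairs or not b_pairs:
        return "skipped-nonpairing"
    left_differs = a1 != b1
    right_differs = a2 != b2
    if left_differs and right_differs:
        return "CBC"
    if left_differs or right_differs:
        return "hCBC"
    return "same"


def bruteforce_parsimony_steps(tree, tip_states: dict, states: tuple) -> int:
    """Minimum edge changes over all full labelings, by exhaustive search."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            edges.append((node.parent_node, node))
    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        for leaf in tree.leaf_node_iter():
            assign[id(leaf)] = tip_states[leaf.taxon.label]
        cost = sum(assign[id(p)] != assign[id(c)] for p, c in edges)
        if best is None or cost < best:
            best = cost
    return best


def random_rna(rng: np.random.Generator, length: int, alphabet: str = "ACGU") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def random_nested_structure(rng: np.random.Generator, n: int,
                            min_hairpin: int = 3, attempts: int = 60) -> set:
    """A random properly nested pair set by rejection sampling."""
    pairs: set[tuple[int, int]] = set()
    taken = set()

    def crosses(i, j):
        for a, b in pairs:
            if (a < i < b < j) or (i < a < j < b):
                return True
        return False

    for _ in range(attempts):
        i, j = sorted(rng.integers(0, n, size=2).tolist())
        if j - i <= min_hairpin or i in taken or j in taken or crosses(i, j):
            continue
        pairs.add((i, j))
        taken.update((i, j))
    return pairs
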