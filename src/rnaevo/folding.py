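"""Secondary-structure prediction by base-pair score maximization.

Per-sequence folding is a Nussinov-style dynamic program maximizing a
total pair score (GC=3, AU=2, GU=1 by default) over all pseudoknot-free
structures with a minimum hairpin size.  Consensus folding runs the same
DP on alignment columns, where a column pair's score sums per-row pair
scores, adds a covariance bonus for every distinct pair type beyond the
first (compensatory substitutions are positive evidence for pairing) and
subtracts a penalty for rows that cannot pair at those columns.

This pair-score model deliberately stands in for a full nearest-neighbor
thermodynamic model: helix topology, compensatory changes and ancestral
states — the quantities this package computes — depend on which positions
pair, not on the free-energy values themselves.  An external thermodynamic
folder can be used as a non-gating cross-check (see
:func:`crosscheck_external`).

All folding is deterministic: the traceback prefers leaving the 5' residue
unpaired over pairing it and, among pairing branches, the smallest 3'
partner, so identical inputs give byte-identical dot-brackets.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import Alignment, RnaSequence
from .structure import (
    CANONICAL_PAIRS,
    VALID_PAIRS,
    SecondaryStructure,
    is_canonical_or_wobble,
)

DEFAULT_PAIR_SCORES = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "U"): 2.0, ("U", "A"): 2.0,
    ("G", "U"): 1.0, ("U", "G"): 1.0,
}


@dataclass(frozen=True)
class FoldParams:
    """Scoring parameters for per-sequence and consensus folding.

    pair_scores are dimensionless stacking-free pair weights; min_hairpin is
    the minimum number of unpaired residues enclosed by any pair (steric
    minimum 3); covariance_bonus and inconsistency_penalty apply to consensus
    folding only.
    """

    pair_scores: dict = field(default_factory=lambda: dict(DEFAULT_PAIR_SCORES))
    min_hairpin: int = 3
    covariance_bonus: float = 1.0
    inconsistency_penalty: float = 0.5

    def __post_init__(self):
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        for (a, b), s in self.pair_scores.items():
            if self.pair_scores.get((b, a)) != s:
                raise ValueError(f"pair_scores not symmetric at ({a},{b})")

    def score_matrix(self, residues: str) -> np.ndarray:
        """n x n matrix of pair scores; 0 forbids pairing (N never pairs)."""
        n = len(residues)
        mat = np.zeros((n, n))
        for (a, b), s in self.pair_scores.items():
            ai = np.frombuffer(residues.encode(), dtype=np.uint8) == ord(a)
            bi = np.frombuffer(residues.encode(), dtype=np.uint8) == ord(b)
            mat[np.ix_(ai, bi)] = s
        return mat


def _nussinov(score: np.ndarray, min_hairpin: int) -> tuple:
    """Maximum-score nested pairing for an arbitrary (column-)pair score matrix.

    ``score[i, k] <= 0`` forbids the pair (i, k).  Returns (pairs, optimum).
    """
    n = score.shape[0]
    if n == 0:
        return frozenset(), 0.0
    # M[i, j] = optimum over inclusive span i..j; padded so out-of-range
    # lookups (empty spans) read 0.
    M = np.zeros((n + 2, n + 2))
    for span in range(min_hairpin + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]
            ks = np.arange(i + min_hairpin + 1, j + 1)
            srow = score[i, ks]
            mask = srow > 0
            if mask.any():
                ks = ks[mask]
                cand = srow[mask] + M[i + 1, ks - 1] + M[ks + 1, j]
                best = max(best, cand.max())
            M[i, j] = best

    # deterministic traceback: prefer i-unpaired, then smallest k
    pairs = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_hairpin + 1:
            continue
        target = M[i, j]
        if target == M[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_hairpin + 1, j + 1):
            if score[i, k] > 0 and math.isclose(
                score[i, k] + M[i + 1, k - 1] + M[k + 1, j], target
            ):
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
    return frozenset(pairs), float(M[0, n - 1])


def fold_mfe(seq: RnaSequence, params: FoldParams | None = None) -> SecondaryStructure:
    """Fold one sequence to its maximum-score structure.

    Sequences too short to form any pair return the empty structure with
    score 0 (not an error).
    """
    params = params or FoldParams()
    n = len(seq.residues)
    if n < params.min_hairpin + 2:
        return SecondaryStructure(seq_id=seq.id, length=n, provenance="mfe")
    pairs, score = _nussinov(params.score_matrix(seq.residues), params.min_hairpin)
    return SecondaryStructure(seq_id=seq.id, length=n, pairs=pairs,
                              score=score, provenance="mfe")


def consensus_column_scores(alignment: Alignment, params: FoldParams) -> np.ndarray:
    """Column-pair score matrix for consensus folding.

    score(k, l) = sum of per-row pair scores
                + covariance_bonus * (distinct valid pair types - 1)
                - inconsistency_penalty * (rows unable to pair; gaps count)
    Non-positive entries forbid the column pair.
    """
    L = alignment.length
    cols = [alignment.column(k) for k in range(L)]
    mat = np.zeros((L, L))
    for k in range(L):
        for l in range(k + 1, L):
            total = 0.0
            types = set()
            bad = 0
            for a, b in zip(cols[k], cols[l]):
                s = params.pair_scores.get((a, b), 0.0)
                if s > 0:
                    total += s
                    types.add((a, b))
                else:
                    bad += 1
            if types:
                total += params.covariance_bonus * (len(types) - 1)
            total -= params.inconsistency_penalty * bad
            if total > 0:
                mat[k, l] = total
    return mat


def fold_consensus(alignment: Alignment, params: FoldParams | None = None) -> tuple:
    """Consensus-fold an alignment.

    Returns ``(structure, stats)`` where *structure* lives on alignment
    columns (provenance ``consensus``) and *stats* is a DataFrame with one
    row per consensus pair: columns ``col5, col3, score, n_pair_types,
    n_inconsistent_rows``.
    """
    params = params or FoldParams()
    if alignment.n_rows == 0:
        raise ValueError("empty alignment")
    score = consensus_column_scores(alignment, params)
    pairs, total = _nussinov(score, params.min_hairpin)
    struct = SecondaryStructure(seq_id="consensus", length=alignment.length,
                                pairs=pairs, score=total, provenance="consensus")
    records = []
    for k, l in struct.sorted_pairs():
        duos = [(a, b) for a, b in zip(alignment.column(k), alignment.column(l))]
        types = {d for d in duos if params.pair_scores.get(d, 0.0) > 0}
        bad = sum(1 for d in duos if params.pair_scores.get(d, 0.0) <= 0)
        records.append({"col5": k, "col3": l, "score": score[k, l],
                        "n_pair_types": len(types), "n_inconsistent_rows": bad})
    stats = pd.DataFrame(records,
                         columns=["col5", "col3", "score", "n_pair_types",
                                  "n_inconsistent_rows"])
    return struct, stats


def project_consensus(consensus: SecondaryStructure, alignment: Alignment,
                      rid: str) -> SecondaryStructure:
    """Map a column-level consensus structure onto one ungapped row.

    Column pairs touching a gap in the row, or whose residues cannot form a
    canonical/wobble pair, are dropped; the result is a valid per-sequence
    structure (projection cannot introduce crossing pairs).
    """
    row = alignment.row(rid)
    if consensus.length != len(row):
        raise ValueError("consensus structure length != alignment length")
    col_to_pos = {}
    pos = 0
    for k, ch in enumerate(row):
        if ch != "-":
            col_to_pos[k] = pos
            pos += 1
    pairs = set()
    for k, l in consensus.pairs:
        if k not in col_to_pos or l not in col_to_pos:
            continue
        if not is_canonical_or_wobble(row[k], row[l]):
            continue
        pairs.add((col_to_pos[k], col_to_pos[l]))
    return SecondaryStructure(seq_id=rid, length=pos, pairs=frozenset(pairs),
                              provenance="consensus-projected")


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def _close_gc_loops_once(structure: SecondaryStructure, residues: str) -> frozenset:
    """Close every 1x1 internal loop whose unpaired residues are G and C."""
    pairs = set(structure.pairs)
    paired = {i for p in pairs for i in p}
    added = set()
    for i, j in pairs:
        if (i + 2, j - 2) in pairs and i + 1 not in paired and j - 1 not in paired:
            duo = {residues[i + 1], residues[j - 1]}
            if duo == {"G", "C"}:
                added.add((i + 1, j - 1))
    return frozenset(pairs | added)


def _drop_noncanonical_helices(structure: SecondaryStructure,
                               residues: str) -> frozenset:
    """Remove any helix containing >= 2 non-canonical, non-wobble pairs."""
    from .topology import find_helices  # local import: topology builds on structure only

    keep = set(structure.pairs)
    for helix in find_helices(structure):
        bad = sum(1 for i, j in helix.pairs
                  if (residues[i], residues[j]) not in VALID_PAIRS)
        if bad >= 2:
            keep -= set(helix.pairs)
    return frozenset(keep)


def curate(structure: SecondaryStructure, seq: RnaSequence,
           reference: SecondaryStructure | None = None) -> SecondaryStructure:
    """Apply the structure-curation rules; total and idempotent.

    Rule 1: a 1x1 internal loop whose two unpaired residues are G and C
    (either orientation) is closed into a pair, extending the helix.
    Rule 2: a helix containing two or more non-canonical (non-GC/AU/GU)
    pairs is removed entirely.  Rules iterate to a fixed point.  Candidate
    selection against *reference* (rule 3) is :func:`select_structure`.
    """
    if structure.length != len(seq.residues):
        raise ValueError("structure and sequence lengths differ")
    residues = seq.residues
    pairs = structure.pairs
    for _ in range(structure.length + 1):
        cur = structure.with_pairs(pairs)
        p1 = _close_gc_loops_once(cur, residues)
        p2 = _drop_noncanonical_helices(structure.with_pairs(p1), residues)
        if p2 == pairs:
            break
        pairs = p2
    return structure.with_pairs(pairs, provenance="curated")


def basepair_f1(a: SecondaryStructure, b: SecondaryStructure) -> float:
    """Base-pair F1 between two structures (1.0 when both are empty)."""
    if not a.pairs and not b.pairs:
        return 1.0
    shared = len(a.pairs & b.pairs)
    return 2.0 * shared / (len(a.pairs) + len(b.pairs))


def select_structure(candidates: list, reference: SecondaryStructure | None
                     ) -> SecondaryStructure:
    """Pick the best candidate: highest score, then best base-pair F1
    against *reference*, then lexicographically smallest dot-bracket.

    The order is total and deterministic, operationalizing "minimum free
    energy or best compatibility with similar sequences".
    """
    if not candidates:
        raise ValueError("no candidate structures")

    def key(s: SecondaryStructure):
        f1 = basepair_f1(s, reference) if reference is not None else 0.0
        return (-s.score, -f1, s.dot_bracket())

    return sorted(candidates, key=key)[0]


# ---------------------------------------------------------------------------
# Optional external cross-check (non-gating)
# ---------------------------------------------------------------------------

def crosscheck_external(seq: RnaSequence, structure: SecondaryStructure) -> float | None:
    """Base-pair F1 between *structure* and RNAfold's thermodynamic MFE
    prediction, or None when RNAfold is unavailable.

    Reported, never asserted: the pair-score model is expected to agree on
    helix placement, not on every pair.
    """
    exe = shutil.which("RNAfold")
    if exe is None:
        return None
    try:
        proc = subprocess.run(
            [exe, "--noPS"], input=f">{seq.id}\n{seq.residues}\n",
            capture_output=True, text=True, timeout=120, check=True,
        )
    except (subprocess.SubprocessError, OSError):
        return None
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    if len(lines) < 3:
        return None
    db = lines[2].split()[0]
    from .structure import parse_dotbracket_string

    ext = parse_dotbracket_string(db, seq_id=seq.id, provenance="external")
    return basepair_f1(structure, ext)
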