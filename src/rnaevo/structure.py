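"""Core secondary-structure container and dot-bracket notation.

A secondary structure is a pseudoknot-free (properly nested) set of base
pairs ``(i, j)`` with ``0 <= i < j < length``, each index in at most one
pair.  Dot-bracket strings use ``(``/``)`` for the 5' and 3' partners of a
pair and ``.`` for unpaired residues; pseudoknot bracket layers are not
supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

CANONICAL_PAIRS = frozenset({("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")})
WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})
VALID_PAIRS = CANONICAL_PAIRS | WOBBLE_PAIRS


def is_canonical_or_wobble(a: str, b: str) -> bool:
    """True when residues *a* and *b* form a Watson-Crick or G:U wobble pair."""
    return (a, b) in VALID_PAIRS


class StructureError(ValueError):
    """Raised for malformed structures or dot-bracket strings."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested base-pair set over a sequence of known length.

    Parameters
    ----------
    seq_id : str
        Identifier of the sequence the structure belongs to.
    length : int
        Number of residues the structure spans.
    pairs : frozenset of (int, int)
        0-based pairs with i < j, properly nested, each index used once.
    score : float
        Folding score (0 for structures not produced by the folder).
    provenance : str
        One of ``mfe``, ``consensus``, ``consensus-projected``, ``curated``,
        ``parsed`` or any free-form tag describing where the pairs came from.
    """

    seq_id: str
    length: int
    pairs: frozenset = field(default_factory=frozenset)
    score: float = 0.0
    provenance: str = "parsed"

    def __post_init__(self):
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        _validate_pairs(self.pairs, self.length)

    # -- queries ---------------------------------------------------------
    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner_map(self) -> dict:
        """Mapping index -> partner index for every paired residue."""
        pm = {}
        for i, j in self.pairs:
            pm[i] = j
            pm[j] = i
        return pm

    def is_paired(self, i: int) -> bool:
        return any(i in p for p in self.pairs)

    def sorted_pairs(self) -> list:
        return sorted(self.pairs)

    # -- rendering -------------------------------------------------------
    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)

    def with_pairs(self, pairs: Iterable, provenance: str | None = None,
                   score: float | None = None) -> "SecondaryStructure":
        """Copy with a new pair set (re-validated)."""
        return replace(
            self,
            pairs=frozenset(tuple(p) for p in pairs),
            provenance=self.provenance if provenance is None else provenance,
            score=self.score if score is None else score,
        )


def _validate_pairs(pairs: frozenset, length: int) -> None:
    seen = set()
    for i, j in pairs:
        if not (0 <= i < j < length):
            raise StructureError(f"pair ({i},{j}) out of bounds for length {length}")
        if i in seen or j in seen:
            raise StructureError(f"index reused in pair ({i},{j})")
        seen.add(i)
        seen.add(j)
    # nesting: no two pairs (i,j), (k,l) with i < k < j < l
    stack = []
    opens = {i: j for i, j in pairs}
    closes = {j for _, j in pairs}
    for idx in range(length):
        if idx in opens:
            stack.append(opens[idx])
        elif idx in closes:
            if not stack or stack[-1] != idx:
                raise StructureError("pairs are not properly nested (pseudoknot)")
            stack.pop()


def parse_dotbracket_string(db: str, seq_id: str = "", score: float = 0.0,
                            provenance: str = "parsed") -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    Raises :class:`StructureError` on the first unbalanced bracket, reporting
    its 0-based column.
    """
    stack = []
    pairs = []
    for col, ch in enumerate(db):
        if ch == "(":
            stack.append(col)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at column {col}")
            pairs.append((stack.pop(), col))
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at column {col}")
    if stack:
        raise StructureError(f"unbalanced '(' at column {stack[0]}")
    return SecondaryStructure(seq_id=seq_id, length=len(db),
                              pairs=frozenset(pairs), score=score,
                              provenance=provenance)
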