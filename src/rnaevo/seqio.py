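"""Sequence, alignment, tree and structure-file I/O.

Conventions used throughout the package:

* all coordinates are 0-based, intervals half-open ``[start, end)``;
* sequences are normalized to the RNA alphabet ``{A, C, G, U, N}``:
  ``T`` becomes ``U``, lowercase is uppercased, and IUPAC degenerate codes
  other than ``N`` collapse to ``N`` (N never pairs downstream);
* dot-bracket is the canonical structure interchange; CT files are read-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structure import SecondaryStructure, StructureError, parse_dotbracket_string

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGUN")
_DEGENERATE = frozenset("RYSWKMBDHVX")


class SeqIOError(ValueError):
    """Raised for malformed sequence/alignment/tree input."""


@dataclass(frozen=True)
class RnaSequence:
    """An identified RNA residue string.

    ``residues`` is guaranteed to be over {A,C,G,U,N} after normalization.
    """

    id: str
    residues: str
    clade: str | None = None
    source: str | None = None

    def __post_init__(self):
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise SeqIOError(
                f"sequence {self.id!r} contains non-normalized residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Ordered gapped rows of equal length over {A,C,G,U,N,-}."""

    rows: list  # list of (id, gapped residue string)
    ids: list = field(init=False)

    def __post_init__(self):
        if self.rows:
            length = len(self.rows[0][1])
            for rid, row in self.rows:
                if len(row) != length:
                    raise SeqIOError(f"row {rid!r} length {len(row)} != {length}")
        self.ids = [rid for rid, _ in self.rows]
        if len(set(self.ids)) != len(self.ids):
            raise SeqIOError("duplicate row ids in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise SeqIOError(f"taxon {rid!r} not in alignment")

    def ungapped(self, rid: str) -> RnaSequence:
        return RnaSequence(id=rid, residues=self.row(rid).replace("-", ""))

    def column(self, k: int) -> list:
        return [s[k] for _, s in self.rows]

    def subset(self, ids: Sequence[str]) -> "Alignment":
        keep = set(ids)
        missing = keep - set(self.ids)
        if missing:
            raise SeqIOError(f"taxa not in alignment: {sorted(missing)}")
        return Alignment(rows=[(r, s) for r, s in self.rows if r in keep])


def normalize_residues(raw: str, *, allow_gaps: bool = False) -> tuple:
    """Normalize to RNA alphabet; returns (normalized, n_degenerate_collapsed)."""
    out = []
    n_collapsed = 0
    for ch in raw.upper():
        if ch == "T":
            ch = "U"
        if ch in _DEGENERATE:
            ch = "N"
            n_collapsed += 1
        if ch == "-" and allow_gaps:
            out.append(ch)
            continue
        if ch not in RNA_ALPHABET:
            raise SeqIOError(f"unrecognized residue {ch!r}")
        out.append(ch)
    return "".join(out), n_collapsed


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, *, source: str | None = None) -> list:
    """Read a FASTA file into normalized :class:`RnaSequence` records.

    T is converted to U, lowercase uppercased and degenerate codes collapsed
    to N (logged once per file).  Duplicate ids and empty records are hard
    errors.  Record order is preserved.
    """
    path = Path(path)
    seqs: list[RnaSequence] = []
    seen: set[str] = set()
    total_collapsed = 0
    had_t = False
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise SeqIOError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
        raw = str(rec.seq)
        if not raw:
            raise SeqIOError(f"empty record {rid!r} in {path}")
        had_t = had_t or ("T" in raw.upper())
        residues, n_collapsed = normalize_residues(raw)
        total_collapsed += n_collapsed
        seqs.append(RnaSequence(id=rid, residues=residues,
                                source=source or str(path)))
    if had_t:
        logger.info("%s: DNA input (T) converted to RNA alphabet (U)", path)
    if total_collapsed:
        logger.info("%s: %d degenerate residues collapsed to N", path, total_collapsed)
    return seqs


def write_fasta(seqs: Iterable[RnaSequence], path) -> None:
    """Write sequences as 60-column wrapped FASTA."""
    seqs = list(seqs)
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise SeqIOError("duplicate ids in FASTA output")
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_alignment_fasta(path) -> Alignment:
    """Read an aligned FASTA (rows may contain ``-``) into an Alignment."""
    rows = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues, _ = normalize_residues(str(rec.seq), allow_gaps=True)
        rows.append((rec.id, residues))
    return Alignment(rows=rows)


def write_alignment_fasta(alignment: Alignment, path) -> None:
    records = [SeqRecord(Seq(s), id=rid, description="") for rid, s in alignment.rows]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(path) -> dendropy.Tree:
    """Read a single rooted Newick tree.

    Branch lengths are optional (parsimony needs topology only).  Raises
    :class:`SeqIOError` on parse failure.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error types
        raise SeqIOError(f"could not parse Newick file {path}: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise SeqIOError(f"duplicate tip labels in {path}")
    return tree


def read_newick_string(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise SeqIOError(f"could not parse Newick string: {exc}") from exc
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


# ---------------------------------------------------------------------------
# Structures: dot-bracket / Vienna / CT
# ---------------------------------------------------------------------------

def parse_dotbracket(db: str, seq: RnaSequence) -> SecondaryStructure:
    """Parse dot-bracket *db* for sequence *seq* (lengths must agree)."""
    if len(db) != len(seq.residues):
        raise StructureError(
            f"dot-bracket length {len(db)} != sequence length {len(seq.residues)}"
        )
    return parse_dotbracket_string(db, seq_id=seq.id)


def render_dotbracket(structure: SecondaryStructure) -> str:
    return structure.dot_bracket()


def read_vienna(path) -> list:
    """Read a Vienna file: repeated (``>header``, sequence, structure) triples.

    Returns a list of (RnaSequence, SecondaryStructure) pairs.
    """
    out = []
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise SeqIOError(f"{path}: expected '>' header at line {i + 1}")
        rid = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise SeqIOError(f"{path}: truncated record {rid!r}")
        residues, _ = normalize_residues(lines[i + 1])
        seq = RnaSequence(id=rid, residues=residues, source=str(path))
        db = lines[i + 2].split()[0]  # optional trailing score ignored
        out.append((seq, parse_dotbracket(db, seq)))
        i += 3
    return out


def write_vienna(entries: Iterable, path) -> None:
    """Write (RnaSequence, SecondaryStructure) pairs as a Vienna file."""
    with open(path, "w") as fh:
        for seq, struct in entries:
            fh.write(f">{seq.id}\n{seq.residues}\n{struct.dot_bracket()}\n")


def read_ct(path) -> tuple:
    """Read a connectivity-table (CT) structure file (read-only courtesy).

    Returns (RnaSequence, SecondaryStructure).  Only the first structure in
    the file is read.
    """
    lines = [ln.strip() for ln in open(path) if ln.strip()]
    header = lines[0].split()
    n = int(header[0])
    title = " ".join(header[1:]) or "ct"
    residues = []
    pairs = set()
    for ln in lines[1:n + 1]:
        fields = ln.split()
        idx = int(fields[0]) - 1
        residues.append(fields[1])
        partner = int(fields[4]) - 1
        if partner >= 0 and idx < partner:
            pairs.add((idx, partner))
    norm, _ = normalize_residues("".join(residues))
    seq = RnaSequence(id=title.split()[0], residues=norm, source=str(path))
    return seq, SecondaryStructure(seq_id=seq.id, length=len(norm),
                                   pairs=frozenset(pairs), provenance="parsed")
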