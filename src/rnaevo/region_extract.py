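"""Anchor-based extraction of the V4 hypervariable region.

The V4 expansion segment of the SSU rRNA (163-261 nt in *Euplotes* and
relatives) sits between highly conserved flanks.  Rather than running a
covariance-model aligner, this module derives short consensus anchors from
any reference alignment in which the V4 columns are known, then locates
them in each full-length sequence by best-scoring ungapped local match
(match +1, mismatch -1, N matches nothing).  The region strictly between
the two anchor matches is the V4.

Extraction is deterministic: ties between equal-scoring placements go to
the leftmost position, and among admissible right-anchor placements the
nearest downstream one is chosen (shortest V4), which guards against
run-on regions in partial sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import yaml

from .seqio import Alignment, RnaSequence

DEFAULT_MAX_MISMATCH_FRACTION = 0.2


class RegionNotFoundError(ValueError):
    """No admissible anchor placement; carries the best partial scores."""

    def __init__(self, msg, left_score=None, right_score=None):
        super().__init__(msg)
        self.left_score = left_score
        self.right_score = right_score


@dataclass(frozen=True)
class AnchorProfile:
    """Conserved flanking anchors bracketing the V4 region."""

    left_anchor: str
    right_anchor: str
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION

    def __post_init__(self):
        if not self.left_anchor or not self.right_anchor:
            raise ValueError("anchors must be non-empty")
        if "-" in self.left_anchor or "-" in self.right_anchor:
            raise ValueError("anchors must not contain gaps")
        if not 0 <= self.max_mismatch_fraction <= 1:
            raise ValueError("max_mismatch_fraction must be in [0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"left_anchor": self.left_anchor,
                            "right_anchor": self.right_anchor,
                            "max_mismatch_fraction": self.max_mismatch_fraction},
                           fh)

    @classmethod
    def from_yaml(cls, path) -> "AnchorProfile":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass(frozen=True)
class RegionHit:
    """A located V4 region on the ungapped sequence, [start, end)."""

    taxon_id: str
    start: int
    end: int
    v4: RnaSequence
    score: float

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")
        if len(self.v4.residues) != self.end - self.start:
            raise ValueError("v4 length != end - start")

    @property
    def length(self) -> int:
        return self.end - self.start


def build_anchor_profile(alignment: Alignment, v4_columns: tuple,
                         anchor_length: int = 20,
                         max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION
                         ) -> AnchorProfile:
    """Majority-rule consensus anchors from the columns flanking the V4.

    *v4_columns* is the half-open [start, end) column interval of the V4 in
    the alignment.  The left anchor is the consensus of the *anchor_length*
    columns immediately 5' of the interval, the right anchor of those
    immediately 3'; gap-majority columns are dropped from the consensus.
    Majority ties break alphabetically (A < C < G < U).
    """
    start, end = v4_columns
    if not (0 <= start < end <= alignment.length):
        raise ValueError("v4_columns outside alignment")
    if start < anchor_length or alignment.length - end < anchor_length:
        raise ValueError(
            f"flank too short: need {anchor_length} columns on each side of the V4"
        )
    left = _consensus(alignment, range(start - anchor_length, start))
    right = _consensus(alignment, range(end, end + anchor_length))
    return AnchorProfile(left_anchor=left, right_anchor=right,
                         max_mismatch_fraction=max_mismatch_fraction)


def _consensus(alignment: Alignment, columns) -> str:
    out = []
    for k in columns:
        counts = Counter(alignment.column(k))
        # ties broken alphabetically; '-' sorts before letters, so handle it apart
        gap = counts.pop("-", 0)
        if not counts or gap > sum(counts.values()):
            continue  # gap-majority column contributes nothing to the anchor
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        out.append(best)
    return "".join(out)


def _scan(residues: str, anchor: str) -> tuple:
    """Best ungapped placement of *anchor*: (start, score, n_mismatch).

    Score: match +1, mismatch -1; N never matches.  Leftmost best wins.
    """
    n, m = len(residues), len(anchor)
    if n < m:
        return 0, -m, m
    seq = np.frombuffer(residues.encode(), dtype=np.uint8)
    anc = np.frombuffer(anchor.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq, m)
    match = (windows == anc) & (windows != ord("N")) & (anc != ord("N"))
    matches = match.sum(axis=1)
    scores = 2 * matches - m
    best = int(np.argmax(scores))  # argmax returns the leftmost maximum
    return best, int(scores[best]), int(m - matches[best])


def locate_v4(seq: RnaSequence, profile: AnchorProfile) -> RegionHit:
    """Locate the V4 region between the profile's anchors.

    The left anchor takes its best-scoring placement; the right anchor the
    nearest admissible placement strictly downstream (shortest V4).  A
    placement is admissible when its mismatch fraction does not exceed the
    profile's ceiling.  Raises :class:`RegionNotFoundError` otherwise.
    """
    residues = seq.residues
    la, ra = profile.left_anchor, profile.right_anchor
    if len(residues) <= len(la) + len(ra):
        raise RegionNotFoundError(
            f"{seq.id}: sequence shorter than the two anchors combined")

    l_start, l_score, l_mm = _scan(residues, la)
    if l_mm / len(la) > profile.max_mismatch_fraction:
        raise RegionNotFoundError(
            f"{seq.id}: left anchor not found (best score {l_score}, "
            f"{l_mm}/{len(la)} mismatches)", left_score=l_score)
    v4_start = l_start + len(la)

    downstream = residues[v4_start:]
    if len(downstream) < len(ra):
        raise RegionNotFoundError(f"{seq.id}: no room for right anchor",
                                  left_score=l_score)
    seq_arr = np.frombuffer(downstream.encode(), dtype=np.uint8)
    anc = np.frombuffer(ra.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq_arr, len(ra))
    match = (windows == anc) & (windows != ord("N")) & (anc != ord("N"))
    mism = len(ra) - match.sum(axis=1)
    admissible = np.nonzero(
        (mism / len(ra) <= profile.max_mismatch_fraction)
        # right anchor strictly downstream of the left: offset >= 1 leaves
        # at least one V4 residue between the anchors
        & (np.arange(len(mism)) >= 1)
    )[0]
    if admissible.size == 0:
        best_r = int((len(ra) - 2 * mism).max()) if mism.size else None
        raise RegionNotFoundError(
            f"{seq.id}: right anchor not found downstream of left anchor",
            left_score=l_score, right_score=best_r)
    offset = int(admissible[0])  # nearest admissible: shortest V4
    r_score = int(len(ra) - 2 * mism[offset])
    v4_end = v4_start + offset
    v4 = RnaSequence(id=seq.id, residues=residues[v4_start:v4_end],
                     clade=seq.clade, source=seq.source)
    return RegionHit(taxon_id=seq.id, start=v4_start, end=v4_end, v4=v4,
                     score=float(l_score + r_score))
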