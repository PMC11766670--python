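"""Compensatory base change (CBC) counting between aligned taxa.

At a paired alignment column (k, l), two taxa show a CBC when both partner
residues differ while each taxon still forms a canonical (G:C, A:U) or
wobble (G:U) pair — the signature of stem-preserving co-evolution used to
delimit cryptic species.  A hemi-CBC (hCBC) changes exactly one partner
with pairing preserved.  Columns where either taxon has a gap/N, or where
either duo cannot pair, are skipped and reported rather than imputed: the
statistic is about changes in nucleotide *bonds*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import Alignment
from .structure import SecondaryStructure, is_canonical_or_wobble

VERDICT_SAME = "same"
VERDICT_CBC = "CBC"
VERDICT_HCBC = "hCBC"
VERDICT_NONCOMP = "non-compensatory"
VERDICT_SKIP_GAP = "skipped-gap"
VERDICT_SKIP_NONPAIR = "skipped-nonpairing"


@dataclass(frozen=True)
class PairColumns:
    """Nested column index pairs (k, l), k < l, each column used once."""

    pairs: tuple

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(sorted(tuple(p) for p in self.pairs)))
        seen = set()
        for k, l in self.pairs:
            if k >= l:
                raise ValueError(f"pair column ({k},{l}) must have k < l")
            if k in seen or l in seen:
                raise ValueError(f"column reused in pair ({k},{l})")
            seen.update((k, l))

    @classmethod
    def from_structure(cls, structure: SecondaryStructure) -> "PairColumns":
        return cls(pairs=tuple(structure.sorted_pairs()))

    def __len__(self):
        return len(self.pairs)


@dataclass
class CbcReport:
    """Pairwise CBC/hCBC counts plus the per-column verdict detail."""

    id_a: str
    id_b: str
    n_cbc: int
    n_hcbc: int
    n_columns_compared: int
    detail: pd.DataFrame = field(repr=False, default=None)


def classify_duo(a1: str, a2: str, b1: str, b2: str) -> str:
    """Verdict for one pair column given taxon A's and B's residue duos."""
    if any(r in ("-", "N") for r in (a1, a2, b1, b2)):
        return VERDICT_SKIP_GAP
    if not (is_canonical_or_wobble(a1, a2) and is_canonical_or_wobble(b1, b2)):
        return VERDICT_SKIP_NONPAIR
    if a1 == b1 and a2 == b2:
        return VERDICT_SAME
    if a1 != b1 and a2 != b2:
        return VERDICT_CBC
    return VERDICT_HCBC


def count_cbc(alignment: Alignment, pair_columns: PairColumns,
              id_a: str, id_b: str) -> CbcReport:
    """Count CBCs and hemi-CBCs between two taxa over shared pair columns.

    The report is symmetric in (A, B) verdict-by-verdict;
    ``n_columns_compared`` counts columns not skipped for gaps/N or
    non-pairing duos.
    """
    row_a = alignment.row(id_a)
    row_b = alignment.row(id_b)
    if pair_columns.pairs and max(l for _, l in pair_columns.pairs) >= alignment.length:
        raise ValueError("pair columns exceed alignment length")
    records = []
    for k, l in pair_columns.pairs:
        verdict = classify_duo(row_a[k], row_a[l], row_b[k], row_b[l])
        records.append({"col5": k, "col3": l,
                        "a": row_a[k] + row_a[l], "b": row_b[k] + row_b[l],
                        "verdict": verdict})
    detail = pd.DataFrame(records,
                          columns=["col5", "col3", "a", "b", "verdict"])
    counts = detail["verdict"].value_counts() if records else pd.Series(dtype=int)
    n_cbc = int(counts.get(VERDICT_CBC, 0))
    n_hcbc = int(counts.get(VERDICT_HCBC, 0))
    n_skipped = int(counts.get(VERDICT_SKIP_GAP, 0) +
                    counts.get(VERDICT_SKIP_NONPAIR, 0))
    return CbcReport(id_a=id_a, id_b=id_b, n_cbc=n_cbc, n_hcbc=n_hcbc,
                     n_columns_compared=len(pair_columns) - n_skipped,
                     detail=detail)


def cbc_matrix(alignment: Alignment, pair_columns: PairColumns,
               taxa: list | None = None) -> tuple:
    """Symmetric pairwise CBC and hCBC count matrices (zero diagonal).

    Returns ``(cbc_df, hcbc_df)`` as DataFrames indexed by taxon id.
    """
    taxa = list(taxa) if taxa is not None else list(alignment.ids)
    if len(taxa) < 2:
        raise ValueError("need at least two taxa for a CBC matrix")
    n = len(taxa)
    cbc = np.zeros((n, n), dtype=int)
    hcbc = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            rep = count_cbc(alignment, pair_columns, taxa[i], taxa[j])
            cbc[i, j] = cbc[j, i] = rep.n_cbc
            hcbc[i, j] = hcbc[j, i] = rep.n_hcbc
    return (pd.DataFrame(cbc, index=taxa, columns=taxa),
            pd.DataFrame(hcbc, index=taxa, columns=taxa))


def restrict_to_stem(pair_columns: PairColumns, col_range: tuple) -> PairColumns:
    """Keep only pair columns fully inside [start, end) — e.g. helix E23_8."""
    start, end = col_range
    return PairColumns(pairs=tuple((k, l) for k, l in pair_columns.pairs
                                   if start <= k and l < end))
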