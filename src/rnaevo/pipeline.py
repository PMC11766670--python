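"""End-to-end orchestration: extract -> fold -> classify -> CBC -> ancestral.

The pipeline is deterministic given its config and inputs.  Per-taxon
failures (e.g. V4 not found) drop the taxon with a machine-readable reason
code and never abort the run; only global problems (no sequences, tree vs
character-matrix mismatch beyond the configured threshold) are errors.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from . import __version__
from .ancestral import changes_table, fitch, resolve_and_map, reversal_report
from .cbc import PairColumns, cbc_matrix
from .folding import (FoldParams, curate, fold_consensus, fold_mfe,
                      project_consensus, select_structure)
from .region_extract import AnchorProfile, RegionNotFoundError, locate_v4
from .seqio import Alignment, RnaSequence, write_vienna
from .topology import DEFAULT_BULGE_TOL, UNCLASSIFIED, classify

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run.

    Inputs may be in-memory objects (library use) or paths (CLI use).
    ``resolution_rule`` defaults to ACCTRAN: reversals — the signal this
    pipeline exists to surface — are only visible under a resolution that
    accelerates changes rootward; the report records the rule used.
    """

    sequences: list = None                    # list[RnaSequence]
    tree: dendropy.Tree | None = None
    alignment: Alignment | None = None        # V4 alignment (optional)
    profile: AnchorProfile | None = None
    skip_extraction: bool = False             # sequences are already V4
    fold_params: FoldParams = field(default_factory=FoldParams)
    bulge_tol: int = DEFAULT_BULGE_TOL
    e23_rule: str = "largest"
    cbc_taxa: list | None = None
    resolution_rule: str = "acctran"
    prefer_state: str | None = None
    max_tree_mismatch_fraction: float = 0.5
    clades: dict | None = None                # taxon -> clade label
    out_dir: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = {
            "n_sequences": len(self.sequences or []),
            "ids": [s.id for s in (self.sequences or [])],
            "skip_extraction": self.skip_extraction,
            "fold_params": {
                "pair_scores": sorted((a + b, s) for (a, b), s
                                      in self.fold_params.pair_scores.items()),
                "min_hairpin": self.fold_params.min_hairpin,
                "covariance_bonus": self.fold_params.covariance_bonus,
                "inconsistency_penalty": self.fold_params.inconsistency_penalty,
            },
            "bulge_tol": self.bulge_tol,
            "e23_rule": self.e23_rule,
            "cbc_taxa": self.cbc_taxa,
            "resolution_rule": self.resolution_rule,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Consolidated per-taxon results plus CBC and reconstruction summaries."""

    per_taxon: pd.DataFrame
    exclusions: pd.DataFrame
    cbc: pd.DataFrame | None
    hcbc: pd.DataFrame | None
    n_steps: int | None
    n_gains: int | None
    n_reversals: int | None
    reversal_edges: pd.DataFrame | None
    changes: pd.DataFrame | None
    resolution_rule: str | None
    root_state: str | None
    provenance: dict
    structures: dict = field(repr=False, default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "per_taxon": self.per_taxon.to_dict(orient="records"),
            "exclusions": self.exclusions.to_dict(orient="records"),
            "cbc": None if self.cbc is None else self.cbc.to_dict(),
            "hcbc": None if self.hcbc is None else self.hcbc.to_dict(),
            "reconstruction": {
                "n_steps": self.n_steps,
                "n_gains": self.n_gains,
                "n_reversals": self.n_reversals,
                "resolution_rule": self.resolution_rule,
                "root_state": self.root_state,
                "reversal_edges": (None if self.reversal_edges is None
                                   else self.reversal_edges.to_dict(orient="records")),
            },
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and (optionally) write per-stage artifacts."""
    if not config.sequences:
        raise ValueError("no input sequences")

    exclusions = []
    hits = {}
    if config.skip_extraction:
        for seq in config.sequences:
            hits[seq.id] = None
        v4_seqs = {s.id: s for s in config.sequences}
    else:
        if config.profile is None:
            raise ValueError("anchor profile required unless skip_extraction")
        v4_seqs = {}
        for seq in config.sequences:
            try:
                hit = locate_v4(seq, config.profile)
            except RegionNotFoundError as exc:
                logger.warning("dropping %s: %s", seq.id, exc)
                exclusions.append({"taxon": seq.id, "stage": "extract",
                                   "reason": "v4_not_found", "detail": str(exc)})
                continue
            hits[seq.id] = hit
            v4_seqs[seq.id] = hit.v4

    # consensus folding (when an alignment is available)
    consensus = None
    aln = config.alignment
    if aln is not None:
        avail = [t for t in aln.ids if t in v4_seqs]
        aln = aln.subset(avail) if set(avail) != set(aln.ids) else aln
        consensus, _ = fold_consensus(aln, config.fold_params)

    # per-taxon structure: best of curated MFE fold and curated consensus
    # projection, judged against the projection as reference
    rows = []
    structures = {}
    for tid, v4 in v4_seqs.items():
        mfe = curate(fold_mfe(v4, config.fold_params), v4)
        candidates = [mfe]
        reference = None
        if consensus is not None and tid in aln.ids:
            proj = project_consensus(consensus, aln, tid)
            if len(proj.dot_bracket()) == len(v4.residues):
                reference = proj
                candidates.append(curate(proj, v4))
        chosen = select_structure(candidates, reference)
        structures[tid] = chosen
        report = classify(chosen, bulge_tol=config.bulge_tol,
                          e23_rule=config.e23_rule)
        hit = hits.get(tid)
        rows.append({
            "taxon": tid,
            "v4_start": hit.start if hit else None,
            "v4_end": hit.end if hit else None,
            "v4_length": len(v4.residues),
            "anchor_score": hit.score if hit else None,
            "fold_score": chosen.score,
            "n_pairs": chosen.n_pairs,
            "provenance": chosen.provenance,
            "struct_type": report.struct_type,
            "terminal_hairpin_size": report.terminal_hairpin_size,
            "n_distal_subhelices": report.n_distal_subhelices,
            "clade": (config.clades or {}).get(tid),
        })
    per_taxon = pd.DataFrame(rows)

    # CBC over the configured taxon subset, on that subset's own consensus
    cbc_df = hcbc_df = None
    if aln is not None and config.cbc_taxa:
        taxa = [t for t in config.cbc_taxa if t in aln.ids]
        missing = set(config.cbc_taxa) - set(taxa)
        for t in sorted(missing):
            exclusions.append({"taxon": t, "stage": "cbc",
                               "reason": "not_in_alignment", "detail": ""})
        if len(taxa) >= 2:
            sub = aln.subset(taxa)
            sub_consensus, _ = fold_consensus(sub, config.fold_params)
            cbc_df, hcbc_df = cbc_matrix(
                sub, PairColumns.from_structure(sub_consensus), taxa)

    # ancestral reconstruction
    n_steps = n_gains = n_reversals = None
    reversal_edges = changes = root_state = None
    rule = None
    if config.tree is not None and not per_taxon.empty:
        matrix = {}
        for rec in rows:
            if rec["struct_type"] == UNCLASSIFIED:
                exclusions.append({"taxon": rec["taxon"], "stage": "ancestral",
                                   "reason": "unclassified_structure",
                                   "detail": ""})
                continue
            matrix[rec["taxon"]] = rec["struct_type"]
        tips = {leaf.taxon.label for leaf in config.tree.leaf_node_iter()}
        on_tree = {t: s for t, s in matrix.items() if t in tips}
        for t in sorted(set(matrix) - set(on_tree)):
            exclusions.append({"taxon": t, "stage": "ancestral",
                               "reason": "not_on_tree", "detail": ""})
        if matrix and len(on_tree) < (1 - config.max_tree_mismatch_fraction) * len(matrix):
            raise ValueError(
                f"tree/matrix mismatch: only {len(on_tree)}/{len(matrix)} classified "
                f"taxa are on the tree (threshold "
                f"{config.max_tree_mismatch_fraction:.0%})")
        if len(on_tree) >= 2:
            rule = config.resolution_rule
            recon = fitch(config.tree, on_tree)
            recon = resolve_and_map(recon, rule, prefer_state=config.prefer_state)
            n_steps = recon.n_steps
            n_reversals = len(recon.reversals)
            n_gains = len(recon.changes) - n_reversals
            reversal_edges = reversal_report(recon)
            changes = changes_table(recon)
            root_state = recon.root_state

    report = RunReport(
        per_taxon=per_taxon,
        exclusions=pd.DataFrame(exclusions,
                                columns=["taxon", "stage", "reason", "detail"]),
        cbc=cbc_df, hcbc=hcbc_df,
        n_steps=n_steps, n_gains=n_gains, n_reversals=n_reversals,
        reversal_edges=reversal_edges, changes=changes,
        resolution_rule=rule, root_state=root_state,
        provenance={"version": __version__, "config_hash": config.config_hash(),
                    "seed": config.seed},
        structures=structures,
    )
    if config.out_dir:
        _write_artifacts(report, v4_seqs, config)
    return report


def _write_artifacts(report: RunReport, v4_seqs: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_taxon.to_csv(out / "report.tsv", sep="\t", index=False)
    report.exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    (out / "report.json").write_text(report.to_json())
    if report.cbc is not None:
        report.cbc.to_csv(out / "cbc_matrix.tsv", sep="\t")
        report.hcbc.to_csv(out / "hcbc_matrix.tsv", sep="\t")
    if report.changes is not None:
        report.changes.to_csv(out / "changes.tsv", sep="\t", index=False)
        report.reversal_edges.to_csv(out / "reversals.tsv", sep="\t", index=False)
    write_vienna(((v4_seqs[t], s) for t, s in report.structures.items()),
                 out / "structures.vienna")


def summarize_by_clade(report: RunReport, clades: dict | None = None
                       ) -> pd.DataFrame:
    """Per-clade Type I/II counts and terminal-hairpin-size ranges."""
    df = report.per_taxon.copy()
    if clades is not None:
        df["clade"] = df["taxon"].map(clades)
    if df["clade"].isna().all():
        raise ValueError("no clade labels available")
    rows = []
    for clade, grp in df.groupby("clade", dropna=True):
        sizes = grp["terminal_hairpin_size"].dropna()
        rows.append({
            "clade": clade,
            "n_taxa": len(grp),
            "n_type_i": int((grp["struct_type"] == "TYPE_I").sum()),
            "n_type_ii": int((grp["struct_type"] == "TYPE_II").sum()),
            "hairpin_min": int(sizes.min()) if len(sizes) else None,
            "hairpin_max": int(sizes.max()) if len(sizes) else None,
        })
    return pd.DataFrame(rows)
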