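"""Clade-based species assignment against a labeled reference panel, and
the cryptic-description mining pipeline.

A query is assigned to a species when the minimal rooted clade containing
the query and at least one reference holds references of exactly one
ingroup species (and, when bootstrap supports are available, that clade's
support passes the configured threshold).  A database entry deposited
under an older name but assigned here to a newly delineated species is a
"cryptic description" of that species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import dendropy
import numpy as np
import pandas as pd

from .align import Alignment, CoverageStats, progressive_msa, query_coverage
from .phylo import (
    BootstrapResult,
    OutgroupError,
    attach_supports,
    bootstrap_support,
    nj_tree,
    p_distance_matrix,
    root_with_outgroup,
    tree_bipartitions,
)
from .seqcore import SequenceRecord

__all__ = [
    "ReferencePanel",
    "SpeciesAssignment",
    "MiningReport",
    "ConcordanceRecord",
    "load_reference_panel",
    "assign_by_clade",
    "assign_all",
    "build_assignment_tree",
    "mine_candidates",
    "reconcile_panel_and_tree",
]

UNASSIGNED = "unassigned"


@dataclass
class ReferencePanel:
    """Species-labeled marker sequences, with type-strain and outgroup flags."""

    records: List[SequenceRecord]
    labels: Dict[str, str]
    type_strain_flags: Dict[str, bool] = field(default_factory=dict)
    outgroup_ids: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = {r.id for r in self.records}
        unlabeled = ids - set(self.labels)
        if unlabeled:
            raise ValueError(f"unlabeled panel records: {sorted(unlabeled)}")
        stray = self.outgroup_ids - ids
        if stray:
            raise ValueError(f"outgroup ids not in panel: {sorted(stray)}")
        self.type_strain_flags = {rid: self.type_strain_flags.get(rid, False) for rid in ids}

    @property
    def ingroup_ids(self) -> Set[str]:
        return {r.id for r in self.records} - self.outgroup_ids

    @property
    def species(self) -> Set[str]:
        return {self.labels[rid] for rid in self.ingroup_ids}

    def record(self, rid: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)


def load_reference_panel(fasta_path: Union[str, Path], labels_path: Union[str, Path]
                         ) -> ReferencePanel:
    """Panel from FASTA + labels TSV (columns: id, species, type_strain, outgroup)."""
    from .seqcore import read_fasta

    records = read_fasta(fasta_path)
    table = pd.read_csv(labels_path, sep="\t", dtype=str, comment="#").fillna("")
    labels = dict(zip(table["id"], table["species"]))
    truthy = {"1", "true", "yes", "y"}
    type_flags = {
        row["id"]: str(row.get("type_strain", "")).strip().lower() in truthy
        for _, row in table.iterrows()
    }
    outgroup = {
        row["id"] for _, row in table.iterrows()
        if str(row.get("outgroup", "")).strip().lower() in truthy
    }
    return ReferencePanel(records, labels, type_flags, outgroup)


@dataclass
class SpeciesAssignment:
    query_id: str
    assigned_species: str  # species name or "unassigned"
    supporting_clade_support: Optional[float] = None
    reference_ids_in_clade: List[str] = field(default_factory=list)


def build_assignment_tree(
    alignment: Alignment,
    panel: ReferencePanel,
    bootstrap_replicates: int = 0,
    seed: Optional[int] = None,
) -> Tuple[dendropy.Tree, Optional[BootstrapResult]]:
    """NJ tree (optionally with bootstrap supports), outgroup-rooted."""
    boot: Optional[BootstrapResult] = None
    if bootstrap_replicates > 0:
        boot = bootstrap_support(alignment, replicates=bootstrap_replicates, seed=seed)
        tree = boot.tree
    else:
        tree = nj_tree(p_distance_matrix(alignment))
    outgroup_labels = sorted(panel.outgroup_ids)
    if outgroup_labels:
        try:
            tree = root_with_outgroup(tree, outgroup_labels)
        except OutgroupError:
            # unlabeled queries may nest inside the outgroup: root on the
            # smallest clade that still contains every outgroup reference
            tree = _root_at_minimal_superset(tree, set(outgroup_labels))
        if boot is not None:
            attach_supports(tree, boot.support)
    else:
        tree.is_rooted = True
    return tree, boot


def _root_at_minimal_superset(tree: dendropy.Tree, og: Set[str]) -> dendropy.Tree:
    tree = tree.clone(depth=1)
    all_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if not og <= all_labels:
        raise OutgroupError(f"outgroup taxa absent: {sorted(og - all_labels)}")
    best = None
    best_size = None
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        labels = {lf.taxon.label for lf in nd.leaf_iter()}
        if og <= labels and (best_size is None or len(labels) < best_size):
            best, best_size = nd, len(labels)
        comp = all_labels - labels
        if og <= comp and (best_size is None or len(comp) < best_size):
            # root on the same edge; the outgroup side is the complement
            best, best_size = nd, len(comp)
    if best is None:
        raise OutgroupError(f"no edge isolates the outgroup {sorted(og)}")
    length = best.edge.length or 0.0
    tree.is_rooted = True
    tree.reroot_at_edge(best.edge, length1=length / 2.0, length2=length / 2.0,
                        update_bipartitions=False)
    return tree


def _node_support(node: dendropy.Node) -> Optional[float]:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def assign_by_clade(
    alignment_or_tree: Union[Alignment, dendropy.Tree],
    query_id: str,
    panel: ReferencePanel,
    support_threshold: Optional[float] = None,
    bootstrap_replicates: int = 0,
    seed: Optional[int] = None,
) -> SpeciesAssignment:
    """Assign a query by the minimal clade containing it and >=1 reference.

    The assignment stands only if all ingroup references inside that clade
    belong to exactly one species, no outgroup reference intrudes, and the
    clade's bootstrap support (when available) meets the threshold
    (default 70 when supports were computed, otherwise topology-only).
    """
    if isinstance(alignment_or_tree, Alignment):
        tree, boot = build_assignment_tree(
            alignment_or_tree, panel, bootstrap_replicates, seed
        )
    else:
        tree = alignment_or_tree
    return _assign_on_tree(tree, query_id, panel, support_threshold)


def _assign_on_tree(
    tree: dendropy.Tree,
    query_id: str,
    panel: ReferencePanel,
    support_threshold: Optional[float],
) -> SpeciesAssignment:
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == query_id:
            leaf = lf
            break
    if leaf is None:
        raise KeyError(f"query {query_id!r} not present in tree")
    panel_ids = {r.id for r in panel.records}
    has_supports = any(_node_support(nd) is not None
                       for nd in tree.preorder_internal_node_iter())
    if support_threshold is None:
        support_threshold = 70.0 if has_supports else 0.0

    node = leaf.parent_node
    while node is not None:
        labels = {l.taxon.label for l in node.leaf_iter()}
        refs = labels & panel_ids
        if refs:
            ingroup_refs = sorted(refs & panel.ingroup_ids)
            outgroup_refs = refs & panel.outgroup_ids
            if outgroup_refs or not ingroup_refs:
                return SpeciesAssignment(query_id, UNASSIGNED, _node_support(node),
                                         sorted(refs))
            species = {panel.labels[r] for r in ingroup_refs}
            if len(species) != 1:
                return SpeciesAssignment(query_id, UNASSIGNED, _node_support(node),
                                         ingroup_refs)
            # the delineating clade is the largest ancestor that still holds
            # only this species' references and no outgroup: its support is
            # what "unambiguous delineation" from the other species means
            target = species.pop()
            delineating = node
            up = node.parent_node
            while up is not None:
                up_labels = {l.taxon.label for l in up.leaf_iter()}
                up_refs = up_labels & panel_ids
                up_species = {panel.labels[r] for r in (up_refs & panel.ingroup_ids)}
                if (up_refs & panel.outgroup_ids) or up_species != {target}:
                    break
                delineating = up
                up = up.parent_node
            support = _node_support(delineating)
            refs_in = sorted({l.taxon.label for l in delineating.leaf_iter()} & panel_ids)
            if support is not None and support < support_threshold:
                return SpeciesAssignment(query_id, UNASSIGNED, support, refs_in)
            return SpeciesAssignment(query_id, target, support, refs_in)
        node = node.parent_node
    raise KeyError(f"no panel reference found in tree containing {query_id!r}")


def assign_all(
    tree: dendropy.Tree,
    query_ids: Sequence[str],
    panel: ReferencePanel,
    support_threshold: Optional[float] = None,
) -> List[SpeciesAssignment]:
    return [_assign_on_tree(tree, qid, panel, support_threshold) for qid in query_ids]


@dataclass
class MiningReport:
    """Per-query assignments plus Table-1-style summary tabulations."""

    per_query: pd.DataFrame
    filtered: pd.DataFrame
    summaries: Dict[str, pd.DataFrame]
    n_retained: int
    tree: Optional[dendropy.Tree] = None

    def __post_init__(self) -> None:
        for name, table in self.summaries.items():
            if not table.empty and int(table["count"].sum()) != self.n_retained:
                raise ValueError(f"summary {name!r} counts do not sum to retained queries")


def _summarize(per_query: pd.DataFrame, by: str) -> pd.DataFrame:
    if per_query.empty:
        return pd.DataFrame(columns=["assigned_species", by, "count"])
    table = (
        per_query.groupby(["assigned_species", by], dropna=False)
        .size()
        .reset_index(name="count")
        .sort_values(["assigned_species", by])
        .reset_index(drop=True)
    )
    return table


def mine_candidates(
    candidates: Sequence[SequenceRecord],
    panel: ReferencePanel,
    marker_name: str = "rIGS-ID800",
    query_record: Optional[SequenceRecord] = None,
    min_coverage: float = 0.90,
    support_threshold: Optional[float] = None,
    bootstrap_replicates: int = 0,
    seed: Optional[int] = None,
    metadata: Optional[pd.DataFrame] = None,
    prealigned: bool = False,
) -> MiningReport:
    """Coverage-filter candidates, build the marker phylogeny, assign each
    survivor by clade and tabulate.

    ``query_record`` is the marker sequence used as the database search
    query; candidates covering < ``min_coverage`` of it (boundary
    inclusive) are excluded and listed in the filtered section.  Metadata
    (columns among: id, prior_label, geography, substrate) is an optional
    sidecar; summaries degrade gracefully when absent.
    """
    if query_record is None:
        typed = [r for r in panel.records
                 if panel.type_strain_flags.get(r.id) and r.id in panel.ingroup_ids]
        query_record = typed[0] if typed else panel.record(sorted(panel.ingroup_ids)[0])

    kept: List[Tuple[SequenceRecord, CoverageStats]] = []
    dropped: List[Tuple[SequenceRecord, CoverageStats]] = []
    for cand in candidates:
        stats = query_coverage(query_record, cand)
        (kept if stats.aligned_query_fraction >= min_coverage else dropped).append(
            (cand, stats)
        )

    filtered = pd.DataFrame(
        [
            {"query_id": c.id, "aligned_query_fraction": s.aligned_query_fraction,
             "identity_fraction": s.identity_fraction, "reason": "coverage_below_minimum"}
            for c, s in dropped
        ],
        columns=["query_id", "aligned_query_fraction", "identity_fraction", "reason"],
    )

    meta = metadata.set_index("id") if metadata is not None and "id" in metadata else None

    if not kept:
        empty = pd.DataFrame(columns=[
            "query_id", "assigned_species", "support", "aligned_query_fraction",
            "identity_fraction", "prior_label", "geography", "substrate", "marker",
        ])
        return MiningReport(empty, filtered, {}, 0, None)

    survivors = [c for c, _ in kept]
    all_records = list(panel.records) + survivors
    if prealigned or len({len(r) for r in all_records}) == 1:
        alignment = Alignment.from_equal_length_records(all_records)
    else:
        alignment = progressive_msa(all_records)
    tree, _ = build_assignment_tree(alignment, panel, bootstrap_replicates, seed)
    assignments = assign_all(tree, [c.id for c in survivors], panel, support_threshold)

    rows = []
    for (cand, stats), assign in zip(kept, assignments):
        md = meta.loc[cand.id] if meta is not None and cand.id in meta.index else {}
        rows.append({
            "query_id": cand.id,
            "assigned_species": assign.assigned_species,
            "support": assign.supporting_clade_support,
            "aligned_query_fraction": stats.aligned_query_fraction,
            "identity_fraction": stats.identity_fraction,
            "prior_label": dict(md).get("prior_label", ""),
            "geography": dict(md).get("geography", ""),
            "substrate": dict(md).get("substrate", ""),
            "marker": marker_name,
        })
    per_query = pd.DataFrame(rows)
    summaries = {
        "by_prior_label": _summarize(per_query, "prior_label"),
        "by_marker": _summarize(per_query, "marker"),
        "by_origin": _summarize(per_query, "geography"),
        "by_substrate": _summarize(per_query, "substrate"),
    }
    return MiningReport(per_query, filtered, summaries, len(kept), tree)


@dataclass
class ConcordanceRecord:
    specimen_id: str
    panel_call: str
    clade_call: str
    concordant: bool
    note: str = ""


def reconcile_panel_and_tree(panel_result, tree_assignment: SpeciesAssignment
                             ) -> ConcordanceRecord:
    """Cross-check the diagnostic-PCR call against the clade-based call.

    Discordance is never silently dropped; an ambiguous/indeterminate
    panel with a clade assignment reports the clade call as provisional.
    """
    panel_call = panel_result.call
    clade_call = tree_assignment.assigned_species
    specimen = panel_result.template_id
    if panel_call == clade_call and clade_call != UNASSIGNED:
        return ConcordanceRecord(specimen, panel_call, clade_call, True)
    if panel_call in ("ambiguous", "indeterminate") and clade_call != UNASSIGNED:
        return ConcordanceRecord(
            specimen, panel_call, clade_call, False,
            "panel inconclusive; clade call reported as provisional",
        )
    if clade_call == UNASSIGNED:
        return ConcordanceRecord(
            specimen, panel_call, clade_call, False,
            "clade analysis unassigned; panel call unconfirmed",
        )
    return ConcordanceRecord(
        specimen, panel_call, clade_call, False,
        "panel and clade calls disagree",
    )
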