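"""End-to-end orchestration: hits → annotation → taxonomy → ORF/domain
mining → GH5 candidate selection.

This is the discovery chain of the package run in one call, mainly for
round-trip validation against the synthetic-data truth tables and for
the command-line driver. Each stage is the public function of its
module; nothing here adds behaviour beyond wiring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import candidate_selection as cs
from .cazy_annotation import (
    CELLULASE_GH_FAMILIES,
    CazyAnnotation,
    HitRecord,
    annotate,
)
from .orf_mining import DomainHit, OrfRecord, find_orfs, screen_domains, tabulate_domains
from .taxonomy import TaxonAssignment, TaxonomyTree, lca_assign, phylum_summary


@dataclass
class PipelineResult:
    annotations: dict[str, CazyAnnotation]
    assignments: dict[str, TaxonAssignment]
    cellulase_unigenes: dict[str, set[str]]  # unigene -> cellulase families
    orfs: list[OrfRecord]
    domain_hits: list[DomainHit]
    domain_table: pd.DataFrame
    phylum_table: pd.DataFrame
    clusters: dict[str, list[str]] = field(default_factory=dict)
    unclustered: list[str] = field(default_factory=list)
    candidates: dict[str, list[str]] = field(default_factory=dict)

    def recovered_cellulase_orfs(self) -> set[tuple[str, str]]:
        """(unigene_id, CD family) pairs with a catalytic-domain hit on a
        ≥600-nt ORF of a cellulase-annotated unigene."""
        orf_owner = {o.orf_id: o.unigene_id for o in self.orfs}
        out = set()
        for hit in self.domain_hits:
            if hit.kind != "CD":
                continue
            unigene = orf_owner[hit.orf_id]
            if hit.family in self.cellulase_unigenes.get(unigene, ()):
                out.add((unigene, hit.family))
        return out


def genetic_code_for(assignment: TaxonAssignment | None, tree: TaxonomyTree) -> str:
    """Bacterial code for bacteria/archaea, standard otherwise."""
    if assignment is None or assignment.node is None:
        return "standard"
    sk = tree.ancestor_at_rank(assignment.node, "superkingdom")
    if sk is not None and tree.name[sk] in ("Bacteria", "Archaea"):
        return "bacterial"
    return "standard"


def run_pipeline(
    hits: list[HitRecord],
    unigenes: dict[str, str],
    tree: TaxonomyTree,
    min_orf_len: int = 600,
    gh5_cluster_threshold: float | None = None,
    per_cluster: int = 1,
    seed: int = 0,
) -> PipelineResult:
    """Run annotation → LCA → ORF mining → domain screen (→ selection).

    Only unigenes annotated to a cellulase-containing GH family are
    mined for ORFs, using the genetic code implied by their LCA
    superkingdom. If ``gh5_cluster_threshold`` is given and at least
    three GH5 catalytic-domain proteins were found, they are clustered
    on a neighbor-joining tree and candidates are drawn per stratum.
    """
    annotations = annotate(hits)
    assignments = lca_assign(hits, tree)
    cellulase_unigenes = {
        qid: set(ann.families) & CELLULASE_GH_FAMILIES
        for qid, ann in annotations.items()
        if set(ann.families) & CELLULASE_GH_FAMILIES
    }
    orfs: list[OrfRecord] = []
    for uid in sorted(cellulase_unigenes):
        if uid not in unigenes:
            continue
        code = genetic_code_for(assignments.get(uid), tree)
        orfs.extend(find_orfs(uid, unigenes[uid], min_len=min_orf_len, genetic_code=code))
    proteins = {o.orf_id: o.protein for o in orfs}
    domain_hits = screen_domains(proteins)
    result = PipelineResult(
        annotations=annotations,
        assignments=assignments,
        cellulase_unigenes=cellulase_unigenes,
        orfs=orfs,
        domain_hits=domain_hits,
        domain_table=tabulate_domains(domain_hits),
        phylum_table=phylum_summary(assignments, annotations),
    )
    if gh5_cluster_threshold is not None:
        gh5 = {
            h.orf_id: proteins[h.orf_id][h.aa_start : h.aa_end]
            for h in domain_hits
            if h.kind == "CD" and h.family == "GH5"
        }
        if len(gh5) >= 3:
            dist = cs.pairwise_distance(gh5)
            nj_tree = cs.build_nj_tree(dist)
            clusters, unclustered = cs.cluster_tree(nj_tree, gh5_cluster_threshold)
            result.clusters = clusters
            result.unclustered = unclustered
            result.candidates = cs.select_candidates(
                clusters, unclustered, per_cluster=per_cluster, seed=seed
            )
    return result


__all__ = ["PipelineResult", "run_pipeline", "genetic_code_for"]
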