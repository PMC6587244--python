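"""Lowest-common-ancestor taxonomy for unigenes.

Each unigene may hit references from several taxa; instead of trusting
the single best hit, the unigene is assigned to the deepest taxonomy
node ancestral to every contributing hit lineage (the MEGAN-style LCA
rule). Only hits with a bit score strictly above 50 and an alignment
longer than 25 nucleotides contribute; hits reported in amino-acid units
are converted at 3 nt per residue before the length test.

The taxonomy is an explicit rooted tree serialized as a two-column
parent→child edge list plus a node-metadata table (name, rank).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cazy_annotation import CazyAnnotation, HitRecord, cazy_class_of

logger = logging.getLogger(__name__)

#: Ordered ranks, root excluded, shallow → deep.
RANKS = (
    "superkingdom", "phylum", "class", "order", "family", "genus", "species",
)

UNCLASSIFIED = "unclassified"

DEFAULT_BITS_MIN = 50.0
DEFAULT_LEN_MIN = 25


@dataclass
class TaxonomyTree:
    """Rooted taxonomy with named, ranked nodes.

    ``parent`` maps child id → parent id (root absent); ``name`` and
    ``rank`` are per-node metadata. Node lookup by name assumes names are
    unique within the tree, which the edge-list format enforces here.
    """

    root: str
    parent: dict[str, str]
    name: dict[str, str]
    rank: dict[str, str]
    _by_name: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for node, par in self.parent.items():
            if par != self.root and par not in self.parent:
                raise ValueError(f"node {node!r} has unknown parent {par!r}")
        self._by_name = {self.name[n]: n for n in self.name}

    @classmethod
    def from_lineages(cls, lineages: Iterable[Sequence[str]], root: str = "root") -> "TaxonomyTree":
        """Build a tree from rank-ordered name paths (superkingdom→…)."""
        parent: dict[str, str] = {}
        name: dict[str, str] = {root: root}
        rank: dict[str, str] = {root: "root"}
        for lineage in lineages:
            prev = root
            for depth, taxon in enumerate(lineage):
                node = taxon  # names are ids; uniqueness enforced below
                if node in parent or node == root:
                    if node != root and parent[node] != prev:
                        raise ValueError(
                            f"taxon {taxon!r} appears under two parents "
                            f"({parent[node]!r} and {prev!r})"
                        )
                else:
                    parent[node] = prev
                    name[node] = taxon
                    rank[node] = RANKS[depth] if depth < len(RANKS) else f"rank{depth}"
                prev = node
        return cls(root=root, parent=parent, name=name, rank=rank)

    @classmethod
    def from_files(cls, edges_path: str | Path, nodes_path: str | Path) -> "TaxonomyTree":
        """Read the two-column edge list and the node metadata CSV."""
        edges = pd.read_csv(edges_path)
        nodes = pd.read_csv(nodes_path)
        parent = dict(zip(edges["child"].astype(str), edges["parent"].astype(str)))
        children = set(parent)
        roots = set(parent.values()) - children
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {sorted(roots)}")
        root = roots.pop()
        name = dict(zip(nodes["node"].astype(str), nodes["name"].astype(str)))
        rank = dict(zip(nodes["node"].astype(str), nodes["rank"].astype(str)))
        name.setdefault(root, root)
        rank.setdefault(root, "root")
        return cls(root=root, parent=parent, name=name, rank=rank)

    def to_files(self, edges_path: str | Path, nodes_path: str | Path) -> None:
        pd.DataFrame(
            sorted((c, p) for c, p in self.parent.items()),
            columns=["child", "parent"],
        ).to_csv(edges_path, index=False)
        pd.DataFrame(
            [
                {"node": n, "name": self.name[n], "rank": self.rank[n]}
                for n in sorted(list(self.parent) + [self.root])
            ],
            columns=["node", "name", "rank"],
        ).to_csv(nodes_path, index=False)

    def path_to_root(self, node: str) -> list[str]:
        """Node ids from ``node`` up to and including the root."""
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def resolve_lineage(self, lineage: Sequence[str]) -> str | None:
        """Deepest node matching a rank-ordered name path, or None."""
        node = None
        for taxon in reversed(lineage):
            node = self._by_name.get(taxon)
            if node is not None:
                return node
        return None

    def lca(self, nodes: Sequence[str]) -> str:
        """Lowest common ancestor of one or more node ids."""
        if not nodes:
            raise ValueError("lca of empty node set")
        common = set(self.path_to_root(nodes[0]))
        for node in nodes[1:]:
            common &= set(self.path_to_root(node))
        # deepest member of the common ancestor set lies on any path
        for anc in self.path_to_root(nodes[0]):
            if anc in common:
                return anc
        return self.root

    def ancestor_at_rank(self, node: str, target_rank: str) -> str | None:
        for anc in self.path_to_root(node):
            if self.rank.get(anc) == target_rank:
                return anc
        return None


@dataclass(frozen=True)
class TaxonAssignment:
    """LCA result for one query."""

    query_id: str
    node: str | None
    rank: str | None
    phylum: str  # phylum name or "unclassified"

    @property
    def assigned(self) -> bool:
        return self.node is not None


def lca_assign(
    hits: Iterable[HitRecord],
    tree: TaxonomyTree,
    bits_min: float = DEFAULT_BITS_MIN,
    len_min: int = DEFAULT_LEN_MIN,
) -> dict[str, TaxonAssignment]:
    """Assign each query the LCA of its contributing hit lineages.

    A hit contributes when bits > ``bits_min`` and its alignment spans
    more than ``len_min`` nucleotides (protein-unit hits converted ×3).
    Hits whose lineage resolves to no tree node are dropped with a
    warning. Queries with no contributing hits are returned unassigned.
    """
    per_query: dict[str, list[str]] = {}
    seen: list[str] = []
    for hit in hits:
        if hit.query_id not in per_query:
            per_query[hit.query_id] = []
            seen.append(hit.query_id)
        align_nt = hit.align_length if hit.subject_is_nt else hit.align_length * 3
        if not (hit.bits > bits_min and align_nt > len_min):
            continue
        node = tree.resolve_lineage(hit.subject_lineage)
        if node is None:
            logger.warning(
                "query %s: lineage %r not in taxonomy, hit dropped",
                hit.query_id, hit.subject_lineage,
            )
            continue
        per_query[hit.query_id].append(node)

    out: dict[str, TaxonAssignment] = {}
    for qid in seen:
        nodes = per_query[qid]
        if not nodes:
            out[qid] = TaxonAssignment(qid, None, None, UNCLASSIFIED)
            continue
        node = tree.lca(nodes)
        if node == tree.root:
            # no informative common ancestor below the root
            out[qid] = TaxonAssignment(qid, None, None, UNCLASSIFIED)
            continue
        phylum_node = tree.ancestor_at_rank(node, "phylum")
        phylum = tree.name[phylum_node] if phylum_node else UNCLASSIFIED
        out[qid] = TaxonAssignment(qid, node, tree.rank.get(node), phylum)
    return out


def phylum_summary(
    assignments: Mapping[str, TaxonAssignment],
    annotations: Mapping[str, CazyAnnotation],
) -> pd.DataFrame:
    """Cross-tabulate CAZyme classes against phyla.

    Counts CAZyme-annotated unigenes per (class, phylum); a unigene
    annotated to several classes contributes to each class row once.
    Queries without an assignment, or assigned above phylum, fall in the
    "unclassified" column.
    """
    rows = []
    for qid, ann in annotations.items():
        assignment = assignments.get(qid)
        phylum = assignment.phylum if assignment is not None else UNCLASSIFIED
        for cls in sorted({cazy_class_of(f) for f in ann.families}):
            rows.append({"cazy_class": cls, "phylum": phylum})
    if not rows:
        return pd.DataFrame(index=pd.Index([], name="cazy_class"))
    df = pd.DataFrame(rows)
    table = pd.crosstab(df["cazy_class"], df["phylum"])
    table.index.name = "cazy_class"
    return table


__all__ = [
    "TaxonomyTree", "TaxonAssignment", "RANKS", "UNCLASSIFIED",
    "lca_assign", "phylum_summary",
]
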