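"""Phylogeny-guided selection of GH5 cellulase candidates.

Catalytic-domain protein sequences are compared by global pairwise
alignment (BLOSUM62), converted to a distance of 1 − fractional identity
over aligned columns, and agglomerated into an unrooted tree by
neighbor joining. Clades whose internal leaf-to-leaf path lengths stay
below a height threshold become clusters; leaves in no such clade of
size ≥ 2 form the "unclustered" pool. Validation candidates are then a
stratified random sample across clusters plus the unclustered pool, and
each candidate gets an RT-PCR primer pair: ORF-terminal cores balanced
for melting temperature, with 22-nt vector-homology tails (pET-28a(+))
prepended verbatim for recombination cloning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .orf_mining import reverse_complement

logger = logging.getLogger(__name__)

#: 5' extensions homologous to the pET-28a(+) insertion site.
DEFAULT_TAIL_F = "GGCCATGGCTGATATCGGATCC"
DEFAULT_TAIL_R = "CTTGTCGACGGAGCTCGAATTC"

UNCLUSTERED = "unclustered"


@dataclass(frozen=True)
class PrimerPair:
    forward_core: str
    reverse_core: str
    tail_f: str
    tail_r: str
    tm_forward: float
    tm_reverse: float
    in_window: bool

    @property
    def forward(self) -> str:
        return self.tail_f + self.forward_core

    @property
    def reverse(self) -> str:
        return self.tail_r + self.reverse_core


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def pairwise_distance(proteins: Mapping[str, str]) -> DistanceMatrix:
    """Identity-based distance matrix from global pairwise alignments.

    distance = 1 − (identical columns / aligned columns), aligned
    columns counting gapped columns. Identical sequences get 0 and
    sequences sharing no residues approach 1.
    """
    labels = list(proteins)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    if any(not proteins[l] for l in labels):
        raise ValueError("empty sequence")
    aligner = _aligner()
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = proteins[labels[i]], proteins[labels[j]]
            if a == b:
                continue
            alignment = aligner.align(a, b)[0]
            sa, sb = str(alignment[0]), str(alignment[1])
            ident = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
            mat[i, j] = mat[j, i] = 1.0 - ident / len(sa)
    return DistanceMatrix(mat, ids=labels)


def build_nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Standard saitou–nei agglomeration (via scikit-bio); additive input
    distances are reproduced exactly by the tree's path lengths.
    Negative branch lengths that NJ can produce on noisy input are
    clamped to zero.
    """
    if dist.shape[0] < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    tree = nj(dist)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def _leaf_names(node: TreeNode) -> list[str]:
    return [t.name for t in node.tips()]


def _max_internal_path(node: TreeNode) -> float:
    """Largest leaf-to-leaf path length within the subtree of ``node``."""
    # bottom-up: track deepest leaf distance per child
    tips = list(node.tips())
    if len(tips) < 2:
        return 0.0
    best = 0.0
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            best = max(best, a.distance(b))
    return best


def cluster_tree(
    tree: TreeNode,
    height_threshold: float,
) -> tuple[dict[str, list[str]], list[str]]:
    """Cut the tree into tight monophyletic clusters.

    A cluster is a maximal clade (≥ 2 leaves) whose largest internal
    leaf-to-leaf path length is ≤ ``height_threshold``; every other
    leaf is returned in the unclustered pool. Each leaf appears exactly
    once across clusters and pool.
    """
    if height_threshold <= 0:
        raise ValueError("height_threshold must be positive")
    clusters: dict[str, list[str]] = {}
    unclustered: list[str] = []
    counter = 0

    def visit(node: TreeNode) -> None:
        nonlocal counter
        if node.is_tip():
            unclustered.append(node.name)
            return
        if _max_internal_path(node) <= height_threshold and node.count(tips=True) >= 2:
            counter += 1
            clusters[f"cluster_{counter}"] = sorted(_leaf_names(node))
            return
        for child in node.children:
            visit(child)

    visit(tree)
    return clusters, sorted(unclustered)


def select_candidates(
    clusters: Mapping[str, Sequence[str]],
    unclustered: Sequence[str],
    per_cluster: int = 1,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Stratified random sample: ``per_cluster`` members per stratum.

    Strata are each cluster plus the unclustered pool; a stratum smaller
    than ``per_cluster`` contributes all its members; empty strata are
    skipped with a warning. Deterministic for a fixed seed.
    """
    if per_cluster < 1:
        raise ValueError("per_cluster must be ≥ 1")
    rng = np.random.default_rng(seed)
    strata = dict(clusters)
    if unclustered:
        strata[UNCLUSTERED] = list(unclustered)
    picked: dict[str, list[str]] = {}
    for name in sorted(strata):
        members = sorted(strata[name])
        if not members:
            logger.warning("stratum %s is empty, skipped", name)
            continue
        if len(members) <= per_cluster:
            picked[name] = members
        else:
            idx = rng.choice(len(members), size=per_cluster, replace=False)
            picked[name] = sorted(members[i] for i in sorted(idx))
    return picked


def melting_temperature(core: str, method: str = "auto") -> float:
    """Primer-core Tm in °C.

    ``method`` is "wallace" (2·AT + 4·GC), "gc" (64.9 + 41·(GC −
    16.4)/N) or "auto", which applies the Wallace rule for cores ≤ 14
    nt and the GC formula above that. Tails are excluded from Tm by the
    caller.
    """
    seq = core.upper()
    n = len(seq)
    if n == 0:
        raise ValueError("empty primer core")
    gc = sum(1 for b in seq if b in "GC")
    at = n - gc
    if method == "wallace" or (method == "auto" and n <= 14):
        return 2.0 * at + 4.0 * gc
    if method in ("gc", "auto"):
        return 64.9 + 41.0 * (gc - 16.4) / n
    raise ValueError(f"unknown Tm method {method!r}")


def design_primers(
    orf_nt: str,
    tail_f: str = DEFAULT_TAIL_F,
    tail_r: str = DEFAULT_TAIL_R,
    core_len_range: tuple[int, int] = (18, 28),
    tm_window: float = 3.0,
) -> PrimerPair:
    """Design a tailed RT-PCR primer pair for one full-length ORF.

    The forward core is the ORF's 5' terminus and the reverse core the
    reverse complement of its 3' terminus; core lengths are chosen
    within ``core_len_range`` to minimise |Tm_f − Tm_r|. If no pair
    falls within ``tm_window`` the best-effort pair is returned flagged
    ``in_window=False``.
    """
    lo, hi = core_len_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid core length range")
    if len(orf_nt) < 2 * lo:
        raise ValueError("ORF shorter than twice the minimum core length")
    seq = orf_nt.upper()
    hi = min(hi, len(seq) // 2)
    best: tuple[float, int, int] | None = None
    for lf in range(lo, hi + 1):
        tm_f = melting_temperature(seq[:lf])
        for lr in range(lo, hi + 1):
            tm_r = melting_temperature(reverse_complement(seq[-lr:]))
            gap = abs(tm_f - tm_r)
            if best is None or gap < best[0]:
                best = (gap, lf, lr)
    gap, lf, lr = best
    fwd = seq[:lf]
    rev = reverse_complement(seq[-lr:])
    return PrimerPair(
        forward_core=fwd,
        reverse_core=rev,
        tail_f=tail_f,
        tail_r=tail_r,
        tm_forward=melting_temperature(fwd),
        tm_reverse=melting_temperature(rev),
        in_window=gap <= tm_window,
    )


__all__ = [
    "PrimerPair", "DEFAULT_TAIL_F", "DEFAULT_TAIL_R", "UNCLUSTERED",
    "pairwise_distance", "build_nj_tree", "cluster_tree",
    "select_candidates", "melting_temperature", "design_primers",
]
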