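"""Distances, neighbor joining on additive matrices, tree cutting,
stratified selection and tailed primer design."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix

from cazymine import candidate_selection as cs
from cazymine import synthetic_data as sd
from cazymine.orf_mining import reverse_complement


class TestPairwiseDistance:
    def test_identical_sequences_distance_zero(self):
        d = cs.pairwise_distance({"a": "MKLVINS", "b": "MKLVINS", "c": "MKLVWNS"})
        assert d["a", "b"] == 0.0
        assert d["a", "c"] > 0.0

    def test_disjoint_alphabets_distance_one(self):
        d = cs.pairwise_distance({"a": "AAAAAAAA", "b": "WWWWWWWW"})
        assert d["a", "b"] == pytest.approx(1.0)

    def test_gapless_case_matches_hand_computed_identity(self):
        # equal-length, high-identity pairs align without gaps under
        # BLOSUM62 with affine penalties, so distance = mismatches / length
        seqs = {
            "s1": "MKLVINSGHEMKLVINSGHE",
            "s2": "MKLVINSGHEMKLVINSGHQ",  # 1 mismatch / 20
            "s3": "MKLVANSGHEMKLVINSGWE",  # 2 vs s1
            "s4": "MKLVINSGHEMKLVINSGHE",  # identical to s1
            "s5": "MELVINSGHEMKLVANSGHE",  # 2 vs s1
        }
        d = cs.pairwise_distance(seqs)
        assert d["s1", "s2"] == pytest.approx(1 / 20)
        assert d["s1", "s3"] == pytest.approx(2 / 20)
        assert d["s1", "s4"] == 0.0
        assert d["s1", "s5"] == pytest.approx(2 / 20)

    def test_duplicate_or_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            cs.pairwise_distance({"a": "MK"})
        with pytest.raises(ValueError):
            cs.pairwise_distance({"a": "MK", "b": ""})


def additive_matrix_from_tree(branch: dict[str, float], pairs: dict[tuple[str, str], list[str]]):
    """Tip-to-tip distances as sums of branch lengths along known paths."""
    labels = sorted({t for pair in pairs for t in pair})
    n = len(labels)
    mat = np.zeros((n, n))
    for (a, b), path in pairs.items():
        d = sum(branch[e] for e in path)
        i, j = labels.index(a), labels.index(b)
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=labels)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree: ((A:1,B:2):1.5,(C:3,D:4)) — internal edge 1.5
        branch = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "I": 1.5}
        pairs = {
            ("A", "B"): ["A", "B"],
            ("A", "C"): ["A", "I", "C"],
            ("A", "D"): ["A", "I", "D"],
            ("B", "C"): ["B", "I", "C"],
            ("B", "D"): ["B", "I", "D"],
            ("C", "D"): ["C", "D"],
        }
        dm = additive_matrix_from_tree(branch, pairs)
        tree = cs.build_nj_tree(dm)
        dists = tree.tip_tip_distances()
        for a, b in itertools.combinations("ABCD", 2):
            assert dists[a, b] == pytest.approx(dm[a, b], abs=1e-9)
        # topology: A and B are sisters (their path avoids the internal edge)
        lca = tree.lowest_common_ancestor(["A", "B"])
        assert {t.name for t in lca.tips()} <= {"A", "B", "C", "D"}
        assert dists["A", "B"] < dists["A", "C"]

    @pytest.mark.parametrize("n_taxa", [5, 6, 8])
    def test_random_additive_matrices_recovered(self, n_taxa):
        # build a random binary tree by successive tip attachment, then
        # derive its exact path-length matrix as the oracle input
        rng = np.random.default_rng(n_taxa)
        from skbio import TreeNode

        labels = [f"t{i}" for i in range(n_taxa)]
        newick = f"({labels[0]}:1,{labels[1]}:1);"
        tree = TreeNode.read([newick])
        for label in labels[2:]:
            tips = list(tree.tips())
            host = tips[int(rng.integers(len(tips)))]
            # split host edge, hang the new tip off the midpoint
            half = host.length / 2
            new_internal = TreeNode(length=half)
            new_tip = TreeNode(name=label, length=float(rng.uniform(0.5, 2.0)))
            parent = host.parent
            parent.remove(host)
            host.length = half
            new_internal.append(host)
            new_internal.append(new_tip)
            parent.append(new_internal)
        dists = tree.tip_tip_distances()
        dm = DistanceMatrix(dists.data, ids=[str(i) for i in dists.ids])
        recovered = cs.build_nj_tree(dm).tip_tip_distances()
        for a, b in itertools.combinations(labels, 2):
            assert recovered[a, b] == pytest.approx(dm[a, b], abs=1e-9)

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=["A", "B", "C"]
        )
        tree = cs.build_nj_tree(dm)
        d = tree.tip_tip_distances()
        # a=(dAB+dAC−dBC)/2=1, b=2, c=3
        assert d["A", "B"] == pytest.approx(3.0)
        assert d["A", "C"] == pytest.approx(4.0)
        assert d["B", "C"] == pytest.approx(5.0)

    def test_label_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(0.2, 1.0, size=(5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        ids = ["a", "b", "c", "d", "e"]
        perm = [3, 1, 4, 0, 2]
        d1 = cs.build_nj_tree(DistanceMatrix(m, ids=ids)).tip_tip_distances()
        d2 = cs.build_nj_tree(
            DistanceMatrix(m[np.ix_(perm, perm)], ids=[ids[i] for i in perm])
        ).tip_tip_distances()
        for a, b in itertools.combinations(ids, 2):
            assert d1[a, b] == pytest.approx(d2[a, b], abs=1e-9)

    def test_too_few_taxa_and_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            cs.build_nj_tree(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))
        from skbio.stats.distance import DistanceMatrixError

        with pytest.raises(DistanceMatrixError):
            DistanceMatrix([[0, 1, 2], [0.5, 0, 1], [2, 1, 0]], ids=list("abc"))


class TestClusterTree:
    @pytest.fixture()
    def planted(self):
        seqs, truth = sd.generate_protein_clusters(
            n_clusters=8, per_cluster=4, n_singletons=3, seed=44
        )
        tree = cs.build_nj_tree(cs.pairwise_distance(seqs))
        return seqs, truth, tree

    def test_threshold_above_diameter_gives_one_cluster(self, planted):
        seqs, _, tree = planted
        clusters, unclustered = cs.cluster_tree(tree, height_threshold=1e6)
        assert len(clusters) == 1
        assert not unclustered
        assert sorted(next(iter(clusters.values()))) == sorted(seqs)

    def test_tiny_threshold_unclusters_everything(self, planted):
        seqs, _, tree = planted
        clusters, unclustered = cs.cluster_tree(tree, height_threshold=1e-9)
        assert not clusters
        assert sorted(unclustered) == sorted(seqs)

    def test_planted_eight_clusters_recovered(self, planted):
        _, truth, tree = planted
        clusters, unclustered = cs.cluster_tree(tree, height_threshold=0.3)
        assert len(clusters) == 8
        expected = {}
        for label, c in truth.items():
            if c != "unclustered":
                expected.setdefault(c, set()).add(label)
        assert {frozenset(v) for v in clusters.values()} == {
            frozenset(v) for v in expected.values()
        }
        assert set(unclustered) == {l for l, c in truth.items() if c == "unclustered"}

    def test_every_leaf_appears_exactly_once(self, planted):
        seqs, _, tree = planted
        clusters, unclustered = cs.cluster_tree(tree, height_threshold=0.3)
        seen = list(unclustered) + [m for v in clusters.values() for m in v]
        assert sorted(seen) == sorted(seqs)

    def test_nonpositive_threshold_rejected(self, planted):
        _, _, tree = planted
        with pytest.raises(ValueError):
            cs.cluster_tree(tree, 0.0)


class TestSelectCandidates:
    CLUSTERS = {"c1": ["x", "y", "z"], "c2": ["p", "q"]}

    def test_every_stratum_represented(self):
        picked = cs.select_candidates(self.CLUSTERS, ["lone"], per_cluster=1, seed=3)
        assert set(picked) == {"c1", "c2", cs.UNCLUSTERED}
        assert all(len(v) == 1 for v in picked.values())

    def test_oversized_request_takes_whole_cluster(self):
        picked = cs.select_candidates(self.CLUSTERS, [], per_cluster=5, seed=3)
        assert picked["c2"] == ["p", "q"]

    def test_fixed_seed_reproducibility_and_membership(self):
        a = cs.select_candidates(self.CLUSTERS, ["lone"], per_cluster=2, seed=9)
        b = cs.select_candidates(self.CLUSTERS, ["lone"], per_cluster=2, seed=9)
        assert a == b
        for stratum, members in a.items():
            pool = self.CLUSTERS.get(stratum, ["lone"])
            assert set(members) <= set(pool)


class TestDesignPrimers:
    ORF = (
        "ATGGCTAAAGGTGAACTGGTTAAAGATCCGGAAGCTCTGGCTGAAGCTGCTAAAGCTGGT"
        "GAACTGGTTAAAGATCCGGAAGCTCTGGCTGAAGCTGCTAAAGCTGGTGGTTCTTAA"
    )

    def test_tails_prepended_verbatim(self):
        pair = cs.design_primers(self.ORF)
        assert pair.forward.startswith("GGCCATGGCTGATATCGGATCC")
        assert pair.reverse.startswith("CTTGTCGACGGAGCTCGAATTC")

    def test_cores_reconstruct_orf_termini(self):
        pair = cs.design_primers(self.ORF)
        f = pair.forward[len(pair.tail_f):]
        r = pair.reverse[len(pair.tail_r):]
        assert self.ORF.startswith(f)
        assert self.ORF.endswith(reverse_complement(r))

    def test_wallace_rule_formula(self):
        core = "AT" * 5 + "GC" * 5  # 10 A/T + 10 G/C
        assert cs.melting_temperature(core, method="wallace") == 60.0
        assert cs.melting_temperature("ATGCATGCAT") == 2 * 6 + 4 * 4  # ≤14 nt: auto=Wallace

    def test_tm_window_flag_when_unreachable(self):
        orf = "AT" * 40 + "GC" * 40  # AT-rich 5', GC-rich 3'
        pair = cs.design_primers(orf, tm_window=0.5)
        assert not pair.in_window

    def test_short_orf_rejected(self):
        with pytest.raises(ValueError):
            cs.design_primers("ATGAAATTT")
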