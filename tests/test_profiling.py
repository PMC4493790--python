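"""Band-ladder encoding, Nei-Li distance, UPGMA and bootstrap support."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import bruteforce_upgma_heights
from tedose.errors import ConfigurationError, MalformedInputError, UndefinedDistanceError
from tedose.profiling import (
    MarkerProfile,
    Node,
    bootstrap_support,
    distance_matrix,
    encode_profile,
    nei_li_distance,
    profiles_from_calls,
    to_newick,
    upgma,
)


def profile(sample, scores, loci=None):
    loci = tuple(loci or [f"L{i}" for i in range(len(scores))])
    return MarkerProfile(sample, loci, dict(zip(loci, scores)))


class TestEncoding:
    def test_full_score_all_ones(self):
        enc = encode_profile(profile("s", [10.0]), bin_width=1)
        assert enc.blocks[0] == (1,) * 10

    def test_zero_score_all_zeros(self):
        enc = encode_profile(profile("s", [0.0]), bin_width=1)
        assert enc.blocks[0] == (0,) * 10

    def test_band_ladder_with_bin_width_two(self):
        enc = encode_profile(profile("s", [6.0]), bin_width=2)
        assert enc.blocks[0] == (1, 1, 1, 0, 0)

    def test_missing_locus_zero_block_flagged(self):
        enc = encode_profile(profile("s", [5.0, None]))
        assert enc.blocks[1] == (0,) * 10
        assert enc.present == (True, False)

    @pytest.mark.parametrize("bad", [3.0, 0.0, 11.0, -1.0])
    def test_bin_width_must_divide_ten(self, bad):
        with pytest.raises(ConfigurationError):
            encode_profile(profile("s", [5.0]), bin_width=bad)


class TestNeiLi:
    def test_identical_vectors(self):
        assert nei_li_distance(np.array([1, 1, 0]), np.array([1, 1, 0])) == 0.0

    def test_disjoint_vectors(self):
        assert nei_li_distance(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 1.0

    def test_hand_computed_dice(self):
        d = nei_li_distance(np.array([1, 1, 1, 0]), np.array([1, 1, 0, 0]))
        assert d == pytest.approx(0.2)

    def test_both_all_zero_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            nei_li_distance(np.zeros(4, int), np.zeros(4, int))

    def test_missing_loci_excluded_pairwise(self):
        a = encode_profile(profile("a", [6.0, None]))
        b = encode_profile(profile("b", [6.0, 3.0]))
        assert nei_li_distance(a, b) == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=40))
    def test_symmetry_and_identity(self, bits):
        a = np.array([x for x, _ in bits])
        b = np.array([y for _, y in bits])
        if a.sum() + b.sum() == 0:
            return
        assert nei_li_distance(a, b) == nei_li_distance(b, a)
        if a.sum() > 0:
            assert nei_li_distance(a, a) == 0.0


class TestUpgma:
    def test_three_sample_hand_computation(self):
        d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        tree = upgma(d, ["A", "B", "C"])
        assert tree.height == pytest.approx(0.3)
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert inner.height == pytest.approx(0.1)
        assert inner.leaves() == frozenset({"A", "B"})

    def test_equal_distances_tie_break_by_index(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        tree = upgma(d, list("ABCD"))
        heights = sorted(n.height for n in tree.internal_nodes())
        assert heights == pytest.approx([0.25, 0.25, 0.25])
        # first merge takes the lowest index pair (A, B)
        clades = {n.leaves() for n in tree.internal_nodes()}
        assert frozenset({"A", "B"}) in clades

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_from_scratch_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        x = rng.random((n, 5))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        tree = upgma(d, [f"s{i}" for i in range(n)])
        mine = sorted(node.height for node in tree.internal_nodes())
        oracle = sorted(bruteforce_upgma_heights(d))
        assert mine == pytest.approx(oracle)

    def test_matches_scipy_average_linkage(self):
        scipy_hier = pytest.importorskip("scipy.cluster.hierarchy")
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(99)
        x = rng.random((7, 4))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        tree = upgma(d, [f"s{i}" for i in range(7)])
        mine = sorted(2 * node.height for node in tree.internal_nodes())
        z = scipy_hier.linkage(squareform(d, checks=False), method="average")
        assert mine == pytest.approx(sorted(z[:, 2]))

    def test_ultrametric_and_monotone(self):
        rng = np.random.default_rng(5)
        x = rng.random((6, 3))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        tree = upgma(d, list("ABCDEF"))

        def depths(node, acc=0.0):
            if node.is_leaf:
                return [acc + node.height]
            assert all(c.height <= node.height for c in node.children)
            return [x for c in node.children for x in depths(c)]

        root_to_leaf = [tree.height - h for h in depths(tree)]
        assert np.allclose(root_to_leaf, tree.height)

    def test_leaf_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(3)
        x = rng.random((6, 3))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        labels = list("ABCDEF")
        perm = rng.permutation(6)
        tree1 = upgma(d, labels)
        tree2 = upgma(d[np.ix_(perm, perm)], [labels[i] for i in perm])
        clades1 = {(n.leaves(), round(n.height, 12)) for n in tree1.internal_nodes()}
        clades2 = {(n.leaves(), round(n.height, 12)) for n in tree2.internal_nodes()}
        assert clades1 == clades2

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(MalformedInputError):
            upgma(np.array([[0.0, 1.0], [0.5, 0.0]]), ["a", "b"])


class TestBootstrap:
    def test_duplicated_locus_information_gives_full_support(self):
        scores = {"a": (2.0, 2.0), "b": (5.0, 5.0), "c": (9.0, 9.0), "d": (9.5, 9.5)}
        profs = [profile(s, list(v), loci=("L0", "L1")) for s, v in scores.items()]
        tree = bootstrap_support(profs, n_replicates=100, seed=1)
        sups = [n.support for n in tree.internal_nodes() if n.support is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_single_replicate_support_is_zero_or_hundred(self):
        rng = np.random.default_rng(2)
        profs = [profile(f"s{i}", rng.uniform(0, 10, 3)) for i in range(6)]
        tree = bootstrap_support(profs, n_replicates=1, seed=3)
        sups = [n.support for n in tree.internal_nodes() if n.support is not None]
        assert set(sups) <= {0.0, 100.0}

    def test_single_locus_support_absent(self):
        profs = [profile(f"s{i}", [float(i + 1)]) for i in range(4)]
        tree = bootstrap_support(profs, n_replicates=10, seed=0)
        assert all(n.support is None for n in tree.internal_nodes())

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        profs = [profile(f"s{i}", rng.uniform(0, 10, 4)) for i in range(5)]
        t1 = bootstrap_support(profs, 50, seed=9)
        t2 = bootstrap_support(profs, 50, seed=9)
        assert to_newick(t1) == to_newick(t2)


class TestNewickAndProfiles:
    def test_newick_parses_and_is_ultrametric(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(4)
        profs = [profile(f"s{i}", rng.uniform(0, 10, 3)) for i in range(5)]
        tree = bootstrap_support(profs, 20, seed=4)
        t = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        depths = [leaf.distance_from_root() for leaf in t.leaf_node_iter()]
        assert np.allclose(depths, depths[0], atol=1e-6)

    def test_profiles_from_calls_missing_statuses(self):
        from tedose.dosage import CallStatus, DosageCall

        calls = [
            DosageCall("s1", "L1", 1.0, 5.0, 5.0, 2.0, CallStatus.OK),
            DosageCall("s1", "L2", None, None, None, float("nan"), CallStatus.INCONCLUSIVE),
            DosageCall("s2", "L1", None, 10.0, 0.0, 2.0, CallStatus.PRESENCE_ONLY),
            DosageCall("s2", "L2", 4.0, 8.0, 2.0, 2.0, CallStatus.OK),
        ]
        profs = profiles_from_calls(calls)
        assert [p.sample_id for p in profs] == ["s1", "s2"]
        assert profs[0].scores["L2"] is None
        assert profs[1].scores["L1"] == 10.0


def test_replicate_profiles_cluster_tightly():
    """Noisy re-runs of the same sample sit at tiny Nei-Li distances.

    Two independently simulated plates of the same three-locus sample
    (Ct noise sd 0.15) are profiled and encoded at bin width 1; the
    distance must stay below 0.05 in at least 95% of simulations (pairs
    where the QC flagged every locus are excluded, as they would be re-run).
    """
    from tedose.profiling import nei_li_distance
    from tedose.synth import PlateScenario, score_plate, simulate_plate

    loci = {"L1": 4.5, "L2": 2.4, "L3": 7.3}
    close = total = 0
    for i in range(200):
        encs = []
        for rep in range(2):
            scn = PlateScenario(samples=(("s", loci),), seed=10_000 + 2 * i + rep)
            calls = score_plate(simulate_plate(scn))
            prof = profiles_from_calls(calls)[0]
            encs.append(encode_profile(prof, bin_width=1))
        try:
            d = nei_li_distance(*encs)
        except UndefinedDistanceError:
            continue
        total += 1
        close += d < 0.05
    assert total > 100
    assert close / total >= 0.95
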