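"""Pairwise identity, threshold clustering, rank placement and NJ trees."""

import itertools

import numpy as np
import pytest

from prospector.demarcation import (
    IdentityMatrix,
    RankDistributions,
    cluster_species,
    global_identity,
    identity_matrix,
    nj_tree,
    nj_tree_from_distances,
    place_rank,
)
from prospector.synthetic_data import RDRP_SEED_A, mutate_protein, random_protein


def test_identical_sequences_are_100_percent():
    assert global_identity("MKLVWD" * 10, "MKLVWD" * 10) == 100.0


def test_hand_aligned_single_substitution():
    # No-gap alignment is optimal: 5 of 6 columns identical.
    assert global_identity("ACDEFG", "ACDKFG") == pytest.approx(83.33, abs=0.01)


def test_identity_is_symmetric(rng):
    for _ in range(25):
        a = random_protein(rng, int(rng.integers(10, 60)))
        b = random_protein(rng, int(rng.integers(10, 60)))
        assert global_identity(a, b) == pytest.approx(global_identity(b, a))


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        global_identity("", "MKL")


def test_matrix_invariants_and_order_permutation(rng):
    seqs = [(f"s{i}", mutate_protein(RDRP_SEED_A, 100 - 10 * i, seed=i)) for i in range(4)]
    m = identity_matrix(seqs)
    assert np.allclose(m.values, m.values.T, atol=1e-9)
    assert np.allclose(np.diag(m.values), 100.0)
    assert (m.values >= 0).all() and (m.values <= 100).all()
    perm = [2, 0, 3, 1]
    m2 = identity_matrix([seqs[i] for i in perm])
    for i, j in itertools.product(range(4), repeat=2):
        assert m2.values[i, j] == pytest.approx(m.values[perm[i], perm[j]])


def test_divergence_series_recovered_within_tolerance():
    targets = [90.0, 70.0, 50.0]
    seqs = [("seed", RDRP_SEED_A)] + [
        (f"m{t:g}", mutate_protein(RDRP_SEED_A, t, seed=int(t))) for t in targets
    ]
    m = identity_matrix(seqs)
    for t in targets:
        assert m.pair("seed", f"m{t:g}") == pytest.approx(t, abs=3.0)


def matrix_from_pairs(labels, pairs):
    n = len(labels)
    values = np.full((n, n), 0.0)
    np.fill_diagonal(values, 100.0)
    idx = {lab: i for i, lab in enumerate(labels)}
    for (a, b), v in pairs.items():
        values[idx[a], idx[b]] = values[idx[b], idx[a]] = v
    return IdentityMatrix(labels=list(labels), values=values)


def test_single_linkage_definition():
    m = matrix_from_pairs("abc", {("a", "b"): 95, ("a", "c"): 40, ("b", "c"): 40})
    assert cluster_species(m, 90) == [["a", "b"], ["c"]]


def test_threshold_100_gives_singletons():
    m = matrix_from_pairs("abcd", {(a, b): 70 for a, b in itertools.combinations("abcd", 2)})
    assert cluster_species(m, 100) == [["a"], ["b"], ["c"], ["d"]]


def test_transitive_linking():
    # a-b and b-c linked, a-c not: single linkage still merges all three.
    m = matrix_from_pairs("abc", {("a", "b"): 92, ("b", "c"): 91, ("a", "c"): 30})
    assert cluster_species(m, 90) == [["a", "b", "c"]]


def test_threshold_monotonicity(rng):
    labels = "abcdef"
    pairs = {
        (a, b): float(rng.uniform(10, 100))
        for a, b in itertools.combinations(labels, 2)
    }
    m = matrix_from_pairs(labels, pairs)
    previous = None
    for threshold in (30, 50, 70, 90, 100):
        clusters = cluster_species(m, threshold)
        if previous is not None:
            assert len(clusters) >= len(previous)
            # raising the threshold only splits, never merges
            for cluster in clusters:
                assert any(set(cluster) <= set(old) for old in previous)
        previous = clusters


def test_seven_distinct_narna_like_species_at_50_percent():
    """Seven RdRps pairwise below 50% identity each become a species."""
    seqs = [(f"mito_{i}", mutate_protein(RDRP_SEED_A, 30, seed=1000 + i)) for i in range(7)]
    m = identity_matrix(seqs)
    off_diag = m.values[~np.eye(7, dtype=bool)]
    assert (off_diag < 50).all()
    assert len(cluster_species(m, 50)) == 7


def test_rank_placement_rules():
    dists = RankDistributions(
        intra_genus=[60, 65, 70, 75, 80], inter_genus=[20, 25, 30, 35]
    )
    verdict, summary = place_rank([70.0], dists)
    assert verdict == "existing_taxon"
    verdict, _ = place_rank([28.0], dists)
    assert verdict == "new_genus_candidate"
    # Below every inter-genus sample too
    verdict, _ = place_rank([10.0], dists)
    assert verdict == "new_genus_candidate"
    assert summary["intra_genus"]["min"] == 60


def test_rank_placement_new_species_band():
    dists = RankDistributions(intra_genus=[60, 70, 80], inter_genus=[20, 30])
    verdict, _ = place_rank([61.0], dists)
    assert verdict == "existing_taxon"
    verdict, _ = place_rank([60.5], dists)  # above min intra, below the 5% quantile
    assert verdict == "new_species"


def test_rank_distributions_must_be_nonempty():
    with pytest.raises(ValueError):
        RankDistributions(intra_genus=[], inter_genus=[10])


def tree_path_lengths(newick, labels):
    import io

    from Bio import Phylo

    tree = Phylo.read(io.StringIO(newick), "newick")
    out = {}
    for a, b in itertools.combinations(labels, 2):
        out[(a, b)] = tree.distance(a, b)
    return out


def test_nj_recovers_additive_four_taxon_tree():
    # Tree: (a:2,b:3):3 joined to (c:4,d:5); internal edge 3.
    labels = ["a", "b", "c", "d"]
    d = np.array(
        [
            [0, 5, 9, 10],
            [5, 0, 10, 11],
            [9, 10, 0, 9],
            [10, 11, 9, 0],
        ],
        dtype=float,
    )
    newick = nj_tree_from_distances(labels, d)
    paths = tree_path_lengths(newick, labels)
    for (a, b), expect in {
        ("a", "b"): 5, ("a", "c"): 9, ("a", "d"): 10,
        ("b", "c"): 10, ("b", "d"): 11, ("c", "d"): 9,
    }.items():
        assert paths[(a, b)] == pytest.approx(expect, abs=1e-6)


def test_nj_three_taxa_solves_three_point_formulas():
    labels = ["x", "y", "z"]
    d = np.array([[0, 7, 9], [7, 0, 10], [9, 10, 0]], dtype=float)
    newick = nj_tree_from_distances(labels, d)
    paths = tree_path_lengths(newick, labels)
    assert paths[("x", "y")] == pytest.approx(7, abs=1e-6)
    assert paths[("x", "z")] == pytest.approx(9, abs=1e-6)
    assert paths[("y", "z")] == pytest.approx(10, abs=1e-6)


def test_identical_sequences_give_zero_length_tree():
    seqs = [(f"s{i}", "MKWLVD" * 20) for i in range(3)]
    m = identity_matrix(seqs)
    newick = nj_tree(m)
    paths = tree_path_lengths(newick, [lab for lab, _ in seqs])
    assert all(abs(v) < 1e-9 for v in paths.values())


def test_nj_requires_three_taxa():
    m = matrix_from_pairs("ab", {("a", "b"): 50})
    with pytest.raises(ValueError):
        nj_tree(m)
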