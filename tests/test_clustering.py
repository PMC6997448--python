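"""Motif distances, hierarchical clustering and Jaccard set distances."""

import itertools

import numpy as np
import pytest

from methmotif import (
    hierarchical_cluster,
    jaccard_distance,
    linkage_to_newick,
    motif_distance,
    motif_distance_matrix,
)
from methmotif.clustering import MotifDistanceMatrix
from methmotif.motif import IUPAC_SETS, Motif


def distance_oracle(a: Motif, b: Motif, min_overlap: int = 3) -> float:
    """Exhaustive-offset re-implementation used as the independent oracle."""
    best = 0.0
    for offset in range(-len(a) + 1, len(b)):
        cols = []
        for i in range(len(a)):
            j = i + offset
            if 0 <= j < len(b):
                sa, sb = a.position_sets[i], b.position_sets[j]
                cols.append(len(sa & sb) / len(sa | sb))
        if len(cols) >= min_overlap:
            best = max(best, sum(cols) / max(len(a), len(b)))
    return 1.0 - best


def test_identical_motifs_at_distance_zero():
    m = Motif.from_consensus("TGACTCA")
    assert motif_distance(m, m) == 0.0


def test_one_ambiguity_distance_via_oracle():
    # AP-1 consensus vs its one-position M = {A,C} variant
    a = Motif.from_consensus("TGACTCA")
    b = Motif.from_consensus("TGACTMA")
    expected = distance_oracle(a, b)
    assert expected == pytest.approx(1 - 6.5 / 7)
    assert motif_distance(a, b) == pytest.approx(expected, abs=1e-12)


def test_disjoint_alphabet_motifs_at_distance_one():
    a = Motif.from_consensus("AAAA")
    b = Motif.from_consensus("CCCC")
    assert motif_distance(a, b) == 1.0


def test_no_offset_reaching_min_overlap_gives_distance_one():
    a = Motif.from_consensus("ACG")
    b = Motif.from_consensus("ACG")
    assert motif_distance(a, b, min_overlap=4) == 1.0


def test_distance_properties_on_random_pairs():
    rng = np.random.default_rng(13)
    letters = sorted(IUPAC_SETS)
    motifs = [
        Motif.from_consensus(
            "".join(rng.choice(letters, size=rng.integers(3, 9)))
        )
        for _ in range(60)
    ]
    for _ in range(400):
        a, b = rng.choice(len(motifs), size=2)
        d_ab = motif_distance(motifs[a], motifs[b])
        assert 0.0 <= d_ab <= 1.0
        assert d_ab == pytest.approx(motif_distance(motifs[b], motifs[a]), abs=1e-12)
        assert d_ab == pytest.approx(
            distance_oracle(motifs[a], motifs[b]), abs=1e-12
        )


def test_shared_flank_does_not_increase_distance():
    a = Motif.from_consensus("TGACT")
    b = Motif.from_consensus("TGAMT")
    base = motif_distance(a, b)
    fa = Motif.from_consensus("CG" + a.consensus)
    fb = Motif.from_consensus("CG" + b.consensus)
    assert motif_distance(fa, fb) <= base + 1e-12


def test_clustering_separates_identical_from_distant():
    dm = MotifDistanceMatrix(
        labels=["a", "b", "c"],
        values=np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float),
    )
    for cut in (0.1, 0.5, 0.9):
        assignment, _ = hierarchical_cluster(dm, cut_height=cut)
        assert assignment[0] == assignment[1] != assignment[2]
        assert len(set(assignment)) == 2


def test_all_zero_distances_form_one_cluster():
    dm = MotifDistanceMatrix(labels=list("abcd"), values=np.zeros((4, 4)))
    assignment, _ = hierarchical_cluster(dm, cut_height=0.5)
    assert len(set(assignment)) == 1


def naive_average_linkage(d: np.ndarray):
    """O(n^3) agglomeration oracle returning merge heights."""
    clusters = {i: [i] for i in range(len(d))}
    heights = []
    next_id = len(d)
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            dij = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
            if best is None or dij < best[0] - 1e-12:
                best = (dij, i, j)
        dij, i, j = best
        heights.append(dij)
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return heights


def test_linkage_agrees_with_naive_agglomeration_oracle():
    rng = np.random.default_rng(21)
    letters = sorted(IUPAC_SETS)
    motifs = [
        Motif.from_consensus("".join(rng.choice(letters, size=6))) for _ in range(8)
    ]
    dm = motif_distance_matrix(motifs)
    _, Z = hierarchical_cluster(dm)
    np.testing.assert_allclose(
        sorted(Z[:, 2]), sorted(naive_average_linkage(dm.values)), atol=1e-10
    )


def test_cluster_rejects_asymmetric_matrix():
    with pytest.raises(ValueError):
        MotifDistanceMatrix(labels=["a", "b"], values=np.array([[0, 0.2], [0.3, 0]]))


def test_newick_export_has_all_leaves():
    import dendropy

    dm = motif_distance_matrix(
        [Motif.from_consensus(w) for w in ("TGACTCA", "TGACTMA", "CCAATCA", "GGGG")]
    )
    _, Z = hierarchical_cluster(dm)
    newick = linkage_to_newick(Z, dm.labels)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set(dm.labels)


def test_planted_variants_cluster_together():
    """One-position IUPAC edits of a word join below cut 0.3 in >= 9/10 trials."""
    rng = np.random.default_rng(17)
    letters = sorted(IUPAC_SETS)
    base = "TGACGTCA"
    ok = 0
    for _ in range(10):
        variants = [base]
        for _ in range(2):
            i = int(rng.integers(len(base)))
            sup = rng.choice([l for l in letters if IUPAC_SETS[base[i]] < IUPAC_SETS[l]])
            variants.append(base[:i] + sup + base[i + 1 :])
        decoys = [
            "".join(rng.choice(list("ACGT"), size=8)) for _ in range(4)
        ]
        motifs = [Motif.from_consensus(w) for w in variants + decoys]
        dm = motif_distance_matrix(motifs)
        assignment, _ = hierarchical_cluster(dm, cut_height=0.3)
        ok += len({assignment[i] for i in range(len(variants))}) == 1
    assert ok >= 9


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ({1, 2}, {1, 2}, 0.0),
        ({1}, {2}, 1.0),
        (set(), set(), 0.0),
        (set(range(100)), set(range(50, 150)), 1 - 50 / 150),
    ],
)
def test_jaccard_examples(a, b, expected):
    assert jaccard_distance(a, b) == pytest.approx(expected)


def test_jaccard_triangle_inequality_exhaustive_on_small_universe():
    universe = range(6)
    subsets = [
        frozenset(c)
        for r in range(7)
        for c in itertools.combinations(universe, r)
    ]
    rng = np.random.default_rng(0)
    idx = rng.integers(0, len(subsets), size=(4000, 3))
    for ia, ib, ic in idx:
        a, b, c = subsets[ia], subsets[ib], subsets[ic]
        assert jaccard_distance(a, c) <= (
            jaccard_distance(a, b) + jaccard_distance(b, c) + 1e-12
        )
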