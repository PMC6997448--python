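"""Fisher enrichment and discriminative motif discovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methmotif import (
    discover_motifs,
    fisher_enrichment,
    gen_flank_sequences,
    mask_matches,
    plant_motif,
)
from methmotif.discovery import _SUPERSETS
from methmotif.motif import IUPAC_SETS, Motif, match_positions


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """Brute-force P(X >= k) by summing the hypergeometric pmf."""
    denom = math.comb(N, n)
    total = 0.0
    for j in range(max(k, 0, n + K - N), min(n, K) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j) / denom
    return total


def test_fisher_trivial_and_derived_cases():
    assert fisher_enrichment(0, 10, 0, 100) == 1.0
    # all 10 positives carry the word, none of 100 background sequences do
    expected = hypergeom_tail_oracle(10, 110, 10, 10)
    assert fisher_enrichment(10, 10, 0, 100) == pytest.approx(expected, abs=1e-12)


def test_fisher_matches_enumeration_oracle_on_small_tables():
    rng = np.random.default_rng(1)
    for _ in range(300):
        pos_total = int(rng.integers(1, 16))
        neg_total = int(rng.integers(1, 16))
        pos_with = int(rng.integers(0, pos_total + 1))
        neg_with = int(rng.integers(0, neg_total + 1))
        p = fisher_enrichment(pos_with, pos_total, neg_with, neg_total)
        oracle = hypergeom_tail_oracle(
            pos_with, pos_total + neg_total, pos_with + neg_with, pos_total
        )
        assert p == pytest.approx(oracle, abs=1e-10)


@given(st.integers(0, 9), st.integers(0, 9))
@settings(derandomize=True, deadline=None)
def test_fisher_tail_monotone_in_pos_with(k1, k2):
    """At fixed margins, observing more positives can only shrink the tail."""
    lo, hi = sorted((k1, k2))
    # margins: pos_total=10, total with = hi + 5, neg_total=30
    p_lo = fisher_enrichment(lo, 10, hi + 5 - lo, 30)
    p_hi = fisher_enrichment(hi, 10, 5, 30)
    assert p_hi <= p_lo + 1e-12


def test_fisher_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        fisher_enrichment(-1, 10, 0, 10)
    with pytest.raises(ValueError):
        fisher_enrichment(11, 10, 0, 10)


def _planted_sets(n_pos, n_total, word, fin, fout, seed):
    recs = gen_flank_sequences(n_total, seed=seed)
    subset = {r.cpg_id for r in recs[:n_pos]}
    planted, truth = plant_motif(recs, word, subset, fin, fout, seed=seed)
    positives = {r.cpg_id: r.sequence for r in planted[:n_pos]}
    background = {r.cpg_id: r.sequence for r in planted}
    planted_pos = {c for c, _ in truth.planted_occurrences[word]} & set(positives)
    return positives, background, planted_pos


def test_discovery_recovers_planted_motif():
    positives, background, planted_pos = _planted_sets(
        200, 1200, "TGACTCA", 0.4, 0.01, seed=5
    )
    results = discover_motifs(positives, background, max_rounds=1)
    assert results, "no motif emitted"
    top = results[0]
    assert top.e_value < 0.05
    jac = len(top.matched_pos_ids & planted_pos) / len(
        top.matched_pos_ids | planted_pos
    )
    assert jac >= 0.8


def test_discovery_on_identical_sets_is_empty():
    seqs = {f"s{i}": s for i, s in enumerate(
        r.sequence for r in gen_flank_sequences(80, seed=3)
    )}
    assert discover_motifs(seqs, seqs, max_rounds=3) == []


def test_discovery_finds_two_disjoint_planted_motifs():
    recs = gen_flank_sequences(1200, seed=9)
    # disjoint halves of the positive set so the plantings cannot collide
    subset_a = {r.cpg_id for r in recs[:125]}
    subset_b = {r.cpg_id for r in recs[125:250]}
    recs, truth = plant_motif(recs, "TAGATAAG", subset_a, 0.9, 0.005, seed=9)
    recs, truth = plant_motif(recs, "CTCCGTTC", subset_b, 0.9, 0.005, seed=10, truth=truth)
    positives = {r.cpg_id: r.sequence for r in recs[:250]}
    background = {r.cpg_id: r.sequence for r in recs}
    results = discover_motifs(positives, background, max_rounds=2)
    assert len(results) == 2
    assert results[0].e_value <= results[1].e_value
    for word in ("TAGATAAG", "CTCCGTTC"):
        planted = {c for c, _ in truth.planted_occurrences[word]} & set(positives)
        best = max(
            len(r.matched_pos_ids & planted) / len(r.matched_pos_ids | planted)
            for r in results
        )
        assert best >= 0.8


def test_emitted_motifs_respect_threshold_and_length_bounds():
    positives, background, _ = _planted_sets(150, 900, "TGACTCA", 0.5, 0.01, seed=2)
    results = discover_motifs(
        positives, background, min_len=3, max_len=8, e_threshold=0.05, max_rounds=4
    )
    for r in results:
        assert r.e_value < 0.05
        assert 3 <= len(r.motif) <= 8
        assert r.e_value == pytest.approx(
            max(r.fisher_p * r.n_candidates, r.fisher_p), rel=1e-12
        )


def test_masking_removes_all_matches_of_emitted_motifs():
    positives, background, _ = _planted_sets(150, 900, "TGACTCA", 0.5, 0.01, seed=4)
    results = discover_motifs(positives, background, max_rounds=4)
    assert results
    seqs = list(positives.values())
    for r in sorted(results, key=lambda r: r.iteration):
        assert any(match_positions(r.motif, s) for s in seqs)
        seqs = mask_matches(r.motif, seqs)
        assert not any(match_positions(r.motif, s) for s in seqs)


def test_generalization_moves_never_shrink_the_match_set():
    rng = np.random.default_rng(8)
    seqs = [r.sequence for r in gen_flank_sequences(100, seed=8)]
    letters = sorted(IUPAC_SETS)
    for _ in range(30):
        word = "".join(rng.choice(letters, size=5))
        motif = Motif.from_consensus(word)
        base_matches = {i for i, s in enumerate(seqs) if match_positions(motif, s)}
        i = int(rng.integers(5))
        for sup in _SUPERSETS[motif.position_sets[i]]:
            gen = Motif(motif.position_sets[:i] + (sup,) + motif.position_sets[i + 1 :])
            gen_matches = {j for j, s in enumerate(seqs) if match_positions(gen, s)}
            assert base_matches <= gen_matches


def test_discovery_power_monotone_in_planting_fraction():
    recovered = {0.05: 0, 0.35: 0}
    for frac in recovered:
        for seed in range(10):
            positives, background, planted_pos = _planted_sets(
                120, 700, "TGACGTCA", frac, 0.01, seed=100 + seed
            )
            results = discover_motifs(positives, background, max_rounds=1)
            if results and planted_pos:
                jac = len(results[0].matched_pos_ids & planted_pos) / len(
                    results[0].matched_pos_ids | planted_pos
                )
                recovered[frac] += jac >= 0.8
    assert recovered[0.35] >= recovered[0.05]
    assert recovered[0.35] >= 9


def test_discovery_rejects_empty_inputs():
    with pytest.raises(ValueError):
        discover_motifs({}, {"a": "ACGT"})
    with pytest.raises(ValueError):
        discover_motifs({"a": "ACGT"}, {})
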