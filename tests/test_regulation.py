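"""Concordance classification, Wilcoxon DE and regulation summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methmotif import (
    DEResult,
    RegulationCall,
    SimulationConfig,
    classify_concordance,
    classify_regulation,
    gen_regulation_fixture,
    regulation_calls,
    summarize_contingency,
    wilcoxon_de,
)


@pytest.mark.parametrize(
    "label,cls,expected",
    [
        ("hyper", "MethylPlus", "concordant"),
        ("hypo", "MethylMinus", "concordant"),
        ("hypo", "MethylPlus", "discordant"),
        ("hyper", "MethylMinus", "discordant"),
        ("undefined", "MethylMinus", "excluded"),
        ("hyper", "unknown", "excluded"),
    ],
)
def test_concordance_rule(label, cls, expected):
    assert classify_concordance(label, cls) == expected


def test_wilcoxon_identical_groups_not_called():
    r = wilcoxon_de([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.direction == "none"


def test_wilcoxon_exact_p_matches_permutation_oracle():
    tumor, normal = [5.0, 6.0, 7.0], [1.0, 2.0, 3.0]
    r = wilcoxon_de(tumor, normal)
    # oracle: enumerate all C(6,3)=20 group assignments of the pooled values
    pooled = sorted(tumor + normal)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in tumor)
    stats = [
        sum(ranks[pooled[i]] for i in combo)
        for combo in itertools.combinations(range(6), 3)
    ]
    mean = np.mean(stats)
    p_oracle = sum(abs(s - mean) >= abs(observed - mean) for s in stats) / len(stats)
    assert r.p == pytest.approx(p_oracle, abs=1e-12)
    # smallest achievable two-sided p at n=3 vs 3 is 0.1, so the strict
    # p < 0.05 rule cannot call a direction despite the clean median shift
    assert r.median_tumor > r.median_normal
    assert r.direction == "none"


def test_wilcoxon_swap_flips_direction_and_keeps_p():
    rng = np.random.default_rng(23)
    t = rng.normal(2, 1, size=30)
    c = rng.normal(0, 1, size=25)
    a = wilcoxon_de(t, c)
    b = wilcoxon_de(c, t)
    assert a.p == pytest.approx(b.p, rel=1e-12)
    assert (a.direction, b.direction) == ("up", "down")


def test_wilcoxon_all_tied_gives_p_one():
    r = wilcoxon_de([2.0] * 5, [2.0] * 5)
    assert r.p == 1.0 and r.direction == "none"


def test_wilcoxon_zero_median_difference_never_called():
    # significant rank shift but identical medians -> direction none
    t = [0.0, 5.0, 5.0, 5.0, 10.0]
    c = [4.9, 4.95, 5.0, 5.05, 5.1]
    r = wilcoxon_de(t, c)
    assert r.median_tumor == r.median_normal
    assert r.direction == "none"


def test_wilcoxon_requires_three_per_group():
    with pytest.raises(ValueError):
        wilcoxon_de([1.0, 2.0], [1.0, 2.0, 3.0])


def _de(direction):
    return DEResult("g", 0, 0, 0.01 if direction != "none" else 0.5, direction)


@pytest.mark.parametrize(
    "directions,expected,n_de",
    [
        (["up", "up", "up", "down"], "up", 4),
        (["up", "up", "down", "down"], "mixed", 4),  # 50% is not > 50%
        (["down", "down", "none"], "down", 2),
        (["none", "none"], "mixed", 0),
        ([], "mixed", 0),
    ],
)
def test_regulation_majority_rule(directions, expected, n_de):
    label, n = classify_regulation([_de(d) for d in directions])
    assert (label, n) == (expected, n_de)


def test_regulation_order_invariant():
    des = [_de(d) for d in ["up", "down", "up", "none", "up"]]
    assert classify_regulation(des) == classify_regulation(des[::-1])


def test_wilcoxon_type_one_error_rate_near_alpha():
    rng = np.random.default_rng(29)
    n_sim = 2000
    false_pos = 0
    for _ in range(n_sim):
        t = rng.normal(size=50)
        c = rng.normal(size=50)
        false_pos += wilcoxon_de(t, c).direction != "none"
    assert 0.03 <= false_pos / n_sim <= 0.07


def test_wilcoxon_power_on_planted_shift():
    cfg = SimulationConfig(expression_effect=2.0, n_tumor=50, n_normal=50, seed=5)
    _, _, expr, labels, truth = gen_regulation_fixture(cfg)
    tumor = labels.index[labels == "tumor"]
    normal = labels.index[labels == "normal"]
    hits = sum(
        wilcoxon_de(expr.loc[g, tumor], expr.loc[g, normal]).direction == d
        for g, d in truth.true_de_genes.items()
    )
    assert hits / len(truth.true_de_genes) >= 0.9


def _call(conc, reg, genes=()):
    return RegulationCall(
        motif=None,
        tf_name="tf",
        motif_label="hyper",
        methyl_class="MethylPlus",
        concordance=conc,
        regulation=reg,
        n_de_targets=len(genes),
        de_results=[DEResult(g, 1, 0, 0.01, "up") for g in genes],
    )


def test_contingency_trivial_cases():
    empty = summarize_contingency([])
    assert (empty.to_numpy() == 0).all()
    one = summarize_contingency([_call("concordant", "down")])
    assert one.loc["concordant", "down"] == 1
    assert one.to_numpy().sum() == 1


def test_contingency_matches_loop_oracle():
    rng = np.random.default_rng(37)
    calls = [
        _call(
            str(rng.choice(["concordant", "discordant"])),
            str(rng.choice(["down", "mixed", "up"])),
        )
        for _ in range(100)
    ]
    table = summarize_contingency(calls)
    for conc in ("concordant", "discordant"):
        for reg in ("down", "mixed", "up"):
            oracle = sum(
                1 for c in calls if c.concordance == conc and c.regulation == reg
            )
            assert table.loc[conc, reg] == oracle


def test_contingency_by_genes_counts_unique_de_targets():
    calls = [
        _call("concordant", "up", genes=("g1", "g2")),
        _call("concordant", "up", genes=("g2", "g3")),
    ]
    table = summarize_contingency(calls, by="genes")
    assert table.loc["concordant", "up"] == 3


def test_regulation_calls_end_to_end_on_fixture():
    cfg = SimulationConfig(tf_db_size=6, n_targets_per_tf=8, seed=11)
    tf_db, targets, expr, labels, truth = gen_regulation_fixture(cfg)
    classes = {tf.tf_name: tf.methyl_class for tf in tf_db}
    pairs = [(None, tf.tf_name, "hyper") for tf in tf_db]
    calls = regulation_calls(pairs, classes, targets, expr, labels)
    assert all(c.concordance in ("concordant", "discordant") for c in calls)
    # unknown-class TFs are excluded entirely
    assert {c.tf_name for c in calls} == {
        t for t, cls in classes.items() if cls != "unknown"
    }


def test_concordant_pairs_dominated_by_one_direction():
    """Planted repression-by-methylation logic yields a Table-1-like asymmetry:
    concordant pairs concentrate in one regulation category at least as much
    as discordant pairs do."""
    ok = 0
    for seed in range(10):
        cfg = SimulationConfig(
            tf_db_size=12, n_targets_per_tf=8, expression_effect=2.0, seed=60 + seed
        )
        # concordant logic: MethylPlus TFs at hyper motifs lose activation ->
        # coherent down-regulation; TFs without the mechanism scatter
        tf_names = [f"TF{i + 1:03d}" for i in range(cfg.tf_db_size)]
        _, _, _, _, pre = gen_regulation_fixture(cfg)
        directions = {
            t: ("down" if pre.tf_classes[t] == "MethylPlus" else "mixed")
            for t in tf_names
        }
        tf_db, targets, expr, labels, truth = gen_regulation_fixture(
            cfg, tf_directions=directions
        )
        classes = {tf.tf_name: tf.methyl_class for tf in tf_db}
        pairs = [(None, t, "hyper") for t in tf_names]
        calls = regulation_calls(pairs, classes, targets, expr, labels)
        table = summarize_contingency(calls)

        def modal_frac(row):
            return row.max() / row.sum() if row.sum() else 1.0

        ok += modal_frac(table.loc["concordant"]) >= modal_frac(
            table.loc["discordant"]
        )
    assert ok >= 8
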