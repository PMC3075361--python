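"""Homolog join, the 2-fold direction contingency, and the Fisher exact test."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from tempotome import concordance_table, fisher_exact, join_homologs


def fisher_two_sided_enumeration(table):
    """Full hypergeometric enumeration over all margin-consistent tables."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    if n == 0:
        return 1.0
    denom = comb(n, c1)
    prob = lambda x: comb(r1, x) * comb(r2, c1 - x) / denom
    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # same near-tie convention as the minimum-likelihood two-sided test
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def test_fisher_diagonal_unit_table():
    result = fisher_exact(np.array([[1, 0], [0, 1]]))
    assert result.p_value == pytest.approx(1.0)
    assert result.odds_ratio == np.inf


def test_fisher_zero_margin_gives_p_one():
    for table in ([[0, 0], [3, 4]], [[2, 0], [5, 0]], [[0, 0], [0, 0]]):
        assert fisher_exact(np.array(table)).p_value == pytest.approx(1.0)


def test_fisher_odds_ratio_conventions():
    assert fisher_exact(np.array([[4, 1], [2, 3]])).odds_ratio == pytest.approx(6.0)
    assert fisher_exact(np.array([[4, 0], [0, 3]])).odds_ratio == np.inf
    assert fisher_exact(np.array([[0, 2], [3, 0]])).odds_ratio == 0.0
    assert np.isnan(fisher_exact(np.array([[0, 2], [0, 0]])).odds_ratio)


def test_fisher_matches_enumeration_oracle(rng):
    for _ in range(100):
        table = rng.integers(0, 31, size=(2, 2))
        p = fisher_exact(table).p_value
        assert p == pytest.approx(fisher_two_sided_enumeration(table), abs=1e-12)


def test_fisher_invariant_under_joint_transposition(rng):
    for _ in range(25):
        t = rng.integers(0, 20, size=(2, 2))
        swapped = t[::-1, ::-1]  # swap both rows and columns
        assert fisher_exact(t).p_value == pytest.approx(
            fisher_exact(swapped).p_value, abs=1e-12
        )


def test_fisher_rejects_negative_counts():
    with pytest.raises(ValueError):
        fisher_exact(np.array([[1, -1], [0, 2]]))


def _pair_inputs(fc_a_vals, fc_b_vals, r_a_vals, r_b_vals):
    genes_a = [f"a{i}" for i in range(len(fc_a_vals))]
    genes_b = [f"b{i}" for i in range(len(fc_b_vals))]
    fc_a = pd.DataFrame({"log2_fc": fc_a_vals}, index=genes_a)
    fc_b = pd.DataFrame({"log2_fc": fc_b_vals}, index=genes_b)
    r_a = pd.Series(r_a_vals, index=genes_a)
    r_b = pd.Series(r_b_vals, index=genes_b)
    homolog_map = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})
    return fc_a, r_a, fc_b, r_b, homolog_map


def test_join_empty_map_gives_empty_table():
    fc_a, r_a, fc_b, r_b, _ = _pair_inputs([1.0], [1.0], [0.9], [0.9])
    empty_map = pd.DataFrame({"gene_a": [], "gene_b": []})
    assert len(join_homologs(fc_a, r_a, fc_b, r_b, empty_map)) == 0


def test_joint_reproducibility_strict_on_both_sides():
    fc_a, r_a, fc_b, r_b, homolog_map = _pair_inputs(
        [2.0, 2.0], [2.0, 2.0], [0.9, 0.9], [0.79, 0.81]
    )
    pairs = join_homologs(fc_a, r_a, fc_b, r_b, homolog_map)
    flags = pairs.set_index("gene_a")["joint_reproducible"]
    assert not flags.loc["a0"]  # r_b = 0.79 fails the strict > 0.8 rule
    assert flags.loc["a1"]


def test_many_to_many_collapsed_by_max_min_correlation():
    fc_a = pd.DataFrame({"log2_fc": [2.0]}, index=["a0"])
    fc_b = pd.DataFrame({"log2_fc": [1.5, 1.5]}, index=["b0", "b1"])
    r_a = pd.Series([0.95], index=["a0"])
    r_b = pd.Series([0.85, 0.92], index=["b0", "b1"])
    homolog_map = pd.DataFrame({"gene_a": ["a0", "a0"], "gene_b": ["b0", "b1"]})
    pairs = join_homologs(fc_a, r_a, fc_b, r_b, homolog_map)
    assert len(pairs) == 1
    assert pairs.iloc[0]["gene_b"] == "b1"  # min(0.95, 0.92) > min(0.95, 0.85)


def test_fold_threshold_boundary_inclusive():
    fc_a, r_a, fc_b, r_b, homolog_map = _pair_inputs(
        [1.0, 0.999], [-1.3, 2.0], [0.9, 0.9], [0.9, 0.9]
    )
    pairs = join_homologs(fc_a, r_a, fc_b, r_b, homolog_map)
    counts = concordance_table(pairs, fold_threshold_log2=1.0)
    # |fc_a| = 1.0 exactly is included and discordant; 0.999 is excluded
    assert counts[0, 1] == 1
    assert counts.sum() == 1


def test_counts_match_brute_force_filter(rng):
    n = 300
    fc_a_vals = rng.normal(0, 1.5, n)
    fc_b_vals = rng.normal(0, 1.5, n)
    r_a_vals = rng.uniform(0, 1, n)
    r_b_vals = rng.uniform(0, 1, n)
    fc_a, r_a, fc_b, r_b, homolog_map = _pair_inputs(fc_a_vals, fc_b_vals, r_a_vals, r_b_vals)
    pairs = join_homologs(fc_a, r_a, fc_b, r_b, homolog_map)
    counts = concordance_table(pairs, fold_threshold_log2=1.0)
    expected = sum(
        1
        for fa, fb, ra, rb in zip(fc_a_vals, fc_b_vals, r_a_vals, r_b_vals)
        if ra > 0.8 and rb > 0.8 and abs(fa) >= 1.0 and abs(fb) >= 1.0
    )
    assert counts.sum() == expected


def test_counts_monotone_in_fold_threshold(rng):
    n = 200
    fc_a, r_a, fc_b, r_b, homolog_map = _pair_inputs(
        rng.normal(0, 2, n), rng.normal(0, 2, n),
        rng.uniform(0.5, 1, n), rng.uniform(0.5, 1, n),
    )
    pairs = join_homologs(fc_a, r_a, fc_b, r_b, homolog_map)
    totals = [
        concordance_table(pairs, fold_threshold_log2=t).sum() for t in (0.5, 1.0, 1.5, 2.0)
    ]
    assert all(a >= b for a, b in zip(totals, totals[1:]))
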