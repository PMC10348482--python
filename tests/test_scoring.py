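import logging

import numpy as np
import pytest

from abguilds import (
    BinaryMatrix, abundance_adjustment, attribution_scores, compute_scores,
    fit_ab, guild_scores, probabilistic_representatives,
)
from abguilds.ab_model import ABFit

from conftest import random_binary_matrix


def _manual_fit(gamma, beta):
    gamma = np.asarray(gamma, float)
    beta = np.asarray(beta, float)
    return ABFit(gamma=gamma, beta=beta, K=beta.shape[0],
                 loglik_trace=np.array([0.0]), n_iter=0, seed=0)


def test_attribution_rows_sum_to_one(small_matrix):
    fit = fit_ab(small_matrix, K=3, n_iter=50, n_restarts=1, seed=0)
    r = attribution_scores(fit, small_matrix)
    assert r.shape == (small_matrix.F, 3)
    assert np.abs(r.sum(axis=1) - 1).max() < 1e-8
    assert r.min() >= 0 and r.max() <= 1 + 1e-12


def test_attribution_k1_is_one(small_matrix):
    fit = fit_ab(small_matrix, K=1, n_iter=10, n_restarts=1, seed=0)
    assert np.allclose(attribution_scores(fit, small_matrix), 1.0)


def test_attribution_two_genome_toy():
    """Opposed genomes with identical beta rows split attribution 50/50."""
    matrix = BinaryMatrix(["g1", "g2"], ["f1", "f2", "f3"],
                          np.array([[1, 0, 1], [0, 1, 1]]))
    fit = _manual_fit([[1.0, 0.0], [0.0, 1.0]],
                      [[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]])
    r = attribution_scores(fit, matrix)
    assert np.allclose(r, 0.5)


def test_attribution_conditional_variant():
    """The conditional mean averages only over genomes carrying the
    function, so a function owned by one aspect's genomes attributes
    fully to that aspect."""
    matrix = BinaryMatrix(["g1", "g2"], ["f1", "f2"],
                          np.array([[1, 0], [0, 1]]))
    fit = _manual_fit([[0.9, 0.1], [0.1, 0.9]],
                      [[0.9, 0.1], [0.1, 0.9]])
    r = attribution_scores(fit, matrix, conditional=True)
    # f1 present only in g1: resp toward aspect 1 is 0.81/0.82
    assert np.allclose(r[0], [0.81 / 0.82, 0.01 / 0.82])
    assert np.allclose(r.sum(axis=1), 1.0)


def test_attribution_shape_mismatch(small_matrix, two_block_matrix):
    fit = fit_ab(small_matrix, K=2, n_iter=10, n_restarts=1, seed=0)
    with pytest.raises(ValueError):
        attribution_scores(fit, two_block_matrix)


@pytest.mark.parametrize("gamma_row,K,expected_aspect", [
    ((0.9, 0.1), 2, None),              # 2/K = 1: nobody qualifies at K=2
    ((1 / 3, 1 / 3, 1 / 3), 3, None),   # uniform row excluded by design
])
def test_representatives_threshold_excludes(gamma_row, K, expected_aspect):
    gamma = np.array([gamma_row])
    beta = np.full((K, 2), 0.5)
    fit = _manual_fit(gamma, beta)
    sets = probabilistic_representatives(fit, ["g1"])
    assert all(not s for s in sets) if expected_aspect is None else None


def test_representatives_large_k_includes():
    """At K=10 the threshold is 0.2, so a 0.25 maximum at aspect 3 (0-based
    index 2) is enough for membership."""
    gamma = np.full((1, 10), 0.75 / 9)
    gamma[0, 2] = 0.25
    fit = _manual_fit(gamma, np.full((10, 3), 0.5))
    sets = probabilistic_representatives(fit, ["g1"])
    assert sets[2] == ["g1"]
    assert sum(len(s) for s in sets) == 1


def test_representatives_disjoint_property(small_matrix):
    fit = fit_ab(small_matrix, K=4, n_iter=80, n_restarts=2, seed=1)
    sets = probabilistic_representatives(fit, small_matrix.genome_ids)
    flat = [g for s in sets for g in s]
    assert len(flat) == len(set(flat))
    gidx = {g: i for i, g in enumerate(small_matrix.genome_ids)}
    for k, members in enumerate(sets):
        for g in members:
            row = fit.gamma[gidx[g]]
            assert row[k] > 2 / 4
            assert k == int(np.argmax(row))


def test_abundance_adjustment_uniform_and_toy():
    # uniform carriage: every function at q = 1
    matrix = BinaryMatrix(["g1", "g2"], ["fA", "fB"], np.ones((2, 2), np.uint8))
    q = abundance_adjustment([["g1", "g2"]], matrix)
    assert np.allclose(q, 1.0)
    # fA in both genomes, fB in neither: q = (2/1, 0/1)
    matrix = BinaryMatrix(["g1", "g2"], ["fA", "fB"],
                          np.array([[1, 0], [1, 0]]))
    q = abundance_adjustment([["g1", "g2"]], matrix)
    assert np.allclose(q[:, 0], [2.0, 0.0])


def test_abundance_adjustment_mean_is_one(small_matrix):
    q = abundance_adjustment([small_matrix.genome_ids[:10]], small_matrix)
    assert np.isclose(q[:, 0].mean(), 1.0)


def test_abundance_adjustment_empty_set_warns(caplog, small_matrix):
    with caplog.at_level(logging.WARNING, logger="abguilds.scoring"):
        q = abundance_adjustment([[]], small_matrix)
    assert np.all(q == 0)
    assert "no probabilistic representatives" in caplog.text


def test_guild_scores_product_and_ties():
    r = np.array([[0.5], [0.5], [0.2]])
    q = np.array([[2.0], [2.0], [1.0]])
    table = guild_scores(r, q, ["fB", "fA", "fC"], ["g1"], [[]])
    assert np.allclose(table.s, r * q)
    # equal scores tie-break by ascending function ID
    assert table.ranked_functions[0] == ["fA", "fB", "fC"]


def test_guild_scores_identity_adjustment_ranks_by_r(small_matrix):
    fit = fit_ab(small_matrix, K=3, n_iter=50, n_restarts=1, seed=3)
    r = attribution_scores(fit, small_matrix)
    ones = np.ones_like(r)
    table = guild_scores(r, ones, small_matrix.function_ids,
                         small_matrix.genome_ids, [[]] * 3)
    for k in range(3):
        by_r = [small_matrix.function_ids[j]
                for j in np.lexsort((small_matrix.function_ids, -r[:, k]))]
        assert table.ranked_functions[k] == by_r


def test_guild_scores_shape_mismatch():
    with pytest.raises(ValueError):
        guild_scores(np.ones((3, 2)), np.ones((2, 3)), ["a", "b", "c"], [], [[]])


def test_four_block_recovery(four_block_matrix):
    """Each planted block owns one aspect, and its functions occupy the
    top of that aspect's s-ranked list ahead of all other functions."""
    fit = fit_ab(four_block_matrix, K=4, n_iter=300, n_restarts=10, seed=0)
    table = compute_scores(fit, four_block_matrix)
    blocks = [set(four_block_matrix.function_ids[3 * b:3 * (b + 1)])
              for b in range(4)]
    recovered = [set(table.ranked_functions[k][:3]) for k in range(4)]
    assert sorted(map(tuple, (sorted(b) for b in blocks))) == \
        sorted(map(tuple, (sorted(r) for r in recovered)))


def test_ranking_invariant_to_genome_order(small_matrix):
    rng = np.random.default_rng(8)
    perm = rng.permutation(small_matrix.G)
    permuted = BinaryMatrix([small_matrix.genome_ids[i] for i in perm],
                            small_matrix.function_ids, small_matrix.values[perm])
    K = 3
    gamma0 = rng.dirichlet(np.ones(K), size=small_matrix.G)
    beta0 = rng.uniform(0.25, 0.75, (K, small_matrix.F))
    fit = fit_ab(small_matrix, K, n_iter=60, n_restarts=1, seed=0,
                 init=(gamma0, beta0), sort_aspects=False)
    fit_p = fit_ab(permuted, K, n_iter=60, n_restarts=1, seed=0,
                   init=(gamma0[perm], beta0), sort_aspects=False)
    table = compute_scores(fit, small_matrix)
    table_p = compute_scores(fit_p, permuted)
    assert table.ranked_functions == table_p.ranked_functions
    assert np.allclose(table.s, table_p.s, atol=1e-10)
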