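import math

import numpy as np
import pandas as pd
import pytest

from oscillate import (
    InputError,
    batch_signal,
    mk_fit_rate,
    mk_loglik,
    parse_newick,
    permutation_signal_test,
    simulate_mk_trait,
    simulate_yule_tree,
)
from conftest import enumeration_loglik

# Reference fits computed with ape::ace (type="discrete", model="ER") on the
# identical tree/state files; ace's log-likelihood omits the flat-root 1/2
# factor, so only the rate is compared.
APE_ORACLE = [
    # (tree seed, trait seed, q_over_depth_factor, ape rate)
    (11, 12, 0.3, 0.1212785),
    (11, 13, 0.08, 0.02598407),
]


def test_cherry_closed_forms(cherry):
    assert mk_loglik(cherry, {"A": 1, "B": 1}, 0.0) == pytest.approx(-math.log(2))
    assert mk_loglik(cherry, {"A": 1, "B": 0}, 0.0) == -math.inf


def test_pruning_matches_enumeration_small_tree():
    t = parse_newick("(((A:0.3,B:0.7):0.4,C:1.1):0.2,(D:0.5,E:0.9):0.6);")
    states = {"A": 0, "B": 1, "C": 1, "D": 0, "E": 1}
    for q in (0.05, 0.3, 1.0, 4.0):
        assert mk_loglik(t, states, q) == pytest.approx(
            enumeration_loglik(t, states, q), abs=1e-10
        )


def test_missing_tip_equals_marginalisation():
    t = parse_newick("(((A:0.3,B:0.7):0.4,C:1.1):0.2,D:0.5);")
    partial = {"A": 0, "B": 1, "D": 1}
    for q in (0.1, 0.8):
        direct = mk_loglik(t, partial, q)
        summed = np.logaddexp(
            mk_loglik(t, {**partial, "C": 0}, q),
            mk_loglik(t, {**partial, "C": 1}, q),
        )
        assert direct == pytest.approx(summed, abs=1e-10)
        assert direct == pytest.approx(enumeration_loglik(t, partial, q),
                                       abs=1e-10)


def test_large_q_limit_independent_tips():
    t = simulate_yule_tree(30, 1.0, seed=5).rescaled(1.0)
    t = t.rescaled(1.0 / t.depth())
    states = {lab: i % 2 for i, lab in enumerate(t.tip_labels)}
    assert mk_loglik(t, states, 1e3) == pytest.approx(30 * math.log(0.5),
                                                      abs=1e-3)


def test_unknown_tip_in_states_rejected(cherry):
    with pytest.raises(InputError):
        mk_loglik(cherry, {"A": 1, "Z": 0}, 0.1)


def test_constant_trait_pins_lower_bound(quartet):
    fit = mk_fit_rate(quartet, {"A": 0, "B": 0, "C": 0, "D": 0})
    assert fit.bounds_hit == "lower"
    assert fit.q < 1e-6


def test_fit_matches_fine_grid_search():
    t = parse_newick("(((A:0.3,B:0.7):0.4,C:1.1):0.2,(D:0.5,E:0.9):0.6,F:1.4);")
    states = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1, "F": 0}
    fit = mk_fit_rate(t, states)
    grid = np.arange(1e-4, 5.0, 1e-4)
    lls = [mk_loglik(t, states, q) for q in grid]
    q_grid = grid[int(np.argmax(lls))]
    assert abs(fit.q - q_grid) <= 1e-4
    assert fit.loglik >= max(lls) - 1e-8


@pytest.mark.parametrize("tree_seed,trait_seed,qfac,ape_rate", APE_ORACLE)
def test_fit_matches_ape_ace(tree_seed, trait_seed, qfac, ape_rate):
    t = simulate_yule_tree(40, 1.0, seed=tree_seed)
    states = simulate_mk_trait(t, qfac / t.depth(), 0, seed=trait_seed)
    fit = mk_fit_rate(t, states)
    assert fit.q == pytest.approx(ape_rate, rel=1e-4)


def test_recovery_of_simulation_rate():
    qs = []
    for rep in range(40):
        t = simulate_yule_tree(120, 1.0, seed=400 + rep)
        q_true = 0.2 / t.depth()
        states = simulate_mk_trait(t, q_true, 0, seed=500 + rep)
        if len(set(states.values())) == 1:
            continue
        qs.append(mk_fit_rate(t, states).q * t.depth())
    assert 0.13 <= float(np.median(qs)) <= 0.27


def test_permutation_requires_variation_and_nperm(cherry, quartet):
    with pytest.raises(InputError):
        permutation_signal_test(quartet, {"A": 0, "B": 1, "C": 0, "D": 1},
                                n_perm=0, seed=1)
    with pytest.warns(UserWarning, match="constant"):
        res = permutation_signal_test(quartet, {t: 1 for t in "ABCD"},
                                      n_perm=19, seed=1)
    assert res.p_value == 1.0
    assert np.all(res.permuted_q == res.observed_q)


def test_p_value_invariant_to_state_relabeling(yule50):
    states = simulate_mk_trait(yule50, 0.2 / yule50.depth(), 0, seed=9)
    flipped = {k: 1 - v for k, v in states.items()}
    r1 = permutation_signal_test(yule50, states, n_perm=49, seed=77)
    r2 = permutation_signal_test(yule50, flipped, n_perm=49, seed=77)
    assert r1.observed_q == pytest.approx(r2.observed_q, rel=1e-9)
    assert r1.p_value == r2.p_value


def test_p_value_plus_one_bound():
    res_p = 0.0
    from oscillate import SignalTestResult

    r = SignalTestResult(observed_q=0.1, permuted_q=np.ones(99),
                         p_value=res_p, n_perm=99, seed=0)
    assert r.p_value_plus_one == pytest.approx(1 / 100)


def test_batch_signal_duplicate_and_constant_columns(yule50):
    states = simulate_mk_trait(yule50, 0.15 / yule50.depth(), 0, seed=21)
    if len(set(states.values())) == 1:  # pragma: no cover
        pytest.skip("degenerate draw")
    mat = pd.DataFrame(
        {
            "a": pd.Series(states),
            "b": pd.Series(states),
            "const": pd.Series({k: 1 for k in states}),
        }
    )
    table, results = batch_signal(yule50, mat, n_perm=199, seed=5)
    row = table.set_index("trait")
    assert row.loc["a", "t_rate"] == pytest.approx(row.loc["b", "t_rate"],
                                                   rel=1e-9)
    # sub-seeds differ by column, so p agrees only to Monte-Carlo error
    assert abs(row.loc["a", "p"] - row.loc["b", "p"]) <= 0.12
    assert row.loc["const", "p"] == 1.0
    assert bool(row.loc["const", "constant"])


def test_clustered_trait_beats_shuffled_trait():
    wins = 0
    n = 20
    for rep in range(n):
        t = simulate_yule_tree(60, 1.0, seed=900 + rep)
        rng = np.random.default_rng(1000 + rep)
        clustered = simulate_mk_trait(t, 0.08 / t.depth(), 0, rng)
        if len(set(clustered.values())) == 1:
            clustered = simulate_mk_trait(t, 0.3 / t.depth(), 0, rng)
        vals = list(clustered.values())
        shuffled = dict(zip(clustered.keys(),
                            rng.permutation(vals).tolist()))
        mat = pd.DataFrame({"clustered": pd.Series(clustered),
                            "shuffled": pd.Series(shuffled)})
        table, _ = batch_signal(t, mat, n_perm=99, seed=1100 + rep)
        row = table.set_index("trait")
        wins += row.loc["clustered", "p"] <= row.loc["shuffled", "p"]
    assert wins >= int(0.8 * n)
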