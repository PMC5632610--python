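import json
import math

import numpy as np
import pytest
import statsmodels.api as sm

from oscillate import (
    CAICFit,
    DegenerateDataError,
    InputError,
    PGLSFit,
    macrocaic,
    model_report,
    parse_newick,
    pgls_fit,
    simulate_yule_tree,
)
from oscillate.comparative import fit_to_json, phylo_covariance
from oscillate.synthetic import simulate_bm_trait


def regression_data(tree, seed, beta=0.8, noise=0.5):
    x = simulate_bm_trait(tree, 1.0, 0.0, seed=seed)
    rng = np.random.default_rng(seed + 1)
    y = {k: beta * v + rng.normal(0, noise) for k, v in x.items()}
    return x, y


def test_covariance_matches_mrca_depths():
    t = parse_newick("((A:1,B:1):0.5,C:2);")
    C, order = phylo_covariance(t)
    i = {lab: k for k, lab in enumerate(order)}
    assert C[i["A"], i["A"]] == pytest.approx(1.5)
    assert C[i["A"], i["B"]] == pytest.approx(0.5)
    assert C[i["A"], i["C"]] == pytest.approx(0.0)
    assert C[i["C"], i["C"]] == pytest.approx(2.0)


def test_lambda_zero_equals_ols():
    tree = simulate_yule_tree(40, 1.0, seed=61)
    x, y = regression_data(tree, 62)
    fit = pgls_fit(tree, x, y, lambda_mode=0.0)
    order = tree.tip_labels
    X = sm.add_constant(np.array([x[k] for k in order]))
    ols = sm.OLS(np.array([y[k] for k in order]), X).fit()
    assert fit.beta == pytest.approx(ols.params[1], abs=1e-10)
    assert fit.intercept == pytest.approx(ols.params[0], abs=1e-10)
    assert fit.se_beta == pytest.approx(ols.bse[1], abs=1e-10)
    assert fit.r_squared == pytest.approx(ols.rsquared, abs=1e-10)


def test_star_tree_is_ols_for_any_lambda():
    star = parse_newick("(" + ",".join(f"t{i}:1" for i in range(12)) + ");")
    x, y = regression_data(star, 63)
    fits = [pgls_fit(star, x, y, lambda_mode=lam) for lam in (0.0, 0.5, 1.0)]
    for f in fits[1:]:
        assert f.beta == pytest.approx(fits[0].beta, abs=1e-10)
        assert f.r_squared == pytest.approx(fits[0].r_squared, abs=1e-10)


def test_fixed_lambda_matches_statsmodels_gls():
    tree = simulate_yule_tree(30, 1.0, seed=64)
    x, y = regression_data(tree, 65)
    lam = 0.5
    fit = pgls_fit(tree, x, y, lambda_mode=lam)
    C, order = phylo_covariance(tree)
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    X = sm.add_constant(np.array([x[k] for k in order]))
    gls = sm.GLS(np.array([y[k] for k in order]), X, sigma=V).fit()
    assert fit.beta == pytest.approx(gls.params[1], abs=1e-8)
    assert fit.se_beta == pytest.approx(gls.bse[1], abs=1e-8)


def test_ml_lambda_is_a_maximum():
    tree = simulate_yule_tree(50, 1.0, seed=66)
    x = simulate_bm_trait(tree, 1.0, 0.0, seed=67)
    # phylogenetically structured residuals: lambda-hat should be interior
    eps = simulate_bm_trait(tree, 0.3, 0.0, seed=68)
    y = {k: 0.5 * x[k] + eps[k] for k in x}
    fit = pgls_fit(tree, x, y, lambda_mode="ML")
    for lam in (0.0, 1.0):
        assert fit.loglik >= pgls_fit(tree, x, y, lambda_mode=lam).loglik - 1e-6


def test_pgls_input_validation():
    tree = simulate_yule_tree(10, 1.0, seed=69)
    x, y = regression_data(tree, 70)
    with pytest.raises(InputError):
        pgls_fit(tree, {k: v for k, v in list(x.items())[:-1]}, y)
    const = {k: 1.0 for k in x}
    with pytest.raises(DegenerateDataError):
        pgls_fit(tree, const, y)


def test_macrocaic_hand_worked_quartet():
    # ((A:1,B:1):1,(C:2,D:2):1); trait 0,4 | 1,7 ; richness 2,2 | 1,8
    t = parse_newick("((A:1,B:1):1,(C:2,D:2):1);")
    trait = {"A": 0.0, "B": 4.0, "C": 1.0, "D": 7.0}
    rich = {"A": 2, "B": 2, "C": 1, "D": 8}
    fit = macrocaic(t, trait, rich)
    got = {node: (tc, rc) for node, tc, rc in fit.contrasts}
    # node AB: |4-0|/sqrt(2), richer side is B's? trait orients B first:
    # ln(2/2) = 0
    # node CD: |7-1|/sqrt(4) = 3, response ln(8/1)
    # root: nodal values 2 (AB) and 4 (CD); adjusted lengths 1+0.5, 1+1;
    # contrast (4-2)/sqrt(3.5), response ln(9/4)
    expect = [
        (4 / math.sqrt(2), 0.0),
        (3.0, math.log(8.0)),
        (2 / math.sqrt(3.5), math.log(9.0 / 4.0)),
    ]
    for (gtc, grc), (etc_, erc) in zip(sorted(got.values()), sorted(expect)):
        assert gtc == pytest.approx(etc_, abs=1e-12)
        assert grc == pytest.approx(erc, abs=1e-12)
    # regression through the origin, checked against statsmodels
    xs = np.array([c[1] for c in fit.contrasts])
    ys = np.array([c[2] for c in fit.contrasts])
    ols = sm.OLS(ys, xs).fit()
    assert fit.slope_through_origin == pytest.approx(ols.params[0], abs=1e-10)
    assert fit.f_stat == pytest.approx(ols.fvalue, abs=1e-8)
    assert fit.adj_r_squared == pytest.approx(ols.rsquared_adj, abs=1e-10)
    assert fit.df == 2


def test_macrocaic_zero_richness_contrasts_give_zero_slope():
    # balanced tree, equal richness everywhere: every ln(N1/N2) is exactly 0
    t = parse_newick("(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);")
    rng = np.random.default_rng(71)
    trait = {lab: float(v) for lab, v in
             zip("abcdefgh", rng.normal(0, 1, 8))}
    rich = {lab: 4 for lab in "abcdefgh"}
    fit = macrocaic(t, trait, rich)
    assert fit.slope_through_origin == 0.0


def test_macrocaic_invariances():
    tree = simulate_yule_tree(20, 1.0, seed=72)
    trait = simulate_bm_trait(tree, 1.0, 0.0, seed=73)
    rng = np.random.default_rng(74)
    rich = {k: int(rng.integers(1, 40)) for k in trait}
    base = macrocaic(tree, trait, rich)
    shifted = macrocaic(tree, {k: v + 100.0 for k, v in trait.items()}, rich)
    scaled = macrocaic(tree, trait, {k: 3 * v for k, v in rich.items()})
    for other in (shifted, scaled):
        assert other.slope_through_origin == pytest.approx(
            base.slope_through_origin, rel=1e-9
        )
        assert other.f_stat == pytest.approx(base.f_stat, rel=1e-9)


def test_macrocaic_polytomy_policy():
    t = parse_newick("(A:1,B:1,C:1);")
    trait = {"A": 0.0, "B": 1.0, "C": 2.0}
    rich = {"A": 1, "B": 2, "C": 3}
    with pytest.raises(InputError, match="polytom"):
        macrocaic(t, trait, rich)
    with pytest.warns(UserWarning, match="resolved"):
        fit = macrocaic(t, trait, rich, polytomies="resolve")
    assert len(fit.contrasts) == 2


def test_model_report_shapes_and_json_roundtrip():
    pf = PGLSFit(beta=0.77, intercept=0.1, se_beta=0.14, f_stat=30.43,
                 df_num=1, df_den=43, r_squared=0.40, lambda_hat=0.70,
                 loglik=-12.3, p_value=1.5e-6)
    rep = model_report(pf)
    assert "β = 0.77" in rep and "λ = 0.70" in rep and "F_43" in rep
    cf = CAICFit(contrasts=[(1, 0.5, 0.2)], slope_through_origin=0.4,
                 f_stat=16.6, adj_r_squared=0.266, df=42, p_value=2e-4)
    rep2 = model_report(cf)
    assert "df = 42" in rep2 and "0.266" in rep2
    for fit in (pf, cf):
        payload = json.loads(fit_to_json(fit))
        for key, val in fit.to_dict().items():
            assert payload[key] == val
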