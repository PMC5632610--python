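"""Replicated simulation experiments over the full pipeline.

Each function runs one of the package's calibration or recovery studies —
the quantitative checks that the statistical machinery behaves as designed
under synthetic data whose generating values mirror the empirical regime —
and returns a small dict of summary numbers. They are shared by the
analysis drivers, the acceptance checks and the test suite so every report
of these quantities comes from the same computation.

Every experiment takes a single master seed; per-replicate seeds are fanned
out deterministically from it.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .comparative import macrocaic, pgls_fit
from .contrasts import hd_maxpoly_correlation
from .hostdata import derive_genus_traits
from .mk_signal import permutation_signal_test
from .synthetic import SimConfig, simulate_host_universe, simulate_mk_trait, \
    simulate_yule_tree

__all__ = [
    "signal_type_i_error",
    "signal_power",
    "pgls_recovery",
    "caic_null_type_i",
    "caic_power",
]

_SEED_CAP = 2**31 - 1


def _rep_seeds(seed: int, n: int, k: int = 3) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _SEED_CAP, size=(n, k))


def signal_type_i_error(
    n_reps: int = 500,
    n_tips: int = 100,
    n_perm: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the permutation signal test under the iid null.

    Tip states are iid Bernoulli(1/2) — no phylogenetic structure — so the
    test should reject at about ``alpha``.
    """
    seeds = _rep_seeds(seed, n_reps)
    rej = 0
    pvals = []
    for s_tree, s_trait, s_perm in seeds:
        tree = simulate_yule_tree(n_tips, 1.0, int(s_tree))
        rng = np.random.default_rng(int(s_trait))
        states = {lab: int(v) for lab, v in
                  zip(tree.tip_labels, rng.integers(0, 2, n_tips))}
        if len(set(states.values())) == 1:  # astronomically rare
            continue
        res = permutation_signal_test(tree, states, n_perm=n_perm,
                                      seed=int(s_perm))
        pvals.append(res.p_value)
        rej += res.p_value <= alpha
    return {
        "n_reps": len(pvals),
        "rejection_rate": rej / len(pvals),
        "p_values": np.array(pvals),
    }


def signal_power(
    n_reps: int = 200,
    n_tips: int = 100,
    q_unit_depth: float = 0.1,
    n_perm: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate when traits truly evolve at a low Mk rate.

    Traits are simulated at rate ``q_unit_depth`` on the unit-depth scale of
    each tree and redrawn if constant (a constant trait carries no signal
    information and short-circuits to p = 1).
    """
    seeds = _rep_seeds(seed, n_reps)
    rej = 0
    n_done = 0
    for s_tree, s_trait, s_perm in seeds:
        tree = simulate_yule_tree(n_tips, 1.0, int(s_tree))
        q = q_unit_depth / tree.depth()
        rng = np.random.default_rng(int(s_trait))
        while True:
            states = simulate_mk_trait(tree, q, 0, rng)
            if len(set(states.values())) > 1:
                break
        res = permutation_signal_test(tree, states, n_perm=n_perm,
                                      seed=int(s_perm))
        rej += res.p_value <= alpha
        n_done += 1
    return {"n_reps": n_done, "power": rej / n_done}


def _universe_fits(
    n_reps: int, config: SimConfig, seed: int, want: Iterable[str]
):
    """Simulate universes and fit the requested models per replicate."""
    seeds = _rep_seeds(seed, n_reps)
    out: dict[str, list] = {k: [] for k in want}
    for s_tree, s_uni, _ in seeds:
        tree = simulate_yule_tree(config.n_tips, config.birth_rate,
                                  int(s_tree))
        uni = simulate_host_universe(tree, config, int(s_uni))
        traits = derive_genus_traits(uni.records, uni.richness)
        log_hd = {t.taxon: math.log10(t.hd) for t in traits}
        log_r = {t.taxon: math.log10(t.n_species) for t in traits}
        if "pgls" in out:
            out["pgls"].append(pgls_fit(tree, log_hd, log_r,
                                        lambda_mode="ML"))
        if "caic" in out:
            rich = {t.taxon: t.n_species for t in traits}
            out["caic"].append(macrocaic(tree, log_hd, rich))
        if "hd_r2" in out:
            out["hd_r2"].append(hd_maxpoly_correlation(traits)[0])
    return out


def pgls_recovery(
    n_reps: int = 200,
    n_tips: int = 60,
    seed: int = 0,
    config: SimConfig | None = None,
) -> dict:
    """Recovery of the generating slope and lambda by ML-lambda PGLS."""
    config = config or SimConfig(n_tips=n_tips)
    fits = _universe_fits(n_reps, config, seed, ("pgls",))["pgls"]
    betas = np.array([f.beta for f in fits])
    lams = np.array([f.lambda_hat for f in fits])
    return {
        "n_reps": n_reps,
        "beta_true": config.beta_true,
        "lambda_true": config.lambda_true,
        "beta_mean": float(betas.mean()),
        "beta_sd": float(betas.std(ddof=1)),
        "lambda_median": float(np.median(lams)),
    }


def caic_null_type_i(
    n_reps: int = 500,
    n_tips: int = 60,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the through-origin richness-contrast regression
    when host diversity has no effect on richness."""
    config = SimConfig(n_tips=n_tips, beta_true=0.0, coupling=0.0)
    fits = _universe_fits(n_reps, config, seed, ("caic",))["caic"]
    rej = sum(f.p_value < alpha for f in fits)
    return {"n_reps": n_reps, "rejection_rate": rej / n_reps}


def caic_power(
    n_reps: int = 100,
    n_tips: int = 60,
    alpha: float = 0.05,
    seed: int = 0,
    config: SimConfig | None = None,
) -> dict:
    """Power of the richness-contrast regression under the default effect."""
    config = config or SimConfig(n_tips=n_tips)
    fits = _universe_fits(n_reps, config, seed, ("caic",))["caic"]
    hits = sum(
        f.p_value < alpha and f.slope_through_origin > 0 for f in fits
    )
    slopes = np.array([f.slope_through_origin for f in fits])
    return {
        "n_reps": n_reps,
        "power": hits / n_reps,
        "slope_mean": float(slopes.mean()),
    }
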