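"""Replicated simulation studies over synthetic cohorts.

These functions reproduce, at desk scale, the calibration experiments the
package's claims rest on: how often the ten-model competition recovers the
generating GxE family at the study sample size, the coverage of the
crossover interval, the type-I behaviour of the exploratory screen, and the
family-wise behaviour of the FDR step.  Each study is a pure function of its
seed; problem sizes are arguments with defaults matching the study scale
(n = 197).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gxe_models, pipeline
from .synthetic_cohort import (CohortConfig, OutcomeSpec, SimulationTruth,
                               make_cohort, regime_family, simulate_null_cohort,
                               simulate_outcome, sigma_for_target_r2)

__all__ = [
    "classification_accuracy", "crossover_coverage",
    "exploratory_type1_rate", "fdr_family_false_alarm",
    "adversity_variance_explained",
]

_FAMILY_REGIMES = {
    "differential_susceptibility": ("ds_weak", "ds_strong"),
    "diathesis_stress": ("diathesis_weak", "diathesis_strong"),
    "vantage_sensitivity": ("vantage_weak", "vantage_strong"),
    "no_gxe": ("intercept", "g_only", "e_only", "g_plus_e"),
}

_RELIABILITIES = (0.76, 0.85, 0.84, 0.81, 0.85)


def classification_accuracy(n_reps: int = 100, n: int = 197,
                            r2_range: tuple = (0.03, 0.10),
                            seed: int = 0) -> dict:
    """Correct-family rate of the ten-model competition on known regimes.

    Generates ``n_reps`` single-outcome cohorts per family at sample size
    ``n`` through the full pipeline (genotypes -> pseudo-GWAS -> C+T PRS ->
    adversity factors -> outcome), cycling the family's weak/strong (or
    null) regimes and the study's outcome reliabilities across replicates,
    with the unique interaction (or, for null regimes, main-effect) variance
    share drawn uniformly from ``r2_range``.  A replicate counts as correct
    when ``compete`` returns a label in the generating family (for null
    regimes: ``no_gxe``).

    Returns per-family accuracies plus their mean under ``"mean"``.
    """
    master = np.random.default_rng(seed)
    out = {}
    for family, regimes in _FAMILY_REGIMES.items():
        hits = 0
        for rep in range(n_reps):
            regime = regimes[rep % len(regimes)]
            rep_seed = int(master.integers(0, 2 ** 31 - 1))
            r2 = float(np.random.default_rng(rep_seed).uniform(*r2_range))
            cfg = CohortConfig(n=n, outcomes={
                "y": OutcomeSpec(regime=regime,
                                 # intercept-only truth is pure noise: no
                                 # signal share to target
                                 target_r2=None if regime == "intercept" else r2,
                                 clip_r2=True,
                                 reliability=_RELIABILITIES[rep % 5],
                                 beta_E=0.0 if regime.endswith("_strong") else 0.25,
                                 beta_S=1.0, beta_G=0.5, c_quantile=0.40),
            })
            cohort = make_cohort(cfg, seed=rep_seed)
            cls = gxe_models.compete(cohort.data, cohort.g_col,
                                     cohort.e_col_for["y"], "y")
            hits += (cls.family == family)
        out[family] = hits / n_reps
    out["mean"] = float(np.mean([out[f] for f in _FAMILY_REGIMES]))
    return out


def _draw_ge(n: int, rng: np.random.Generator):
    g = rng.uniform(0.0, 1.0, n)
    G = (g - g.min()) / (g.max() - g.min())
    E = rng.standard_normal(n)
    return G, E


def crossover_coverage(n_reps: int = 500, n: int = 197, level: float = 0.95,
                       target_r2: float = 0.07, seed: int = 0) -> float:
    """Empirical coverage of the crossover interval under weak-DS truth.

    Each replicate draws fresh (G, E), fixes the true crossover at the 0.4
    quantile of E, calibrates the residual SD to the target interaction
    variance share, fits ``ds_weak`` and checks whether the delta-method
    interval covers the true crossover.
    """
    master = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_reps):
        rng = np.random.default_rng(int(master.integers(0, 2 ** 31 - 1)))
        G, E = _draw_ge(n, rng)
        c_true = float(np.quantile(E, 0.4))
        truth = SimulationTruth("ds_weak", beta0=0.0, beta_E=0.25, beta_S=1.0,
                                c=c_true, sigma=1.0)
        sigma = sigma_for_target_r2(truth, G, E, None, target_r2)
        truth = SimulationTruth("ds_weak", beta0=0.0, beta_E=0.25, beta_S=1.0,
                                c=c_true, sigma=sigma)
        y = simulate_outcome(G, E, None, truth, rng=rng)
        df = pd.DataFrame({"G": G, "E": E, "Y": y})
        fit = gxe_models.fit_model(df, "ds_weak", "G", "E", "Y")
        if not fit.crossover_identified:
            continue
        lo, hi = gxe_models.crossover_ci(fit, level=level)
        covered += (lo <= c_true <= hi)
    return covered / n_reps


def exploratory_type1_rate(n_reps: int = 2000, n: int = 197,
                           alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of null replicates where the interaction term reaches
    ``p < alpha`` in the exploratory OLS screen."""
    master = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        rng = np.random.default_rng(int(master.integers(0, 2 ** 31 - 1)))
        G, E = _draw_ge(n, rng)
        df = pd.DataFrame({"G": G, "E": E, "Y": rng.standard_normal(n)})
        table, _ = gxe_models.exploratory_interaction_test(df, "G", "E", "Y")
        hits += (table.loc["G:E", "p"] < alpha)
    return hits / n_reps


def fdr_family_false_alarm(n_reps: int = 500, n: int = 197,
                           alpha: float = 0.05, seed: int = 0) -> float:
    """Proportion of all-null cohorts in which any FDR-adjusted interaction
    p-value in a (score set, outcome) family falls below ``alpha``.

    Each replicate is a fast all-null cohort (4 thresholds x 3 factors per
    family); one outcome family is examined per replicate.
    """
    master = np.random.default_rng(seed)
    alarms = 0
    for _ in range(n_reps):
        coh = simulate_null_cohort(n=n, n_outcomes=1,
                                   seed=int(master.integers(0, 2 ** 31 - 1)))
        praw = []
        for t, g_col in coh.prs_cols.items():
            for e_col in coh.env_cols:
                table, _ = gxe_models.exploratory_interaction_test(
                    coh.data, g_col, e_col, "y1",
                    covariates=coh.covariate_cols)
                praw.append(float(table.loc["G:E", "p"]))
        alarms += bool((pipeline.bh_fdr(praw) < alpha).any())
    return alarms / n_reps


def adversity_variance_explained(n_seeds: int = 20, n: int = 197,
                                 n_factors: int = 4, seed: int = 0) -> float:
    """Mean pre-rotation top-k eigenvalue share of default synthetic
    batteries across ``n_seeds`` generator seeds."""
    from .adversity_factors import fit_pca_oblique
    from .synthetic_cohort import simulate_adversity

    master = np.random.default_rng(seed)
    shares = []
    for _ in range(n_seeds):
        battery = simulate_adversity(n, seed=int(master.integers(0, 2 ** 31 - 1)))
        shares.append(fit_pca_oblique(battery, n_factors).var_explained)
    return float(np.mean(shares))
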