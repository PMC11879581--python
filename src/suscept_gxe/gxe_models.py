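"""Competitive-confirmatory crossover GxE models.

The family distinguishes three substantive gene-by-environment patterns by
where the regression lines for different susceptibility levels cross:

* **differential susceptibility (DS)** -- lines cross at a free point ``c``
  inside the observed environment range ("for better and for worse");
* **diathesis-stress** -- lines converge at the most favorable environment
  (``c`` fixed at ``min(E)``, with E oriented so larger = more adverse);
* **vantage sensitivity** -- lines converge at the most adverse environment
  (``c`` fixed at ``max(E)``).

Each pattern has a *weak* and a *strong* variant.  With the susceptibility
score G min-max rescaled to [0, 1] and covariates X, the mean function is

    mu = beta0 + gamma'X + (beta_E + beta_S * G) * (E - c)

where the strong variants constrain ``beta_E = 0`` (the least-susceptible
individual is environment-insensitive).  Four no-interaction models
(intercept, G only, E only, G + E) complete the ten-model family; if one of
them wins, the verdict is "no evidence of GxE".

All ten models are fitted by ordinary least squares -- the free-crossover
models through the exact linear reparameterization (basis {E, G*E, G} for
weak DS, {G*E, G} for strong DS, with ``c = -coef(G)/coef(G*E)``) -- and
compared by AIC under a Gaussian likelihood with the residual variance at
its MLE.  A DS winner is only accepted if the 95% delta-method interval for
the crossover lies inside the observed environment bounds; otherwise the
verdict is ``ds_unconfirmed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MODEL_IDS", "GXE_MODEL_IDS", "NULL_MODEL_IDS",
    "GxEModelSpec", "GxEFit", "GxEClassification",
    "exploratory_interaction_test", "fit_model", "crossover_ci", "compete",
    "label_family", "plot_crossover",
]

NULL_MODEL_IDS = ("intercept", "g_only", "e_only", "g_plus_e")
GXE_MODEL_IDS = ("diathesis_weak", "diathesis_strong",
                 "vantage_weak", "vantage_strong", "ds_weak", "ds_strong")
MODEL_IDS = NULL_MODEL_IDS + GXE_MODEL_IDS

_LABELS = {
    "ds_weak": "differential_susceptibility_weak",
    "ds_strong": "differential_susceptibility_strong",
    "diathesis_weak": "diathesis_stress_weak",
    "diathesis_strong": "diathesis_stress_strong",
    "vantage_weak": "vantage_sensitivity_weak",
    "vantage_strong": "vantage_sensitivity_strong",
}


def label_family(label: str) -> str:
    """Collapse a classification label to its model family."""
    for fam in ("differential_susceptibility", "diathesis_stress",
                "vantage_sensitivity"):
        if label.startswith(fam):
            return fam
    if label == "no_gxe":
        return "no_gxe"
    return label            # ds_unconfirmed stays its own (non-)family


@dataclass(frozen=True)
class GxEModelSpec:
    model_id: str
    crossover_mode: str               # free | fixed_at_env_min | fixed_at_env_max | absent
    beta_E_constrained_zero: bool
    includes_G_main: bool
    includes_E_main: bool

    @classmethod
    def from_id(cls, model_id: str) -> "GxEModelSpec":
        if model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {model_id!r}")
        mode = ("free" if model_id.startswith("ds") else
                "fixed_at_env_min" if model_id.startswith("diathesis") else
                "fixed_at_env_max" if model_id.startswith("vantage") else
                "absent")
        return cls(
            model_id=model_id,
            crossover_mode=mode,
            beta_E_constrained_zero=model_id.endswith("_strong"),
            includes_G_main=model_id in ("g_only", "g_plus_e"),
            includes_E_main=model_id in ("e_only", "g_plus_e"),
        )


@dataclass
class GxEFit:
    """One fitted model: estimates, SEs, Gaussian likelihood, AIC."""

    spec: GxEModelSpec
    params: dict
    ses: dict
    sigma_hat: float
    loglik: float
    n_params: int
    aic: float
    r2: float
    n: int
    e_bounds: tuple
    crossover: float | None = None
    crossover_se: float | None = None
    crossover_identified: bool = False
    fitted: np.ndarray | None = None
    _arrays: dict = field(default_factory=dict, repr=False)


def _design(model_id: str, G: np.ndarray, E: np.ndarray,
            X: np.ndarray, e_bounds: tuple):
    """Design columns (beyond intercept and covariates) and their names."""
    emin, emax = e_bounds
    if model_id == "intercept":
        cols, names = [], []
    elif model_id == "g_only":
        cols, names = [G], ["beta_G"]
    elif model_id == "e_only":
        cols, names = [E], ["beta_E"]
    elif model_id == "g_plus_e":
        cols, names = [G, E], ["beta_G", "beta_E"]
    elif model_id in ("diathesis_weak", "diathesis_strong",
                      "vantage_weak", "vantage_strong"):
        c0 = emin if model_id.startswith("diathesis") else emax
        Ec = E - c0
        if model_id.endswith("weak"):
            cols, names = [Ec, G * Ec], ["beta_E", "beta_S"]
        else:
            cols, names = [G * Ec], ["beta_S"]
    elif model_id == "ds_weak":
        cols, names = [E, G * E, G], ["_bE", "_bGE", "_bG"]
    elif model_id == "ds_strong":
        cols, names = [G * E, G], ["_bGE", "_bG"]
    else:
        raise ValueError(model_id)
    return cols, names


def _rescale_g(g: np.ndarray) -> np.ndarray:
    lo, hi = np.min(g), np.max(g)
    if hi <= lo:
        raise ValueError("susceptibility score is constant; cannot rescale to [0, 1]")
    return (g - lo) / (hi - lo)


def fit_model(data: pd.DataFrame, model_id: str, g_col: str, e_col: str,
              y_col: str, covariates: Sequence[str] = (),
              rescale_g: bool = True, aicc: bool = False) -> GxEFit:
    """Fit one of the ten models by (reparameterized) least squares.

    The parameter count includes the intercept, every free slope, the free
    crossover (through the reparameterized G coefficient) and the residual
    variance, so AIC is comparable across the whole family.
    """
    spec = GxEModelSpec.from_id(model_id)
    G = data[g_col].to_numpy(dtype=float)
    E = data[e_col].to_numpy(dtype=float)
    Y = data[y_col].to_numpy(dtype=float)
    X = data[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(Y), 0))
    if not (np.isfinite(G).all() and np.isfinite(E).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite values in modelling columns")
    if rescale_g:
        G = _rescale_g(G)
    e_bounds = (float(np.min(E)), float(np.max(E)))
    if spec.crossover_mode != "absent" and e_bounds[0] >= e_bounds[1]:
        raise ValueError("environment score is constant; crossover models undefined")

    n = len(Y)
    cols, names = _design(model_id, G, E, X, e_bounds)
    D = np.column_stack([np.ones(n)] + cols + [X]) if X.size else \
        np.column_stack([np.ones(n)] + cols) if cols else np.ones((n, 1))
    if X.size and not cols:
        D = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ coef
    rss = float(resid @ resid)
    p_lin = D.shape[1]
    if n <= p_lin:
        raise ValueError("need more observations than linear parameters")

    var_y = float(np.var(Y))
    # scale-aware floor: numerically-zero RSS (exact fits) must tie exactly
    # across models so the parsimony tie-break decides, including when Y is
    # a non-zero constant (var_y = 0)
    floor = 1e-16 * (var_y + 1e-8 * float(np.mean(Y ** 2))) + 1e-300
    sigma2_ml = max(rss / n, floor)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
    k = p_lin + 1                                  # + sigma
    aic = 2 * k - 2 * loglik
    if aicc:
        aic += 2 * k * (k + 1) / max(n - k - 1, 1)

    sigma2_u = max(rss / (n - p_lin), floor)
    XtX_inv = np.linalg.pinv(D.T @ D)
    cov = sigma2_u * XtX_inv
    se_lin = np.sqrt(np.maximum(np.diag(cov), 0.0))

    all_names = ["beta0"] + names + [f"gamma_{c}" for c in covariates]
    params = dict(zip(all_names, coef))
    ses = dict(zip(all_names, se_lin))

    crossover = crossover_se = None
    identified = False
    if spec.crossover_mode == "free":
        iGE = all_names.index("_bGE")
        iG = all_names.index("_bG")
        bGE, bG = coef[iGE], coef[iG]
        scale = np.std(Y) + 1e-300
        identified = abs(bGE) > 1e-8 * scale
        if identified:
            c_hat = -bG / bGE
            grad = np.zeros(p_lin)
            grad[iG] = -1.0 / bGE
            grad[iGE] = bG / bGE ** 2
            crossover_se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
            crossover = float(c_hat)
            # report on the substantive scale
            params["beta_S"] = bGE
            ses["beta_S"] = ses.pop("_bGE")
            params["c"] = crossover
            ses["c"] = crossover_se
            if model_id == "ds_weak":
                params["beta_E"] = params.pop("_bE")
                ses["beta_E"] = ses.pop("_bE")
                params["beta0"] = params["beta0"] + params["beta_E"] * crossover
            params.pop("_bGE", None)
            params.pop("_bG", None)
            ses.pop("_bG", None)

    tss = float(np.sum((Y - Y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0

    return GxEFit(
        spec=spec, params=params, ses=ses,
        sigma_hat=float(np.sqrt(sigma2_ml)), loglik=float(loglik),
        n_params=k, aic=float(aic), r2=float(r2), n=n, e_bounds=e_bounds,
        crossover=crossover, crossover_se=crossover_se,
        crossover_identified=identified,
        fitted=Y - resid,
        _arrays={"G": G, "E": E, "Y": Y, "X": X, "coef": coef, "rss": rss},
    )


def crossover_ci(fit: GxEFit, level: float = 0.95,
                 method: str = "delta") -> tuple[float, float]:
    """Confidence interval for the crossover point of a free-c fit.

    ``method="delta"`` (default): ``c +- z * SE(c)`` with the delta-method SE
    propagated through ``c = -coef(G)/coef(G*E)``.  ``method="profile"``
    inverts the profile likelihood in ``c`` as a cross-check.
    """
    if fit.spec.crossover_mode != "free":
        raise ValueError("crossover_ci requires a free-crossover (DS) fit")
    if not fit.crossover_identified:
        raise ValueError("crossover point is not identified (interaction ~ 0)")
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    if method == "delta":
        z = stats.norm.ppf(0.5 * (1 + level))
        return (fit.crossover - z * fit.crossover_se,
                fit.crossover + z * fit.crossover_se)
    if method == "profile":
        return _profile_ci(fit, level)
    raise ValueError(f"unknown method {method!r}")


def _profile_rss(fit: GxEFit, c: float) -> float:
    a = fit._arrays
    G, E, Y, X = a["G"], a["E"], a["Y"], a["X"]
    Ec = E - c
    if fit.spec.model_id == "ds_weak":
        cols = [Ec, G * Ec]
    else:
        cols = [G * Ec]
    D = np.column_stack([np.ones(len(Y))] + cols + ([X] if X.size else []))
    coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    r = Y - D @ coef
    return float(r @ r)


def _profile_ci(fit: GxEFit, level: float) -> tuple[float, float]:
    from scipy.optimize import brentq
    n = fit.n
    rss0 = fit._arrays["rss"]
    floor = 1e-16 * np.var(fit._arrays["Y"]) + 1e-300
    crit = stats.chi2.ppf(level, 1)

    def stat(c):
        return n * np.log(max(_profile_rss(fit, c), floor) /
                          max(rss0, floor)) - crit

    span = fit.e_bounds[1] - fit.e_bounds[0]
    lo = hi = fit.crossover
    step = max(span, 10 * (fit.crossover_se or span)) or 1.0
    lo_bound, hi_bound = fit.crossover - 50 * step, fit.crossover + 50 * step
    # march outward until the profile statistic crosses the critical value
    x = fit.crossover
    while stat(x) < 0 and x > lo_bound:
        x -= 0.05 * step
    lo = brentq(stat, x, fit.crossover) if stat(x) >= 0 else lo_bound
    x = fit.crossover
    while stat(x) < 0 and x < hi_bound:
        x += 0.05 * step
    hi = brentq(stat, fit.crossover, x) if stat(x) >= 0 else hi_bound
    return (float(lo), float(hi))


def exploratory_interaction_test(data: pd.DataFrame, g_col: str, e_col: str,
                                 y_col: str, covariates: Sequence[str] = ()):
    """Phase-1 OLS: ``y ~ G + E + G:E + covariates``.

    Returns ``(table, r2)`` where ``table`` has rows G, E, ``G:E`` and each
    covariate, with columns ``est``, ``se``, ``p`` (two-sided t-tests),
    mirroring an "Est. (SE), P, R^2" report layout.
    """
    import statsmodels.api as sm

    G = data[g_col].to_numpy(dtype=float)
    E = data[e_col].to_numpy(dtype=float)
    Y = data[y_col].to_numpy(dtype=float)
    used = [g_col, e_col, y_col, *covariates]
    if data[used].isna().any().any():
        raise ValueError("missing values in modelling columns")
    X = pd.DataFrame({"G": G, "E": E, "G:E": G * E}, index=data.index)
    for c in covariates:
        X[c] = data[c].to_numpy(dtype=float)
    n, p = X.shape
    if n < p + 1 + 10:
        raise ValueError("need at least 10 more observations than parameters")
    design = sm.add_constant(X)
    if np.linalg.cond(design.to_numpy()) > 1e12:
        raise np.linalg.LinAlgError("ill-conditioned design (collinear columns)")
    res = sm.OLS(Y, design).fit()
    table = pd.DataFrame({
        "est": res.params, "se": res.bse, "p": res.pvalues,
    }).drop(index="const")
    return table, float(res.rsquared)


@dataclass
class GxEClassification:
    """Outcome of the ten-model AIC competition."""

    label: str
    best_model: str
    aic_table: pd.DataFrame
    e_bounds: tuple
    crossover: float | None = None
    crossover_interval: tuple | None = None
    fits: dict = field(default_factory=dict)

    @property
    def family(self) -> str:
        return label_family(self.label)


def compete(data: pd.DataFrame, g_col: str, e_col: str, y_col: str,
            covariates: Sequence[str] = (), level: float = 0.95,
            aicc: bool = False) -> GxEClassification:
    """Fit all ten models, pick the lowest AIC, classify the interaction.

    Ties (within 1e-9) break to the model with the fewest parameters, then to
    the fixed model order.  A winning DS model must additionally have an
    identified crossover whose ``level`` interval lies inside the observed
    environment bounds; otherwise the verdict is ``ds_unconfirmed``.
    """
    fits: dict[str, GxEFit] = {}
    for mid in MODEL_IDS:
        try:
            fits[mid] = fit_model(data, mid, g_col, e_col, y_col,
                                  covariates=covariates, aicc=aicc)
        except Exception as exc:                    # noqa: BLE001
            raise RuntimeError(f"model {mid!r} failed to fit: {exc}") from exc

    table = pd.DataFrame({
        "model": MODEL_IDS,
        "n_params": [fits[m].n_params for m in MODEL_IDS],
        "loglik": [fits[m].loglik for m in MODEL_IDS],
        "aic": [fits[m].aic for m in MODEL_IDS],
        "r2": [fits[m].r2 for m in MODEL_IDS],
    })

    aics = table["aic"].to_numpy()
    amin = aics.min()
    cand = [i for i in range(len(MODEL_IDS)) if aics[i] - amin <= 1e-9]
    best_i = min(cand, key=lambda i: (table["n_params"][i], i))
    best = MODEL_IDS[best_i]
    bf = fits[best]

    crossover = interval = None
    if best in NULL_MODEL_IDS:
        label = "no_gxe"
    elif best.startswith("ds"):
        if bf.crossover_identified:
            interval = crossover_ci(bf, level=level)
            crossover = bf.crossover
            lo, hi = bf.e_bounds
            if lo <= interval[0] and interval[1] <= hi:
                label = _LABELS[best]
            else:
                label = "ds_unconfirmed"
        else:
            label = "ds_unconfirmed"
    else:
        label = _LABELS[best]

    return GxEClassification(label=label, best_model=best, aic_table=table,
                             e_bounds=bf.e_bounds, crossover=crossover,
                             crossover_interval=interval, fits=fits)


def plot_crossover(fit: GxEFit, path: str, g_levels: Sequence[float] = (0.0, 1.0),
                   n_grid: int = 100) -> str:
    """Plot fitted outcome lines over E at fixed susceptibility levels.

    For a free-crossover fit the estimated crossover point is marked.
    Covariates are held at their means.  Returns the written path.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = fit._arrays
    E_grid = np.linspace(fit.e_bounds[0], fit.e_bounds[1], n_grid)
    X_mean = a["X"].mean(axis=0) if a["X"].size else np.empty(0)
    fig, ax = plt.subplots(figsize=(5, 4))
    for g in g_levels:
        mu = _mean_on_grid(fit, g, E_grid, X_mean)
        ax.plot(E_grid, mu, label=f"G = {g:g}")
    if fit.spec.crossover_mode == "free" and fit.crossover_identified:
        ax.axvline(fit.crossover, ls="--", color="grey")
        ax.annotate(f"c = {fit.crossover:.2f}", (fit.crossover, ax.get_ylim()[0]),
                    textcoords="offset points", xytext=(4, 6), fontsize=8)
    ax.set_xlabel("environment (adversity)")
    ax.set_ylabel("predicted outcome")
    ax.set_title(fit.spec.model_id)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _mean_on_grid(fit: GxEFit, g: float, E_grid: np.ndarray,
                  X_mean: np.ndarray) -> np.ndarray:
    p = fit.params
    mid = fit.spec.model_id
    base = p["beta0"] + sum(
        p[f"gamma_{c}"] * xm
        for c, xm in zip([k[6:] for k in p if k.startswith("gamma_")], X_mean))
    if mid == "intercept":
        return np.full_like(E_grid, base)
    if mid == "g_only":
        return np.full_like(E_grid, base + p["beta_G"] * g)
    if mid == "e_only":
        return base + p["beta_E"] * E_grid
    if mid == "g_plus_e":
        return base + p["beta_G"] * g + p["beta_E"] * E_grid
    if mid in ("diathesis_weak", "diathesis_strong", "vantage_weak", "vantage_strong"):
        c0 = fit.e_bounds[0] if mid.startswith("diathesis") else fit.e_bounds[1]
        bE = p.get("beta_E", 0.0)
        return base + (bE + p["beta_S"] * g) * (E_grid - c0)
    bE = p.get("beta_E", 0.0)
    return base + (bE + p["beta_S"] * g) * (E_grid - p["c"])
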