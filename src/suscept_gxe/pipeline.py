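"""Two-phase screening + competitive-confirmatory pipeline.

Phase 1 runs the exploratory OLS interaction test (``y ~ G + E + G:E + PCs``)
for every cell of (score set, PRS threshold, adversity factor, outcome) and
applies Benjamini-Hochberg FDR within families of cells sharing a score set
and outcome (thresholds x factors jointly, the default family rule).

Phase 2 re-examines every cell whose *raw* interaction p-value passes the
gate (default .05) with the ten-model crossover competition, after trimming
non-significant covariates from that cell's phase-1 model.  The result is a
report table in the familiar "Est. (SE), P (P_FDR), R^2, best GxE model"
layout, with crossover estimates and intervals where applicable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gxe_models
from .synthetic_cohort import CohortTable

__all__ = ["PipelineConfig", "ResultsTable", "bh_fdr", "trim_covariates",
           "run_two_phase", "report"]


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, alpha=0.05, method="fdr_bh")[1]


def trim_covariates(data: pd.DataFrame, g_col: str, e_col: str, y_col: str,
                    covariates: Sequence[str], alpha: float = 0.05) -> list[str]:
    """Covariates kept for phase 2: significant (p < alpha) in the phase-1
    full model of this cell."""
    if not covariates:
        return []
    table, _ = gxe_models.exploratory_interaction_test(
        data, g_col, e_col, y_col, covariates=covariates)
    return [c for c in covariates if table.loc[c, "p"] < alpha]


@dataclass(frozen=True)
class PipelineConfig:
    """Which cells to run and how to gate/correct them.

    ``score_sets`` maps a score-set name to ``{threshold: column}``.
    """

    score_sets: Mapping
    env_cols: tuple
    outcome_cols: tuple
    covariates: tuple = ("PC1", "PC2")
    gate_alpha: float = 0.05
    trim_alpha: float = 0.05
    ci_level: float = 0.95
    aicc: bool = False

    @classmethod
    def from_cohort(cls, cohort: CohortTable, **overrides) -> "PipelineConfig":
        base = dict(
            score_sets={"PRS": dict(cohort.prs_cols)},
            env_cols=tuple(cohort.env_cols),
            outcome_cols=tuple(cohort.outcome_cols),
            covariates=tuple(cohort.covariate_cols),
        )
        base.update(overrides)
        return cls(**base)

    def config_hash(self) -> str:
        blob = json.dumps({
            "score_sets": {k: {str(t): c for t, c in v.items()}
                           for k, v in self.score_sets.items()},
            "env_cols": list(self.env_cols),
            "outcome_cols": list(self.outcome_cols),
            "covariates": list(self.covariates),
            "gate_alpha": self.gate_alpha, "trim_alpha": self.trim_alpha,
            "ci_level": self.ci_level, "aicc": self.aicc,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_COLUMNS = ["score_set", "threshold", "factor", "outcome",
            "est_g", "se_g", "p_g", "est_e", "se_e", "p_e",
            "est_gxe", "se_gxe", "p_gxe", "p_gxe_fdr", "r2",
            "label", "best_model", "crossover", "ci_lo", "ci_hi",
            "covariates_kept", "error"]


@dataclass
class ResultsTable:
    """One row per (score set, threshold, factor, outcome) cell."""

    table: pd.DataFrame
    failures: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_csv(self, path: str, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path: str, sep: str = "\t") -> "ResultsTable":
        return cls(table=pd.read_csv(path, sep=sep))


def run_two_phase(cohort, config: PipelineConfig | None = None) -> ResultsTable:
    """Run phase 1 on every cell, FDR per (score set, outcome) family, then
    phase 2 on gated cells.  Failures flag their cell and the run continues.
    """
    data = cohort.data if isinstance(cohort, CohortTable) else cohort
    if config is None:
        if not isinstance(cohort, CohortTable):
            raise ValueError("pass a PipelineConfig when cohort is a bare table")
        config = PipelineConfig.from_cohort(cohort)

    rows: list[dict] = []
    failures: list[str] = []
    for sset, thr_map in config.score_sets.items():
        thresholds = sorted(thr_map)
        for outcome in config.outcome_cols:
            fam_rows = []
            for t in thresholds:
                for factor in config.env_cols:
                    row = {"score_set": sset, "threshold": t, "factor": factor,
                           "outcome": outcome, "error": ""}
                    try:
                        tab, r2 = gxe_models.exploratory_interaction_test(
                            data, thr_map[t], factor, outcome,
                            covariates=config.covariates)
                        row.update(
                            est_g=tab.loc["G", "est"], se_g=tab.loc["G", "se"],
                            p_g=tab.loc["G", "p"],
                            est_e=tab.loc["E", "est"], se_e=tab.loc["E", "se"],
                            p_e=tab.loc["E", "p"],
                            est_gxe=tab.loc["G:E", "est"],
                            se_gxe=tab.loc["G:E", "se"],
                            p_gxe=tab.loc["G:E", "p"], r2=r2)
                    except Exception as exc:                 # noqa: BLE001
                        row["error"] = f"phase1: {exc}"
                        failures.append(f"{sset}/{t}/{factor}/{outcome}: {exc}")
                    fam_rows.append(row)
            ok = [r for r in fam_rows if not r["error"]]
            if ok:
                adj = bh_fdr([r["p_gxe"] for r in ok])
                for r, a in zip(ok, adj):
                    r["p_gxe_fdr"] = a
            rows.extend(fam_rows)

    for row in rows:
        row.setdefault("label", "")
        row.setdefault("best_model", "")
        row.setdefault("crossover", np.nan)
        row.setdefault("ci_lo", np.nan)
        row.setdefault("ci_hi", np.nan)
        row.setdefault("covariates_kept", "")
        if row["error"] or not (row.get("p_gxe", np.nan) < config.gate_alpha):
            continue
        sset, t = row["score_set"], row["threshold"]
        g_col = config.score_sets[sset][t]
        try:
            kept = trim_covariates(data, g_col, row["factor"], row["outcome"],
                                   config.covariates, alpha=config.trim_alpha)
            cls = gxe_models.compete(data, g_col, row["factor"], row["outcome"],
                                     covariates=kept, level=config.ci_level,
                                     aicc=config.aicc)
            row["label"] = cls.label
            row["best_model"] = cls.best_model
            row["covariates_kept"] = ",".join(kept)
            if cls.crossover is not None:
                row["crossover"] = cls.crossover
                row["ci_lo"], row["ci_hi"] = cls.crossover_interval
        except Exception as exc:                             # noqa: BLE001
            row["error"] = f"phase2: {exc}"
            failures.append(
                f"{sset}/{t}/{row['factor']}/{row['outcome']}: {exc}")

    table = pd.DataFrame(rows, columns=_COLUMNS)
    meta = {"config_hash": config.config_hash(), "n_cells": len(table),
            "n_failures": len(failures)}
    if isinstance(cohort, CohortTable):
        meta["cohort_seed"] = cohort.meta.get("seed")
    return ResultsTable(table=table, failures=failures, meta=meta)


def report(results: ResultsTable, outdir: str, fmt: str = "tsv",
           data: pd.DataFrame | None = None,
           config: PipelineConfig | None = None, make_plots: bool = True) -> list[str]:
    """Write the results table (and a crossover plot per classified cell).

    Plots need the cohort ``data`` and ``config`` to refit the winning model;
    they are skipped otherwise.  Returns the written paths.
    """
    import os

    if results.table.empty:
        raise ValueError("results table is empty")
    os.makedirs(outdir, exist_ok=True)
    written = []
    sep = "\t" if fmt == "tsv" else ","
    path = os.path.join(outdir, f"results.{fmt}")
    results.to_csv(path, sep=sep)
    written.append(path)

    if make_plots and data is not None and config is not None:
        classified = results.table[
            results.table["label"].isin(gxe_models._LABELS.values())]
        for _, row in classified.iterrows():
            g_col = config.score_sets[row["score_set"]][row["threshold"]]
            kept = [c for c in str(row["covariates_kept"]).split(",") if c]
            fit = gxe_models.fit_model(data, row["best_model"], g_col,
                                       row["factor"], row["outcome"],
                                       covariates=kept)
            fname = (f"crossover_{row['score_set']}_p{row['threshold']:g}_"
                     f"{row['factor']}_{row['outcome']}.png")
            written.append(gxe_models.plot_crossover(
                fit, os.path.join(outdir, fname)))
    return written
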