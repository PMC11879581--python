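"""Synthetic cohorts with known gene-by-environment ground truth.

Everything downstream of the generators (C+T scoring, oblique adversity
factors, the crossover model competition, the two-phase pipeline) is testable
without any data download:

* ``simulate_genotypes`` -- LD-blocked dosages from a latent-Gaussian copula:
  two haplotype-like latent AR(1) processes per block, thresholded at the
  allele frequency, so the implied dosage correlations have a closed form.
* ``simulate_gwas_summary`` -- a pseudo-GWAS over the panel's SNPs under a
  point-normal effect distribution, with Wald p-values at a declared pseudo
  sample size; provides realistic weights for C+T.
* ``simulate_adversity`` -- 13 subscale scores (emulating CTQ/ITEC/CECA-style
  instruments) as linear images of 4 correlated latent factors; one factor
  (sexual abuse) gets a heavy floor so the downstream skewness screen has
  something to catch.
* ``simulate_outcome`` -- outcomes under any of the 10 competing regimes
  (4 no-interaction + weak/strong differential susceptibility,
  diathesis-stress, vantage sensitivity), sharing the exact mean function of
  the fitting side.
* ``make_cohort`` -- the end-to-end composition at the study scale
  (n = 197, 4 PRS thresholds, 4 adversity factors of which 3 survive the
  skew screen, 5 outcomes with stated reliabilities, 2 ancestry-PC nuisance
  covariates).

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import prs_engine
from .adversity_factors import fit_pca_oblique, skewness_screen

__all__ = [
    "REGIMES", "NULL_REGIMES", "GXE_REGIMES", "regime_family",
    "SimulationTruth", "AdversityBattery", "CohortTable",
    "OutcomeSpec", "CohortConfig",
    "simulate_genotypes", "simulate_gwas_summary", "simulate_adversity",
    "simulate_outcome", "make_cohort", "simulate_null_cohort",
    "regime_mean", "sigma_for_target_r2",
]

NULL_REGIMES = ("intercept", "g_only", "e_only", "g_plus_e")
GXE_REGIMES = ("vantage_weak", "vantage_strong", "diathesis_weak",
               "diathesis_strong", "ds_weak", "ds_strong")
REGIMES = NULL_REGIMES + GXE_REGIMES


def regime_family(regime_id: str) -> str:
    if regime_id in NULL_REGIMES:
        return "no_gxe"
    if regime_id.startswith("ds"):
        return "differential_susceptibility"
    if regime_id.startswith("diathesis"):
        return "diathesis_stress"
    if regime_id.startswith("vantage"):
        return "vantage_sensitivity"
    raise ValueError(f"unknown regime {regime_id!r}")


# ---------------------------------------------------------------------------
# truth container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters of one outcome.

    The mean function mirrors the fitting side exactly: for GxE regimes
    ``mu = beta0 + gamma'X + (beta_E + beta_S G)(E - c)`` with ``c`` anchored
    to min(E) (diathesis), max(E) (vantage) or free (DS); null regimes use
    ``mu = beta0 + gamma'X + beta_G G + beta_E E`` with the unused main
    effects zero.  ``sigma`` is the latent residual SD.
    """

    regime_id: str
    beta0: float = 0.0
    beta_G: float = 0.0
    beta_E: float = 0.0
    beta_S: float = 0.0
    c: float = 0.0
    sigma: float = 1.0
    gamma: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.regime_id not in REGIMES:
            raise ValueError(f"unknown regime {self.regime_id!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.regime_id.endswith("_strong") and self.beta_E != 0:
            raise ValueError("strong regimes require beta_E = 0")
        if self.regime_id in NULL_REGIMES:
            if self.beta_S != 0:
                raise ValueError("null regimes require beta_S = 0")
            if self.regime_id in ("intercept", "e_only") and self.beta_G != 0:
                raise ValueError(f"{self.regime_id} requires beta_G = 0")
            if self.regime_id in ("intercept", "g_only") and self.beta_E != 0:
                raise ValueError(f"{self.regime_id} requires beta_E = 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(n_individuals: int, n_snps: int,
                       maf_low: float = 0.05, maf_high: float = 0.5,
                       block_size: int = 5, block_rho: float = 0.7,
                       seed: int = 0, dosage_mode: str = "hard",
                       spacing_bp: int = 10_000) -> prs_engine.GenotypePanel:
    """LD-blocked dosage panel from a thresholded latent-Gaussian copula.

    SNPs fall in contiguous blocks of ``block_size``; within a block the two
    haplotype-like latent processes follow an AR(1) with first-order
    correlation ``block_rho``, independent across blocks.  Each latent value
    is thresholded at the normal quantile of the SNP's allele frequency
    (drawn uniformly in [maf_low, maf_high]), so dosages are Binomial(2, maf)
    marginally and Hardy-Weinberg within SNP.  Positions are 1-based and
    ``spacing_bp`` apart, all on one chromosome; with the defaults a block
    spans well under 1000 kb.

    ``dosage_mode="continuous"`` adds a small truncated jitter emulating
    imputed (non-integer) dosages.
    """
    if n_individuals <= 0 or n_snps <= 0:
        raise ValueError("n_individuals and n_snps must be positive")
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if not (0 <= block_rho < 1):
        raise ValueError("block_rho must lie in [0, 1)")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")

    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_low, maf_high, size=n_snps)
    thresh = stats.norm.ppf(maf)

    dosage = np.zeros((n_individuals, n_snps))
    innov_scale = np.sqrt(1.0 - block_rho ** 2)
    for _hap in range(2):
        e = rng.standard_normal((n_individuals, n_snps))
        z = np.empty_like(e)
        for j in range(n_snps):
            if j % block_size == 0:
                z[:, j] = e[:, j]
            else:
                z[:, j] = block_rho * z[:, j - 1] + innov_scale * e[:, j]
        dosage += (z < thresh)

    if dosage_mode == "continuous":
        dosage = np.clip(dosage + rng.uniform(-0.1, 0.1, dosage.shape), 0.0, 2.0)
    elif dosage_mode != "hard":
        raise ValueError("dosage_mode must be 'hard' or 'continuous'")

    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
             ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
    pick = rng.integers(0, len(pairs), size=n_snps)
    markers = pd.DataFrame({
        "snp": [f"snp{j + 1:05d}" for j in range(n_snps)],
        "chr": "1",
        "bp": 1 + spacing_bp * np.arange(n_snps),
        "a1": [pairs[i][0] for i in pick],
        "a2": [pairs[i][1] for i in pick],
    })
    ids = np.array([f"I{i + 1:04d}" for i in range(n_individuals)], dtype=object)
    return prs_engine.GenotypePanel(ids=ids, markers=markers, dosages=dosage)


# ---------------------------------------------------------------------------
# pseudo-GWAS
# ---------------------------------------------------------------------------

def simulate_gwas_summary(panel: prs_engine.GenotypePanel,
                          prop_causal: float = 0.3, effect_sd: float = 0.15,
                          seed: int = 0, n_gwas: int = 20_000) -> pd.DataFrame:
    """Point-normal pseudo-GWAS over the panel's SNPs.

    A fraction ``prop_causal`` of SNPs get true effects ~ N(0, effect_sd^2);
    estimates add sampling noise at the standard error implied by the pseudo
    sample size ``n_gwas`` and the SNP's allele frequency, and p-values are
    two-sided Wald.  For half the SNPs (at random) the reported effect allele
    is the panel's *other* allele with the sign flipped, so downstream
    scoring must reconcile alleles.  The extra column ``BETA_TRUE`` records
    the generating effect (ignored by the C+T reader).
    """
    if panel.n_snps == 0:
        raise ValueError("empty genotype panel")
    if not (0 < prop_causal <= 1):
        raise ValueError("prop_causal must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    m = panel.n_snps
    freq = np.clip(panel.counted_allele_freq(), 0.01, 0.99)
    causal = rng.random(m) < prop_causal
    beta_true = np.where(causal, rng.normal(0.0, effect_sd, m) if effect_sd > 0
                         else 0.0, 0.0)
    se = 1.0 / np.sqrt(n_gwas * 2.0 * freq * (1.0 - freq))
    beta_hat = beta_true + rng.normal(0.0, 1.0, m) * se
    p = np.clip(2.0 * stats.norm.sf(np.abs(beta_hat) / se), 1e-300, 1.0)

    flip = rng.random(m) < 0.5
    a1 = np.where(flip, panel.markers["a2"], panel.markers["a1"])
    a2 = np.where(flip, panel.markers["a1"], panel.markers["a2"])
    beta_rep = np.where(flip, -beta_hat, beta_hat)
    return pd.DataFrame({
        "SNP": panel.markers["snp"],
        "CHR": panel.markers["chr"],
        "BP": panel.markers["bp"],
        "A1": a1, "A2": a2,
        "BETA": beta_rep, "P": p,
        "BETA_TRUE": np.where(flip, -beta_true, beta_true),
    })


# ---------------------------------------------------------------------------
# adversity battery
# ---------------------------------------------------------------------------

SUBSCALES = (
    "ctq_sexual_abuse", "ctq_physical_abuse", "ctq_emotional_abuse",
    "ctq_emotional_neglect", "ctq_physical_neglect",
    "itec_sexual_abuse", "itec_physical_abuse", "itec_emotional_abuse",
    "itec_emotional_neglect", "itec_physical_neglect",
    "ceca_antipathy", "ceca_parental_discord", "ceca_bullying",
)

FACTOR_NAMES = ("intrafamilial_adversity", "deprivation", "threat", "sexual_abuse")

# simple-structure defaults: intrafamilial adversity (CECA antipathy/discord +
# ITEC emotional neglect), deprivation (physical/emotional neglect), threat
# (abuse + bullying), sexual abuse (the 2 sexual-abuse subscales).  Primary
# loadings 0.65 (0.85 for sexual abuse) calibrated once so a 4-component
# oblique solution at n = 197 explains ~63% of total variance.
_PRIMARY = {
    "intrafamilial_adversity": ("ceca_antipathy", "ceca_parental_discord",
                                "itec_emotional_neglect"),
    "deprivation": ("itec_physical_neglect", "ctq_physical_neglect",
                    "ctq_emotional_neglect"),
    "threat": ("ceca_bullying", "itec_emotional_abuse", "itec_physical_abuse",
               "ctq_emotional_abuse", "ctq_physical_abuse"),
    "sexual_abuse": ("ctq_sexual_abuse", "itec_sexual_abuse"),
}


def default_loading_matrix() -> np.ndarray:
    L = np.zeros((len(SUBSCALES), len(FACTOR_NAMES)))
    for k, fac in enumerate(FACTOR_NAMES):
        val = 0.85 if fac == "sexual_abuse" else 0.65
        for sub in _PRIMARY[fac]:
            L[SUBSCALES.index(sub), k] = val
    return L


DEFAULT_FACTOR_CORR = np.array([
    [1.00, 0.45, 0.50, 0.20],
    [0.45, 1.00, 0.45, 0.20],
    [0.50, 0.45, 1.00, 0.20],
    [0.20, 0.20, 0.20, 1.00],
])


@dataclass
class AdversityBattery:
    """n x 13 subscale score matrix with declared floor/ceiling bounds."""

    data: pd.DataFrame            # subject_id + one column per subscale
    bounds: tuple = (0.0, 100.0)
    loading_matrix: np.ndarray | None = None      # generating truth
    factor_corr: np.ndarray | None = None
    skewed_factor_index: int | None = None

    def __post_init__(self):
        sub = self.subscales()
        if sub.isna().any().any():
            raise ValueError("adversity battery contains missing values")
        lo, hi = self.bounds
        vals = sub.to_numpy()
        if (vals < lo - 1e-9).any() or (vals > hi + 1e-9).any():
            raise ValueError("subscale scores outside declared bounds")

    def subscales(self) -> pd.DataFrame:
        cols = [c for c in self.data.columns if c != "subject_id"]
        return self.data[cols]

    def to_csv(self, path: str) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, bounds: tuple = (0.0, 100.0)) -> "AdversityBattery":
        return cls(data=pd.read_csv(path), bounds=bounds)


def simulate_adversity(n: int, loading_matrix: np.ndarray | None = None,
                       factor_corr: np.ndarray | None = None,
                       skewed_factor_index: int | None = 3,
                       skew_severity: float = 1.0, seed: int = 0,
                       uniqueness: float | np.ndarray | None = None,
                       subject_ids: Sequence[str] | None = None) -> AdversityBattery:
    """Subscales = linear images of 4 correlated latent factors + noise.

    The factor at ``skewed_factor_index`` is floored before mixing:
    ``max(z - skew_severity, 0)``, standardized -- a heavy floor at "no
    exposure" with a right tail, the statistical signature of a sexual-abuse
    score in a non-clinical cohort.  ``skew_severity`` is the floor location
    in latent SD units (larger = heavier floor and stronger skew).

    ``uniqueness`` overrides the per-subscale noise variance (default
    ``1 - communality``; pass 0 for noise-free batteries in tests).  Scores
    are mapped to a bounded 0-100 scale (mean 50, SD 10, clipped).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    L = default_loading_matrix() if loading_matrix is None else np.asarray(loading_matrix, float)
    Phi = DEFAULT_FACTOR_CORR if factor_corr is None else np.asarray(factor_corr, float)
    p, k = L.shape
    if Phi.shape != (k, k):
        raise ValueError("factor_corr shape does not match loading columns")
    try:
        chol = np.linalg.cholesky(Phi)
    except np.linalg.LinAlgError as exc:
        raise ValueError("factor_corr must be positive definite") from exc

    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n, k)) @ chol.T
    if skewed_factor_index is not None:
        if not (0 <= skewed_factor_index < k):
            raise ValueError("skewed_factor_index out of range")
        w = np.maximum(F[:, skewed_factor_index] - skew_severity, 0.0)
        sd = w.std()
        if sd > 0:
            F[:, skewed_factor_index] = (w - w.mean()) / sd
        else:  # degenerate draw (tiny n): leave the latent unskewed
            warnings.warn("skew transform degenerate; factor left Gaussian")

    communality = np.einsum("ij,jk,ik->i", L, Phi, L)
    if uniqueness is None:
        psi = np.maximum(1.0 - communality, 1e-6)
    else:
        psi = np.broadcast_to(np.asarray(uniqueness, float), (p,)).copy()
        if (psi < 0).any():
            raise ValueError("uniqueness must be non-negative")
    X = F @ L.T + rng.standard_normal((n, p)) * np.sqrt(psi)

    scores = np.clip(50.0 + 10.0 * X, 0.0, 100.0)
    if subject_ids is None:
        subject_ids = [f"I{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame(scores, columns=list(SUBSCALES)[:p] if p == len(SUBSCALES)
                      else [f"sub{j + 1}" for j in range(p)])
    df.insert(0, "subject_id", list(subject_ids))
    return AdversityBattery(data=df, bounds=(0.0, 100.0), loading_matrix=L,
                            factor_corr=Phi, skewed_factor_index=skewed_factor_index)


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def regime_mean(truth: SimulationTruth, G: np.ndarray, E: np.ndarray) -> np.ndarray:
    """The regime's mean function (no covariates, no noise)."""
    r = truth.regime_id
    if r in NULL_REGIMES:
        mu = np.full_like(E, truth.beta0, dtype=float)
        if r in ("g_only", "g_plus_e"):
            mu = mu + truth.beta_G * G
        if r in ("e_only", "g_plus_e"):
            mu = mu + truth.beta_E * E
        return mu
    c = (np.min(E) if r.startswith("diathesis")
         else np.max(E) if r.startswith("vantage") else truth.c)
    return truth.beta0 + (truth.beta_E + truth.beta_S * G) * (E - c)


def simulate_outcome(G: np.ndarray, E: np.ndarray, covariates: np.ndarray | None,
                     truth: SimulationTruth,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """``Y = regime mean + gamma'X + N(0, sigma^2)``.

    G must already follow the [0, 1] susceptibility convention of the
    fitting side; E any finite score.  Deterministic given ``truth.seed``
    (or an explicit ``rng``).
    """
    G = np.asarray(G, float)
    E = np.asarray(E, float)
    if G.shape != E.shape:
        raise ValueError("G and E length mismatch")
    if not np.isfinite(E).all() or not np.isfinite(G).all():
        raise ValueError("non-finite G or E")
    if G.min() < -1e-9 or G.max() > 1 + 1e-9:
        raise ValueError("G must be rescaled to [0, 1]")
    mu = regime_mean(truth, G, E)
    if covariates is not None and np.size(covariates):
        X = np.atleast_2d(np.asarray(covariates, float))
        if X.shape[0] != len(G):
            raise ValueError("covariate rows must match G length")
        gamma = np.asarray(truth.gamma, float)
        if gamma.size != X.shape[1]:
            raise ValueError("gamma length must match covariate columns")
        mu = mu + X @ gamma
    elif truth.gamma and any(g != 0 for g in truth.gamma):
        raise ValueError("truth has covariate effects but no covariates given")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    return mu + rng.normal(0.0, truth.sigma, size=len(G))


def _signal_variances(truth: SimulationTruth, G: np.ndarray, E: np.ndarray,
                      covariates: np.ndarray | None) -> tuple[float, float]:
    """(v_sig, v_mean): unique-signal and full-mean variance of the regime.

    For GxE regimes the unique signal is the part of ``beta_S G (E - c)``
    orthogonal to {1, G, E} -- the variance only an interaction can explain;
    for null regimes it is the whole centered mean.
    """
    mu = regime_mean(truth, G, E)
    if covariates is not None and np.size(covariates):
        mu = mu + np.atleast_2d(covariates) @ np.asarray(truth.gamma, float)
    v_mean = float(np.var(mu))
    if truth.regime_id in NULL_REGIMES:
        return v_mean, v_mean
    c = (np.min(E) if truth.regime_id.startswith("diathesis")
         else np.max(E) if truth.regime_id.startswith("vantage") else truth.c)
    f_int = truth.beta_S * G * (E - c)
    D = np.column_stack([np.ones_like(G), G, E])
    coef, *_ = np.linalg.lstsq(D, f_int, rcond=None)
    return float(np.var(f_int - D @ coef)), v_mean


def max_attainable_r2(truth: SimulationTruth, G: np.ndarray, E: np.ndarray,
                      covariates: np.ndarray | None = None,
                      reliability: float = 1.0) -> float:
    """Largest unique-signal variance share reachable at zero residual noise.

    Regimes whose crossover sits at the environment boundary (diathesis,
    vantage) put most of their GxE term on the main-effect axis, so their
    unique interaction share is structurally bounded well below 1 no matter
    how small sigma is.
    """
    v_sig, v_mean = _signal_variances(truth, G, E, covariates)
    if v_mean <= 0:
        return 0.0
    return reliability * v_sig / v_mean


def sigma_for_target_r2(truth: SimulationTruth, G: np.ndarray, E: np.ndarray,
                        covariates: np.ndarray | None, target_r2: float,
                        reliability: float = 1.0,
                        clip_to_attainable: bool = False) -> float:
    """Latent residual SD so the regime's unique signal explains ``target_r2``.

    ``reliability`` folds measurement noise of ``(1 - alpha)/alpha`` times
    the model variance into the total, mimicking Cronbach-alpha attenuation.
    Raises if the target exceeds the attainable share (see
    ``max_attainable_r2``) unless ``clip_to_attainable``, which instead
    lowers the target to 95% of the cap.
    """
    if not (0 < target_r2 < 1):
        raise ValueError("target_r2 must lie in (0, 1)")
    if not (0 < reliability <= 1):
        raise ValueError("reliability must lie in (0, 1]")
    v_sig, v_mean = _signal_variances(truth, G, E, covariates)
    if v_sig <= 0:
        raise ValueError("regime has no unique signal; cannot target an R^2")
    cap = reliability * v_sig / v_mean if v_mean > 0 else 1.0
    if target_r2 >= cap:
        if not clip_to_attainable:
            raise ValueError(
                f"target_r2={target_r2} unattainable (cap ~{cap:.4f}) at "
                "these effect sizes")
        target_r2 = 0.95 * cap
    sigma_lat2 = reliability * (v_sig / target_r2) - v_mean
    return float(np.sqrt(sigma_lat2))


# ---------------------------------------------------------------------------
# end-to-end cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeSpec:
    """How one outcome column is generated."""

    regime: str = "e_only"
    reliability: float = 0.85         # Cronbach-alpha-style attenuation
    e_factor: int = 0                 # index into the retained env factors
    beta0: float = 0.0
    beta_G: float = 0.0
    beta_E: float = 0.5
    beta_S: float = 1.0
    c_quantile: float = 0.4           # DS crossover placement in E quantiles
    sigma: float = 1.0
    target_r2: float | None = None    # overrides sigma when set
    clip_r2: bool = False             # lower target_r2 to the attainable cap


def _default_outcomes() -> dict:
    # reliabilities follow the instrument alphas: CAPE positive .76, WSS
    # positive .85, WSS negative .84, SCL-90-R anxiety .81, depression .85
    return {
        "ple": OutcomeSpec(reliability=0.76, e_factor=0),
        "positive_schizotypy": OutcomeSpec(reliability=0.85, e_factor=2),
        "negative_schizotypy": OutcomeSpec(reliability=0.84, e_factor=1),
        "anxiety": OutcomeSpec(reliability=0.81, e_factor=0),
        "depression": OutcomeSpec(reliability=0.85, e_factor=2),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration for ``make_cohort`` (defaults = study scale)."""

    n: int = 197
    n_snps: int = 300
    maf: tuple = (0.05, 0.5)
    block_size: int = 5
    block_rho: float = 0.7
    prop_causal: float = 0.3
    effect_sd: float = 0.15
    gwas_n: int = 20_000
    clump_r2: float = 0.1
    window_kb: float = 1000.0
    thresholds: tuple = (0.001, 0.01, 0.05, 0.1)
    score_set: str = "PRS"
    g_threshold: float = 0.05          # which threshold's score drives truth
    n_factors: int = 4
    skew_cutoff: float = 2.0
    skew_severity: float = 1.0
    n_pcs: int = 2
    pc_effect: float = 0.0             # gamma for each simulated ancestry PC
    outcomes: Mapping = field(default_factory=_default_outcomes)


@dataclass
class CohortTable:
    """Per-subject modelling table with its generating truth attached."""

    data: pd.DataFrame
    truths: dict                        # outcome -> SimulationTruth
    prs_cols: dict                      # threshold -> column name
    env_cols: list
    outcome_cols: list
    covariate_cols: list
    g_col: str
    e_col_for: dict                     # outcome -> env column used as truth E
    meta: dict = field(default_factory=dict)

    def to_csv(self, path: str, truth_path: str | None = None) -> None:
        self.data.to_csv(path, index=False)
        if truth_path:
            payload = {
                "truths": {k: asdict(v) for k, v in self.truths.items()},
                "prs_cols": {str(k): v for k, v in self.prs_cols.items()},
                "env_cols": self.env_cols,
                "outcome_cols": self.outcome_cols,
                "covariate_cols": self.covariate_cols,
                "g_col": self.g_col,
                "e_col_for": self.e_col_for,
                "meta": self.meta,
            }
            with open(truth_path, "w") as fh:
                json.dump(payload, fh, indent=2)

    @classmethod
    def from_csv(cls, path: str, truth_path: str) -> "CohortTable":
        data = pd.read_csv(path)
        with open(truth_path) as fh:
            payload = json.load(fh)
        truths = {k: SimulationTruth(**{**v, "gamma": tuple(v["gamma"])})
                  for k, v in payload["truths"].items()}
        return cls(data=data, truths=truths,
                   prs_cols={float(k): v for k, v in payload["prs_cols"].items()},
                   env_cols=payload["env_cols"],
                   outcome_cols=payload["outcome_cols"],
                   covariate_cols=payload["covariate_cols"],
                   g_col=payload["g_col"],
                   e_col_for=payload["e_col_for"],
                   meta=payload.get("meta", {}))


def make_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortTable:
    """Full composition: genotypes -> pseudo-GWAS -> C+T PRS -> adversity
    battery -> oblique factors + skew screen -> outcomes under each outcome's
    regime, plus simulated ancestry PCs.

    The susceptibility score driving every outcome's truth is the PRS at
    ``config.g_threshold``, min-max rescaled to [0, 1]; the environment is
    the retained factor named by each ``OutcomeSpec.e_factor``.
    """
    cfg = config or CohortConfig()
    master = np.random.default_rng(seed)
    sub = master.integers(0, 2 ** 31 - 1, size=6 + len(cfg.outcomes))

    panel = simulate_genotypes(cfg.n, cfg.n_snps, *cfg.maf,
                               block_size=cfg.block_size,
                               block_rho=cfg.block_rho, seed=int(sub[0]))
    gwas = simulate_gwas_summary(panel, prop_causal=cfg.prop_causal,
                                 effect_sd=cfg.effect_sd, seed=int(sub[1]),
                                 n_gwas=cfg.gwas_n)
    profile = prs_engine.construct_prs(
        panel, gwas, r2_threshold=cfg.clump_r2, window_kb=cfg.window_kb,
        p_thresholds=cfg.thresholds, standardize=True)

    battery = simulate_adversity(cfg.n, skew_severity=cfg.skew_severity,
                                 seed=int(sub[2]), subject_ids=panel.ids)
    solution = skewness_screen(fit_pca_oblique(battery, cfg.n_factors),
                               cutoff=cfg.skew_cutoff)
    env = solution.retained_scores().to_numpy()
    if env.shape[1] == 0:
        raise RuntimeError("skewness screen retained no environment factors")
    env_cols = [f"adv_f{j + 1}" for j in range(env.shape[1])]

    pcs = np.random.default_rng(int(sub[3])).standard_normal((cfg.n, cfg.n_pcs))
    cov_cols = [f"PC{j + 1}" for j in range(cfg.n_pcs)]

    df = pd.DataFrame({"subject_id": panel.ids})
    prs_cols = {}
    for t in cfg.thresholds:
        col = f"{cfg.score_set}_p{t:g}"
        df[col] = profile.scores[t].to_numpy()
        prs_cols[t] = col
    for j, c in enumerate(env_cols):
        df[c] = env[:, j]
    for j, c in enumerate(cov_cols):
        df[c] = pcs[:, j]

    g_col = prs_cols[cfg.g_threshold]
    g_raw = df[g_col].to_numpy()
    G = (g_raw - g_raw.min()) / (g_raw.max() - g_raw.min())

    truths, e_col_for = {}, {}
    for i, (name, spec_) in enumerate(cfg.outcomes.items()):
        e_idx = spec_.e_factor % env.shape[1]
        E = env[:, e_idx]
        e_col_for[name] = env_cols[e_idx]
        strong = spec_.regime.endswith("_strong")
        in_null = spec_.regime in NULL_REGIMES
        truth = SimulationTruth(
            regime_id=spec_.regime,
            beta0=spec_.beta0,
            beta_G=spec_.beta_G if spec_.regime in ("g_only", "g_plus_e") else 0.0,
            beta_E=(0.0 if strong or spec_.regime in ("intercept", "g_only")
                    else spec_.beta_E),
            beta_S=0.0 if in_null else spec_.beta_S,
            c=(float(np.quantile(E, spec_.c_quantile))
               if spec_.regime.startswith("ds") else 0.0),
            sigma=spec_.sigma,
            gamma=(cfg.pc_effect,) * cfg.n_pcs,
            seed=int(sub[6 + i]),
        )
        if spec_.target_r2 is not None:
            truth = replace(truth, sigma=sigma_for_target_r2(
                truth, G, E, pcs, spec_.target_r2,
                reliability=spec_.reliability,
                clip_to_attainable=spec_.clip_r2))
        rng_out = np.random.default_rng(truth.seed)
        y = simulate_outcome(G, E, pcs, truth, rng=rng_out)
        if spec_.reliability < 1.0:
            model_var = float(np.var(regime_mean(truth, G, E)
                                     + pcs @ np.asarray(truth.gamma))) \
                + truth.sigma ** 2
            noise_sd = np.sqrt((1.0 - spec_.reliability) / spec_.reliability * model_var)
            y = y + rng_out.normal(0.0, noise_sd, cfg.n)
        df[name] = y
        truths[name] = truth

    return CohortTable(
        data=df, truths=truths, prs_cols=prs_cols, env_cols=env_cols,
        outcome_cols=list(cfg.outcomes), covariate_cols=cov_cols,
        g_col=g_col, e_col_for=e_col_for,
        meta={"seed": int(seed), "n": cfg.n,
              "snp_counts": {str(k): v for k, v in profile.snp_counts.items()},
              "var_explained": solution.var_explained,
              "retained_factors": int(env.shape[1]),
              "g_threshold": cfg.g_threshold},
    )


def simulate_null_cohort(n: int = 197, n_prs: int = 4, n_env: int = 3,
                         n_outcomes: int = 5, seed: int = 0,
                         thresholds: Sequence[float] = (0.001, 0.01, 0.05, 0.1),
                         ) -> CohortTable:
    """Fast all-null cohort: every column independent standard normal.

    The shape mirrors ``make_cohort`` output (PRS columns per threshold, env
    factors, outcomes, 2 PCs) so pipeline calibration studies can run many
    replicates cheaply.
    """
    rng = np.random.default_rng(seed)
    thresholds = list(thresholds)[:n_prs]
    df = pd.DataFrame({"subject_id": [f"I{i + 1:04d}" for i in range(n)]})
    prs_cols = {}
    for t in thresholds:
        col = f"PRS_p{t:g}"
        df[col] = rng.standard_normal(n)
        prs_cols[t] = col
    env_cols = [f"adv_f{j + 1}" for j in range(n_env)]
    for c in env_cols:
        df[c] = rng.standard_normal(n)
    out_cols = [f"y{j + 1}" for j in range(n_outcomes)]
    for c in out_cols:
        df[c] = rng.standard_normal(n)
    for c in ("PC1", "PC2"):
        df[c] = rng.standard_normal(n)
    truths = {c: SimulationTruth(regime_id="intercept", sigma=1.0, seed=seed)
              for c in out_cols}
    return CohortTable(data=df, truths=truths, prs_cols=prs_cols,
                       env_cols=env_cols, outcome_cols=out_cols,
                       covariate_cols=["PC1", "PC2"],
                       g_col=prs_cols[thresholds[-1]],
                       e_col_for={c: env_cols[0] for c in out_cols},
                       meta={"seed": int(seed), "null": True})
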