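"""Polygenic score construction by clumping + thresholding (C+T).

A polygenic score is the weighted sum of risk-allele dosages, with weights
taken from an external GWAS.  Construction follows the classical C+T recipe:

1. *Clumping* greedily prunes the summary statistics so that no two retained
   SNPs within a physical window are in linkage disequilibrium (LD) above an
   r-squared cutoff, always keeping the SNP with the smaller p-value.
2. *Thresholding* forms nested SNP subsets at a ladder of GWAS p-value
   cutoffs (default .001, .01, .05, .1).
3. *Scoring* sums ``beta * dosage`` per individual after reconciling the
   panel's counted allele with the GWAS effect allele (allele swap, strand
   flip, and strand-ambiguous cases are handled by policy).

LD can come from a genotype panel (r-squared = squared Pearson correlation of
dosages) or from a precomputed long-format pair table, so no external
reference panel is required at run time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Collection, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "PanelLD",
    "TableLD",
    "PrsProfile",
    "read_gwas",
    "write_gwas",
    "validate_gwas",
    "clump",
    "threshold_select",
    "score",
    "construct_prs",
]

GWAS_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "BETA", "P")
DEFAULT_THRESHOLDS = (0.001, 0.01, 0.05, 0.1)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Individuals x SNPs dosage matrix with marker metadata.

    ``markers`` has columns ``snp, chr, bp, a1, a2`` where ``a1`` is the
    counted allele (dosages count copies of ``a1``) and ``bp`` is a 1-based
    physical position.  Dosages live in [0, 2]; NaN marks missing calls.
    """

    ids: np.ndarray
    markers: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.markers)} markers"
            )
        missing = {"snp", "chr", "bp", "a1", "a2"} - set(self.markers.columns)
        if missing:
            raise ValueError(f"marker table lacks columns {sorted(missing)}")
        if self.markers["snp"].duplicated().any():
            raise ValueError("duplicate SNP ids in marker table")
        if (self.markers["bp"] <= 0).any():
            raise ValueError("marker positions must be strictly positive")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < -1e-9) | (self.dosages > 2 + 1e-9)
        if bad.any():
            raise ValueError("dosages must lie in [0, 2]")
        self.markers = self.markers.reset_index(drop=True)
        self._col = {s: j for j, s in enumerate(self.markers["snp"])}

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    def column(self, snp: str) -> np.ndarray:
        return self.dosages[:, self._col[snp]]

    def counted_allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per SNP (missing-aware)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    # -- I/O ----------------------------------------------------------------

    def to_raw(self, path: str) -> None:
        """Write the PLINK ``.raw`` text dialect (space delimited)."""
        cols = [f"{r.snp}_{r.a1}" for r in self.markers.itertuples()]
        df = pd.DataFrame(self.dosages, columns=cols)
        df.insert(0, "PHENOTYPE", -9)
        df.insert(0, "SEX", 0)
        df.insert(0, "MAT", 0)
        df.insert(0, "PAT", 0)
        df.insert(0, "IID", self.ids)
        df.insert(0, "FID", self.ids)
        df.to_csv(path, sep=" ", index=False, na_rep="NA")

    @classmethod
    def from_raw(cls, path: str, markers: pd.DataFrame | None = None) -> "GenotypePanel":
        """Read a PLINK ``.raw`` file.

        ``.raw`` files carry no positions; pass a marker table to restore
        chromosome/position/other-allele metadata, otherwise placeholders
        (chr "0", bp = column index + 1, a2 "N") are used.
        """
        df = pd.read_csv(path, sep=r"\s+")
        snp_cols = [c for c in df.columns
                    if c not in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")]
        snps = [c.rsplit("_", 1)[0] for c in snp_cols]
        a1s = [c.rsplit("_", 1)[1] for c in snp_cols]
        if markers is None:
            markers = pd.DataFrame({
                "snp": snps, "chr": "0",
                "bp": np.arange(1, len(snps) + 1),
                "a1": a1s, "a2": "N",
            })
        else:
            markers = markers.set_index("snp").loc[snps].reset_index()
        return cls(ids=df["IID"].to_numpy(dtype=object),
                   markers=markers,
                   dosages=df[snp_cols].to_numpy(dtype=float))

    def to_csv(self, dosage_path: str, marker_path: str) -> None:
        pd.DataFrame(self.dosages, index=pd.Index(self.ids, name="id"),
                     columns=self.markers["snp"]).to_csv(dosage_path)
        self.markers.to_csv(marker_path, index=False)

    @classmethod
    def from_csv(cls, dosage_path: str, marker_path: str) -> "GenotypePanel":
        dos = pd.read_csv(dosage_path, index_col=0)
        markers = pd.read_csv(marker_path)
        markers = markers.set_index("snp").loc[dos.columns]
        markers.index.name = "snp"   # dos.columns carries no name
        markers = markers.reset_index()
        return cls(ids=dos.index.to_numpy(dtype=object), markers=markers,
                   dosages=dos.to_numpy(dtype=float))


def validate_gwas(gwas: pd.DataFrame) -> pd.DataFrame:
    """Check a GWAS summary table (SNP, CHR, BP, A1, A2, BETA, P)."""
    missing = set(GWAS_COLUMNS) - set(gwas.columns)
    if missing:
        raise ValueError(f"GWAS table lacks columns {sorted(missing)}")
    if gwas["SNP"].duplicated().any():
        raise ValueError("duplicate SNP ids in GWAS table")
    p = gwas["P"].to_numpy(dtype=float)
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("GWAS p-values must lie in (0, 1]")
    if (gwas["A1"].astype(str) == gwas["A2"].astype(str)).any():
        raise ValueError("effect and other allele must differ")
    return gwas


def read_gwas(path: str) -> pd.DataFrame:
    return validate_gwas(pd.read_csv(path, sep="\t"))


def write_gwas(gwas: pd.DataFrame, path: str) -> None:
    validate_gwas(gwas)
    gwas.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LD sources
# ---------------------------------------------------------------------------

class PanelLD:
    """LD from a genotype panel: r2 = squared Pearson correlation of dosages."""

    def __init__(self, panel: GenotypePanel):
        X = panel.dosages.copy()
        # mean-impute missing dosages before correlating
        col_mean = np.nanmean(X, axis=0)
        nan_idx = np.where(np.isnan(X))
        X[nan_idx] = np.take(col_mean, nan_idx[1])
        X = X - X.mean(axis=0)
        norm = np.sqrt((X ** 2).sum(axis=0))
        norm[norm == 0] = np.nan  # monomorphic: correlation undefined -> r2 0
        self._Z = X / norm
        self._col = dict(panel._col)

    def has(self, snp: str) -> bool:
        return snp in self._col

    def r2(self, snp: str, others: Sequence[str]) -> np.ndarray:
        zi = self._Z[:, self._col[snp]]
        cols = [self._col[s] for s in others]
        r = zi @ self._Z[:, cols]
        return np.nan_to_num(r, nan=0.0) ** 2


class TableLD:
    """LD from a precomputed long-format pair table (snp_a, snp_b, r2).

    Pairs absent from the table are taken to be unlinked (r2 = 0).
    """

    def __init__(self, table: pd.DataFrame):
        missing = {"snp_a", "snp_b", "r2"} - set(table.columns)
        if missing:
            raise ValueError(f"LD table lacks columns {sorted(missing)}")
        self._r2 = {}
        self._snps = set()
        for a, b, r2 in zip(table["snp_a"], table["snp_b"], table["r2"]):
            key = (a, b) if a <= b else (b, a)
            self._r2[key] = float(r2)
            self._snps.update((a, b))

    def has(self, snp: str) -> bool:
        return snp in self._snps

    def r2(self, snp: str, others: Sequence[str]) -> np.ndarray:
        out = np.empty(len(others))
        for j, o in enumerate(others):
            key = (snp, o) if snp <= o else (o, snp)
            out[j] = self._r2.get(key, 0.0)
        return out


# ---------------------------------------------------------------------------
# C + T
# ---------------------------------------------------------------------------

def clump(gwas: pd.DataFrame, ld, r2_threshold: float = 0.1,
          window_kb: float = 1000.0, missing: str = "drop") -> list[str]:
    """Greedy LD clumping of a GWAS summary table.

    SNPs are visited in ascending p-value order (ties broken by SNP id for
    determinism).  Each unclaimed SNP becomes an index SNP and claims every
    unclaimed SNP on the same chromosome within +-``window_kb`` whose r2 with
    it is >= ``r2_threshold``.  Returns the index SNPs in p-value order.

    ``missing`` controls SNPs the LD source cannot resolve: ``"drop"`` (warn
    and exclude, default) or ``"strict"`` (raise).
    """
    validate_gwas(gwas)
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must lie in (0, 1]")
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")

    resolvable = gwas["SNP"].map(ld.has)
    if not resolvable.all():
        absent = gwas.loc[~resolvable, "SNP"].tolist()
        if missing == "strict":
            raise KeyError(f"SNPs absent from LD source: {absent[:10]}...")
        warnings.warn(f"dropping {len(absent)} SNPs absent from LD source")
        gwas = gwas[resolvable]

    order = gwas.sort_values(["P", "SNP"], kind="mergesort")
    snp = order["SNP"].to_numpy(dtype=object)
    chrom = order["CHR"].to_numpy(dtype=object)
    bp = order["BP"].to_numpy(dtype=float)
    window_bp = window_kb * 1000.0

    claimed = np.zeros(len(order), dtype=bool)
    retained: list[str] = []
    for i in range(len(order)):
        if claimed[i]:
            continue
        retained.append(snp[i])
        claimed[i] = True
        in_win = (~claimed) & (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= window_bp)
        idx = np.where(in_win)[0]
        if idx.size:
            r2 = ld.r2(snp[i], snp[idx])
            claimed[idx[r2 >= r2_threshold]] = True
    return retained


def threshold_select(gwas: pd.DataFrame, retained: Collection[str],
                     p_thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                     inclusive: bool = False) -> dict[float, list[str]]:
    """Nested per-threshold SNP subsets: ``{t: [s in retained: p(s) < t]}``.

    Comparison is strict ``<`` by default (``inclusive=True`` switches to
    ``<=``).  Thresholds must be ascending and in (0, 1].
    """
    thresholds = [float(t) for t in p_thresholds]
    if any(not (0 < t <= 1) for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    if not retained:
        warnings.warn("empty retained set: all threshold subsets are empty")
    pmap = dict(zip(gwas["SNP"], gwas["P"].astype(float)))
    out: dict[float, list[str]] = {}
    for t in thresholds:
        if inclusive:
            out[t] = [s for s in retained if pmap[s] <= t]
        else:
            out[t] = [s for s in retained if pmap[s] < t]
    return out


@dataclass
class PrsProfile:
    """Per-individual polygenic scores at each p-value threshold."""

    ids: np.ndarray
    scores: pd.DataFrame                 # n x T, columns = threshold labels
    snp_counts: dict = field(default_factory=dict)
    standardization: dict = field(default_factory=dict)   # label -> (mean, sd)
    dropped: dict = field(default_factory=dict)           # label -> {snp: reason}
    standardized: bool = False

    def to_csv(self, path: str) -> None:
        df = self.scores.copy()
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False)

    def log_json(self) -> str:
        return json.dumps({
            "snp_counts": {str(k): v for k, v in self.snp_counts.items()},
            "standardized": self.standardized,
            "standardization": {str(k): list(v) for k, v in self.standardization.items()},
            "dropped": {str(k): v for k, v in self.dropped.items()},
        }, indent=2)


def _reconcile(p1: str, p2: str, g1: str, g2: str) -> str:
    """Orient panel alleles (p1 counted, p2 other) against GWAS (g1 effect).

    Returns ``"direct"`` (use dosage), ``"swap"`` (use 2 - dosage),
    ``"ambiguous"`` (palindromic A/T or C/G pair: strand unresolvable) or
    ``"irreconcilable"``.
    """
    known = set(_COMPLEMENT)
    if {p1, p2} <= known and p1 == _COMPLEMENT.get(p2):
        return "ambiguous"
    if (p1, p2) == (g1, g2):
        return "direct"
    if (p1, p2) == (g2, g1):
        return "swap"
    if {p1, p2} <= known and {g1, g2} <= known:
        c1, c2 = _COMPLEMENT[p1], _COMPLEMENT[p2]
        if (c1, c2) == (g1, g2):
            return "direct"
        if (c1, c2) == (g2, g1):
            return "swap"
    return "irreconcilable"


def score(panel: GenotypePanel, gwas: pd.DataFrame,
          snp_sets: Mapping | Collection[str], standardize: bool = True,
          allele_policy: str = "drop") -> PrsProfile:
    """Score individuals: ``sum_s beta_s * d'_is`` over each SNP subset.

    ``d'`` is the dosage oriented to the GWAS effect allele (``2 - d`` when
    the panel counts the other allele).  Missing dosages are mean-imputed per
    SNP.  ``allele_policy`` governs strand-ambiguous (A/T, C/G) pairs:
    ``"drop"`` (default, with warning), ``"keep"`` (assume same strand) or
    ``"strict"`` (raise).  Irreconcilable pairs always drop (or raise under
    ``"strict"``).

    ``snp_sets`` may be a mapping ``label -> SNP collection`` (one score
    column per label) or a single collection (column label ``"score"``).
    """
    validate_gwas(gwas)
    if not isinstance(snp_sets, Mapping):
        snp_sets = {"score": list(snp_sets)}
    grows = gwas.set_index("SNP")
    n = panel.n_individuals

    cols, counts, stand, dropped_all = {}, {}, {}, {}
    for label, snps in snp_sets.items():
        total = np.zeros(n)
        used = 0
        dropped: dict[str, str] = {}
        for s in snps:
            if s not in panel._col:
                dropped[s] = "absent_from_panel"
                continue
            if s not in grows.index:
                raise KeyError(f"SNP {s} not in GWAS table")
            row = grows.loc[s]
            mrow = panel.markers.iloc[panel._col[s]]
            orient = _reconcile(str(mrow["a1"]), str(mrow["a2"]),
                                str(row["A1"]), str(row["A2"]))
            if orient == "ambiguous":
                if allele_policy == "strict":
                    raise ValueError(f"strand-ambiguous alleles for {s}")
                if allele_policy == "drop":
                    dropped[s] = "strand_ambiguous"
                    continue
                orient = "direct"  # "keep": assume same strand
            if orient == "irreconcilable":
                if allele_policy == "strict":
                    raise ValueError(f"irreconcilable alleles for {s}")
                dropped[s] = "irreconcilable_alleles"
                continue
            d = panel.column(s).copy()
            if np.isnan(d).any():
                d[np.isnan(d)] = np.nanmean(d) if np.isfinite(np.nanmean(d)) else 1.0
            if orient == "swap":
                d = 2.0 - d
            total += float(row["BETA"]) * d
            used += 1
        if dropped:
            warnings.warn(
                f"{label}: dropped {len(dropped)} SNPs ({set(dropped.values())})")
        if standardize:
            mu, sd = total.mean(), total.std(ddof=0)
            if sd > 0:
                total = (total - mu) / sd
            else:
                warnings.warn(f"{label}: zero-variance score left unstandardized")
                mu, sd = 0.0, 1.0
            stand[label] = (float(mu), float(sd))
        cols[label] = total
        counts[label] = used
        dropped_all[label] = dropped

    return PrsProfile(ids=panel.ids.copy(),
                      scores=pd.DataFrame(cols),
                      snp_counts=counts,
                      standardization=stand,
                      dropped=dropped_all,
                      standardized=standardize)


def construct_prs(panel: GenotypePanel, gwas: pd.DataFrame, ld=None,
                  r2_threshold: float = 0.1, window_kb: float = 1000.0,
                  p_thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                  standardize: bool = True,
                  allele_policy: str = "drop") -> PrsProfile:
    """Full C+T: clump, threshold, score.  LD defaults to the panel itself."""
    if ld is None:
        ld = PanelLD(panel)
    retained = clump(gwas, ld, r2_threshold=r2_threshold, window_kb=window_kb)
    sets = threshold_select(gwas, retained, p_thresholds)
    return score(panel, gwas, sets, standardize=standardize,
                 allele_policy=allele_policy)
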