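"""Polygenic risk score construction and threshold selection.

PRSice-style workflow: P-value-informed LD clumping of the discovery GWAS
(r^2 cutoff 0.1 in a 250-kb window by default), additive dosage-weighted
scoring across a high-resolution grid of 103 P-value thresholds, a
case-control logistic scan reporting Nagelkerke's pseudo-R^2 per threshold,
and the partition of a discovery SNP selection into the subset shared with a
second disorder and the disorder-specific remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genoqc import AMBIGUOUS_PAIRS, DosageMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SummaryStatTable:
    """Per-SNP discovery GWAS records: id, map, alleles, log-odds beta, P."""

    table: pd.DataFrame  # columns SNP, CHR, BP, A1, A2, BETA, P

    REQUIRED = ("SNP", "CHR", "BP", "A1", "A2", "BETA", "P")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns {missing}")
        t = self.table
        if t["SNP"].duplicated().any():
            dups = t.loc[t["SNP"].duplicated(), "SNP"].tolist()
            raise ValueError(f"duplicate SNP ids in summary statistics: {dups[:5]}")
        p = t["P"].to_numpy(dtype=float)
        if len(t) and (np.any(p <= 0) or np.any(p > 1)):
            raise ValueError("P values must lie in (0, 1]")
        if len(t) and (t["A1"].astype(str) == t["A2"].astype(str)).any():
            raise ValueError("effect and other allele identical for some SNP")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def read_tsv(cls, path, or_column: bool = False) -> "SummaryStatTable":
        """Read a GWAS summary TSV; with ``or_column`` the effect column is
        an odds ratio and is log-transformed to the beta scale."""
        df = pd.read_csv(path, sep="\t")
        if or_column:
            if "OR" not in df.columns:
                raise ValueError("or_column=True but no OR column present")
            df = df.assign(BETA=np.log(df["OR"].to_numpy(dtype=float)))
        return cls(df[list(cls.REQUIRED)].copy())

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def make_grid() -> np.ndarray:
    """High-resolution P_T grid: multiples of 0.005 in (0, 0.5] plus
    {1e-5, 1e-4, 1e-3}, ascending — 103 thresholds in total.

    A threshold of exactly 0 would select no SNPs and is excluded.
    """
    grid = np.concatenate([[1e-5, 1e-4, 1e-3],
                           np.arange(1, 101) * 0.005])
    return np.sort(grid)


@dataclass
class ClumpResult:
    """Outcome of greedy P-informed LD clumping."""

    retained: list[str]
    absorbed: pd.DataFrame  # columns snp, index_snp, r2

    def retained_set(self) -> set[str]:
        return set(self.retained)


@dataclass
class PRSProfile:
    """Per-subject scores over the threshold grid for one SNP selection."""

    subject_ids: list[str]
    thresholds: np.ndarray
    scores: np.ndarray          # (n_subjects, n_thresholds)
    n_snps: np.ndarray          # per threshold
    label: str = "ASD"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite PRS")
        if np.any(np.diff(self.n_snps) < 0):
            raise ValueError("n_snps must be non-decreasing in P_T")

    def column(self, p_t: float) -> np.ndarray:
        j = int(np.argmin(np.abs(self.thresholds - p_t)))
        if not np.isclose(self.thresholds[j], p_t):
            raise KeyError(f"threshold {p_t} not in profile")
        return self.scores[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=pd.Index(self.subject_ids, name="subject"),
            columns=[f"{self.label}_pT_{t:g}" for t in self.thresholds])


@dataclass
class ScanResult:
    """Per-threshold logistic association of a PRS with case status."""

    table: pd.DataFrame            # index p_t; columns p, nagelkerke_r2, n_snps, converged
    selected: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

def _dosage_r2(values: np.ndarray, i: int, js: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage column i and columns js."""
    x = values[:, i]
    y = values[:, js]
    x = x - x.mean()
    y = y - y.mean(axis=0)
    denom = np.sqrt(np.sum(x**2) * np.sum(y**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (x @ y) / denom, 0.0)
    return r**2


def clump(stats: SummaryStatTable, ld_source: DosageMatrix,
          r2_cutoff: float = 0.1, window_kb: float = 250.0) -> ClumpResult:
    """Greedy P-value-informed LD clumping.

    SNPs are visited by ascending P (ties: ascending position, then id);
    each unclaimed SNP becomes an index SNP and claims every unclaimed SNP
    on its chromosome within the window whose squared dosage correlation
    with it exceeds ``r2_cutoff``.  LD comes from the target-sample dosages.
    """
    t = stats.table
    missing = [s for s in t["SNP"] if s not in set(ld_source.snp_ids)]
    if missing:
        raise KeyError(f"SNPs absent from LD source: {missing[:5]}")

    order = t.sort_values(["P", "BP", "SNP"], kind="mergesort").index.to_numpy()
    col_of = {s: ld_source.snp_index(s) for s in t["SNP"]}
    # mean-impute missing dosages so correlations are defined
    values = ld_source.values
    if np.any(~np.isfinite(values)):
        values = np.where(np.isfinite(values), values,
                          np.nanmean(values, axis=0, keepdims=True))

    chrom = t["CHR"].astype(str).to_numpy()
    pos = t["BP"].to_numpy(dtype=np.int64)
    snp = t["SNP"].to_numpy()
    window = int(window_kb * 1000)

    claimed = np.zeros(len(t), dtype=bool)
    retained: list[str] = []
    absorbed_rows = []
    for idx in order:
        if claimed[idx]:
            continue
        claimed[idx] = True
        retained.append(snp[idx])
        near = np.flatnonzero((chrom == chrom[idx]) & ~claimed
                              & (np.abs(pos - pos[idx]) <= window))
        if near.size == 0:
            continue
        cols = np.array([col_of[s] for s in snp[near]])
        r2 = _dosage_r2(values, col_of[snp[idx]], cols)
        hit = near[r2 > r2_cutoff]
        for h, r2v in zip(hit, r2[r2 > r2_cutoff]):
            claimed[h] = True
            absorbed_rows.append((snp[h], snp[idx], float(r2v)))
    absorbed = pd.DataFrame(absorbed_rows, columns=["snp", "index_snp", "r2"])
    return ClumpResult(retained=retained, absorbed=absorbed)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _align_dosage(dosages: DosageMatrix, stats_row) -> np.ndarray | None:
    """Dosage of the stats effect allele, or None if unresolvable/ambiguous."""
    j = dosages.snp_index(stats_row.SNP)
    ta1, ta2 = dosages.a1[j], dosages.a2[j]
    if (ta1, ta2) in AMBIGUOUS_PAIRS:
        return None
    d = dosages.values[:, j]
    if np.any(~np.isfinite(d)):
        mean = np.nanmean(d)
        d = np.where(np.isfinite(d), d, mean)
    if ta1 == stats_row.A1 and ta2 == stats_row.A2:
        return d
    if ta1 == stats_row.A2 and ta2 == stats_row.A1:
        return 2.0 - d
    return None


def score(dosages: DosageMatrix, stats: SummaryStatTable, clumped: ClumpResult,
          p_t: float, snp_subset: set[str] | None = None) -> pd.Series:
    """Additive dosage-weighted PRS at one threshold (PRSice convention).

    Sums aligned_dosage x beta over clump-retained SNPs with P <= p_t,
    optionally intersected with ``snp_subset``.  Strand-ambiguous (A/T, C/G)
    and allele-unresolvable SNPs are dropped with a logged count; missing
    dosages are replaced by the SNP's mean dosage.
    """
    t = stats.table
    keep = t["SNP"].isin(clumped.retained_set()) & (t["P"] <= p_t)
    if snp_subset is not None:
        keep &= t["SNP"].isin(snp_subset)
    rows = t[keep]
    total = np.zeros(dosages.n_subjects)
    used = 0
    dropped = 0
    for row in rows.itertuples():
        d = _align_dosage(dosages, row)
        if d is None:
            dropped += 1
            continue
        total += d * row.BETA
        used += 1
    if dropped:
        logger.info("score: dropped %d ambiguous/unresolvable SNPs at P_T=%g",
                    dropped, p_t)
    if used == 0:
        raise ValueError(f"all SNPs dropped at P_T={p_t}: empty score")
    s = pd.Series(total, index=pd.Index(dosages.subject_ids, name="subject"))
    s.attrs["n_snps"] = used
    return s


def score_profile(dosages: DosageMatrix, stats: SummaryStatTable,
                  clumped: ClumpResult, thresholds: np.ndarray | None = None,
                  snp_subset: set[str] | None = None,
                  label: str = "ASD") -> PRSProfile:
    """Score every threshold of the grid into one profile.

    Thresholds at which the selection is empty carry a zero score and
    n_snps = 0 (the scan skips them).
    """
    thresholds = make_grid() if thresholds is None else np.asarray(thresholds, float)
    scores = np.zeros((dosages.n_subjects, len(thresholds)))
    n_snps = np.zeros(len(thresholds), dtype=int)
    for j, p_t in enumerate(thresholds):
        try:
            s = score(dosages, stats, clumped, p_t, snp_subset=snp_subset)
        except ValueError:
            continue
        scores[:, j] = s.to_numpy()
        n_snps[j] = s.attrs["n_snps"]
    return PRSProfile(subject_ids=list(dosages.subject_ids),
                      thresholds=thresholds, scores=scores,
                      n_snps=n_snps, label=label)


# ---------------------------------------------------------------------------
# Nagelkerke pseudo-R^2 and the case-control scan
# ---------------------------------------------------------------------------

def nagelkerke_r2(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke's rescaled likelihood-ratio R^2.

    R^2 = (1 - exp(2(ll_null - ll_full)/n)) / (1 - exp(2 ll_null / n)).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if ll_full < ll_null - 1e-9:
        raise ValueError("ll_full must be >= ll_null")
    if ll_null == 0.0:
        raise ValueError("degenerate null likelihood (ll_null = 0)")
    num = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    den = 1.0 - np.exp(2.0 * ll_null / n)
    return float(num / den)


def scan(profile: PRSProfile, status: np.ndarray,
         covariates: pd.DataFrame | None = None, top_k: int = 10) -> ScanResult:
    """Logistic case-control association at every threshold.

    Per P_T: logistic regression of status on [score, covariates]; the
    association P is the Wald test of the score coefficient and Nagelkerke
    R^2 compares the full fit with the covariates-only fit.  The ``top_k``
    thresholds with smallest P are selected (ties: smaller P_T).
    Non-converged or separated thresholds are flagged and excluded from
    selection.
    """
    y = np.asarray(status, dtype=float)
    n = len(y)
    if covariates is not None:
        c = covariates.to_numpy(dtype=float)
        x_null = sm.add_constant(c, has_constant="add")
    else:
        x_null = np.ones((n, 1))
    null_fit = sm.Logit(y, x_null).fit(disp=0)
    ll_null_cov = float(null_fit.llf)

    rows = []
    for j, p_t in enumerate(profile.thresholds):
        if profile.n_snps[j] == 0:
            rows.append((p_t, np.nan, np.nan, 0, False))
            continue
        x = np.column_stack([profile.scores[:, j]] +
                            ([c] if covariates is not None else []))
        x = sm.add_constant(x, has_constant="add")
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
            converged = bool(fit.mle_retvals.get("converged", False)) and \
                np.all(np.isfinite(fit.bse))
        except Exception:  # perfect separation raises in statsmodels
            converged = False
        if not converged:
            logger.warning("scan: non-convergence at P_T=%g; excluded", p_t)
            rows.append((p_t, np.nan, np.nan, int(profile.n_snps[j]), False))
            continue
        p_score = float(fit.pvalues[1])
        r2 = nagelkerke_r2(ll_null_cov, float(fit.llf), n)
        rows.append((p_t, p_score, r2, int(profile.n_snps[j]), True))

    table = pd.DataFrame(rows, columns=["p_t", "p", "nagelkerke_r2",
                                        "n_snps", "converged"]).set_index("p_t")
    ok = table[table["converged"] & table["p"].notna()]
    ranked = ok.sort_values(["p"], kind="mergesort")  # index already ascending
    selected = list(ranked.index[:top_k])
    return ScanResult(table=table, selected=selected)


# ---------------------------------------------------------------------------
# shared / disorder-specific partition
# ---------------------------------------------------------------------------

def partition(asd_stats: SummaryStatTable, scz_stats: SummaryStatTable,
              clumped: ClumpResult, p_t: float,
              scz_criterion: str = "threshold") -> tuple[set[str], set[str]]:
    """Split the discovery selection into shared and disorder-specific SNPs.

    Over the ASD SNPs retained by clumping with asd_P <= p_t: ``shared``
    are those also present in the SCZ statistics with scz_P <= p_t
    (``scz_criterion="threshold"``, default) or present at any P
    (``scz_criterion="any"``); ``specific`` is the remainder.
    """
    if scz_criterion not in ("threshold", "any"):
        raise ValueError("scz_criterion must be 'threshold' or 'any'")
    t = asd_stats.table
    selection = set(t.loc[t["SNP"].isin(clumped.retained_set())
                          & (t["P"] <= p_t), "SNP"])
    s = scz_stats.table
    if scz_criterion == "threshold":
        scz_hits = set(s.loc[s["P"] <= p_t, "SNP"])
    else:
        scz_hits = set(s["SNP"])
    shared = selection & scz_hits
    specific = selection - shared
    return shared, specific
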