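"""Genotype quality control and ancestry principal components.

Works on a dosage matrix (subjects x SNPs, expected effect-allele counts in
[0, 2], possibly fractional after imputation).  Variant-level filters are
minor allele frequency, call rate and Hardy-Weinberg equilibrium; sample
level filters are missingness, a precomputed sex-mismatch flag and pairwise
relatedness (PLINK-style method-of-moments PI_HAT).  Ancestry structure is
summarised by the leading principal components of the standardized dosage
matrix, which downstream association models use as covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DosageMatrix:
    """Subjects x SNPs allele-dosage matrix with per-SNP map information.

    ``values[i, j]`` is the dosage of allele ``a1[j]`` carried by subject
    ``subject_ids[i]``; missing genotypes are ``NaN``.
    """

    subject_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray          # str per SNP
    pos: np.ndarray            # 1-based int per SNP
    a1: np.ndarray             # effect/counted allele
    a2: np.ndarray             # other allele
    values: np.ndarray         # float (n_subjects, n_snps), NaN = missing

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.a1 = np.asarray(self.a1, dtype=object)
        self.a2 = np.asarray(self.a2, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        if self.values.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape does not match id lists")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not present in dosage matrix") from None

    def subset(self, subjects: np.ndarray | None = None,
               snps: np.ndarray | None = None) -> "DosageMatrix":
        """Return a copy restricted to boolean/index masks over rows/columns."""
        si = np.arange(self.n_subjects) if subjects is None else np.asarray(subjects)
        vi = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if vi.dtype == bool:
            vi = np.flatnonzero(vi)
        return DosageMatrix(
            subject_ids=[self.subject_ids[i] for i in si],
            snp_ids=[self.snp_ids[j] for j in vi],
            chrom=self.chrom[vi], pos=self.pos[vi],
            a1=self.a1[vi], a2=self.a2[vi],
            values=self.values[np.ix_(si, vi)],
        )

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of a1 from mean dosage / 2 (missing ignored);
        NaN for a fully missing SNP."""
        finite = np.isfinite(self.values)
        counts = finite.sum(axis=0)
        sums = np.where(finite, self.values, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / counts, np.nan) / 2.0

    def hard_calls(self) -> np.ndarray:
        """Dosages rounded to nearest genotype in {0, 1, 2}; NaN preserved."""
        return np.clip(np.round(self.values), 0, 2)


@dataclass
class QCThresholds:
    """Variant- and sample-level exclusion thresholds.

    Defaults follow standard array QC practice: MAF < 1%, call rate < 95%,
    HWE P < 1e-5 exclude a variant; missingness > 5%, sex mismatch or
    pairwise PI_HAT > 0.90 exclude a sample.
    """

    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-5
    sample_missing_max: float = 0.05
    ibd_max: float = 0.90

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min",
                     "sample_missing_max", "ibd_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Per-variant and per-sample QC metrics with pass flags and reasons."""

    snp_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    sample_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    removed_counts: dict[str, int] = field(default_factory=dict)

    def passing_snps(self) -> list[str]:
        return list(self.snp_table.index[self.snp_table["pass"]])

    def passing_samples(self) -> list[str]:
        return list(self.sample_table.index[self.sample_table["pass"]])


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided HWE goodness-of-fit P value (1-df chi-square).

    Observed genotype counts are compared with the p^2 / 2pq / q^2
    expectations at the sample allele frequency.  A monomorphic site fits
    its own expectation perfectly and returns P = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or p == 1.0:
        logger.debug("monomorphic site in HWE test; returning P = 1")
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(statistic, df=1))


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------

def variant_qc(dosages: DosageMatrix, thresholds: QCThresholds | None = None) -> QCReport:
    """Flag SNPs failing MAF, call-rate or HWE thresholds.

    MAF comes from mean dosage / 2 folded to <= 0.5; the HWE test runs on
    hard calls (dosage rounded to the nearest genotype).  A SNP's ``reason``
    lists every failed criterion.
    """
    if dosages.n_snps == 0 or dosages.n_subjects == 0:
        raise ValueError("empty dosage matrix")
    thresholds = thresholds or QCThresholds()

    values = dosages.values
    n = dosages.n_subjects
    n_missing = np.sum(~np.isfinite(values), axis=0)
    call_rate = 1.0 - n_missing / n

    freq = dosages.allele_freq()
    freq = np.where(np.isfinite(freq), freq, 0.0)
    maf = np.minimum(freq, 1.0 - freq)

    hard = dosages.hard_calls()
    hwe_p = np.ones(dosages.n_snps)
    for j in range(dosages.n_snps):
        col = hard[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            continue
        counts = [int(np.sum(col == g)) for g in (2, 1, 0)]
        hwe_p[j] = hwe_test(*counts)

    reasons = []
    for j in range(dosages.n_snps):
        r = []
        if maf[j] < thresholds.maf_min:
            r.append("maf")
        if call_rate[j] < thresholds.call_rate_min:
            r.append("call_rate")
        if hwe_p[j] < thresholds.hwe_p_min:
            r.append("hwe")
        reasons.append(",".join(r))

    table = pd.DataFrame(
        {"maf": maf, "call_rate": call_rate, "hwe_p": hwe_p,
         "pass": [r == "" for r in reasons], "reason": reasons},
        index=pd.Index(dosages.snp_ids, name="snp"),
    )
    removed = {
        "maf": int(table["reason"].str.contains("maf").sum()),
        "call_rate": int(table["reason"].str.contains("call_rate").sum()),
        "hwe": int(table["reason"].str.contains("hwe").sum()),
        "total_snps_removed": int((~table["pass"]).sum()),
    }
    return QCReport(snp_table=table, removed_counts=removed)


# ---------------------------------------------------------------------------
# identity by descent
# ---------------------------------------------------------------------------

def _ibs_ibd_expectations(freq: np.ndarray) -> tuple[float, float, float, float, float]:
    """Summed per-SNP P(IBS | IBD) terms of the moment estimator.

    Returns (e00, e10, e20, e11, e21): expected counts of IBS 0/1/2 given
    IBD 0, and of IBS 1/2 given IBD 1, over the supplied SNPs.
    """
    p = np.clip(freq, 1e-12, 1 - 1e-12)
    q = 1.0 - p
    e00 = float(np.sum(2 * p**2 * q**2))
    e10 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e20 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e11 = float(np.sum(2 * p * q))
    e21 = float(np.sum(p**2 + q**2))
    return e00, e10, e20, e11, e21


def _pihat_from_ibs(n0: float, n1: float, n2: float,
                    e00: float, e10: float, e20: float,
                    e11: float, e21: float, n_obs: float) -> float:
    p0 = n0 / e00 if e00 > 0 else 0.0
    p1 = (n1 - p0 * e10) / e11 if e11 > 0 else 0.0
    p2 = (n2 - p0 * e20 - p1 * e21) / n_obs
    p0, p1, p2 = (max(0.0, v) for v in (p0, p1, p2))
    total = p0 + p1 + p2
    if total > 0:
        p0, p1, p2 = p0 / total, p1 / total, p2 / total
    return float(np.clip(p1 / 2.0 + p2, 0.0, 1.0))


def estimate_ibd(dosages: DosageMatrix, pair: tuple[str, str],
                 min_shared: int = 100) -> float:
    """Method-of-moments PI_HAT for one subject pair.

    Identity-by-state counts on hard-called genotypes are compared with
    their expectations under IBD state 0/1/2 at sample allele frequencies
    (the PLINK moment estimator); the result is clipped to [0, 1].
    """
    ia = dosages.subject_ids.index(pair[0])
    ib = dosages.subject_ids.index(pair[1])
    hard = dosages.hard_calls()
    ga, gb = hard[ia], hard[ib]
    shared = np.isfinite(ga) & np.isfinite(gb)
    if int(shared.sum()) < min_shared:
        raise ValueError(
            f"pair ({pair[0]}, {pair[1]}) shares only {int(shared.sum())} "
            f"non-missing SNPs (< {min_shared})")
    freq = dosages.allele_freq()[shared]
    ga, gb = ga[shared], gb[shared]
    diff = np.abs(ga - gb)
    n0 = float(np.sum(diff == 2))
    n2 = float(np.sum(diff == 0))
    n1 = float(diff.size) - n0 - n2
    return _pihat_from_ibs(n0, n1, n2, *_ibs_ibd_expectations(freq), float(diff.size))


def pairwise_pihat(dosages: DosageMatrix) -> pd.DataFrame:
    """PI_HAT for every subject pair (vectorized over one-hot genotypes)."""
    hard = dosages.hard_calls()
    valid = np.isfinite(hard)
    g = np.where(valid, hard, -1)
    onehot = [np.asarray((g == k) & valid, dtype=float) for k in (0, 1, 2)]
    ibs2 = sum(h @ h.T for h in onehot)
    ibs0 = onehot[0] @ onehot[2].T + onehot[2] @ onehot[0].T
    n_valid = np.asarray(valid, dtype=float) @ np.asarray(valid, dtype=float).T
    ibs1 = n_valid - ibs0 - ibs2

    e00, e10, e20, e11, e21 = _ibs_ibd_expectations(dosages.allele_freq())
    m = dosages.n_snps
    rows = []
    for i in range(dosages.n_subjects):
        for j in range(i + 1, dosages.n_subjects):
            if n_valid[i, j] <= 0:
                continue
            scale = n_valid[i, j] / m  # rescale expectations to shared SNPs
            pihat = _pihat_from_ibs(
                ibs0[i, j], ibs1[i, j], ibs2[i, j],
                e00 * scale, e10 * scale, e20 * scale,
                e11 * scale, e21 * scale, n_valid[i, j])
            rows.append((dosages.subject_ids[i], dosages.subject_ids[j], pihat))
    return pd.DataFrame(rows, columns=["id1", "id2", "pi_hat"])


# ---------------------------------------------------------------------------
# sample QC
# ---------------------------------------------------------------------------

def sample_qc(dosages: DosageMatrix, thresholds: QCThresholds | None = None,
              reported_sex_mismatch: dict[str, bool] | None = None) -> QCReport:
    """Flag samples failing missingness, sex-mismatch or relatedness rules.

    For a pair with PI_HAT above ``ibd_max`` the member with higher
    missingness is removed (ties: lexicographically smaller id removed).
    """
    if dosages.n_subjects == 0:
        raise ValueError("empty dosage matrix")
    thresholds = thresholds or QCThresholds()
    mismatch = reported_sex_mismatch or {}

    missing = np.mean(~np.isfinite(dosages.values), axis=1)
    reasons: dict[str, list[str]] = {sid: [] for sid in dosages.subject_ids}
    for sid, miss in zip(dosages.subject_ids, missing):
        if miss > thresholds.sample_missing_max:
            reasons[sid].append("missingness")
        if mismatch.get(sid, False):
            reasons[sid].append("sex_mismatch")

    pihat = pairwise_pihat(dosages)
    miss_by_id = dict(zip(dosages.subject_ids, missing))
    max_pihat = {sid: 0.0 for sid in dosages.subject_ids}
    for _, row in pihat.iterrows():
        for sid in (row.id1, row.id2):
            max_pihat[sid] = max(max_pihat[sid], row.pi_hat)
        if row.pi_hat > thresholds.ibd_max:
            m1, m2 = miss_by_id[row.id1], miss_by_id[row.id2]
            if m1 > m2:
                drop = row.id1
            elif m2 > m1:
                drop = row.id2
            else:
                drop = min(row.id1, row.id2)
            if "ibd" not in reasons[drop]:
                reasons[drop].append("ibd")

    table = pd.DataFrame(
        {"missingness": missing,
         "max_pi_hat": [max_pihat[s] for s in dosages.subject_ids],
         "pass": [not reasons[s] for s in dosages.subject_ids],
         "reason": [",".join(reasons[s]) for s in dosages.subject_ids]},
        index=pd.Index(dosages.subject_ids, name="subject"),
    )
    removed = {
        "missingness": int(table["reason"].str.contains("missingness").sum()),
        "sex_mismatch": int(table["reason"].str.contains("sex_mismatch").sum()),
        "ibd": int(table["reason"].str.contains("ibd").sum()),
        "total_samples_removed": int((~table["pass"]).sum()),
    }
    return QCReport(sample_table=table, removed_counts=removed)


# ---------------------------------------------------------------------------
# ancestry principal components
# ---------------------------------------------------------------------------

def compute_pcs(dosages: DosageMatrix, k: int = 4) -> pd.DataFrame:
    """Leading principal components of the standardized dosage matrix.

    Each SNP column is centred at 2p and scaled by sqrt(2p(1-p)) (the
    population-genetics convention); missing dosages are mean-imputed.
    Components are ordered by decreasing variance explained and the sign of
    each is fixed so its largest-magnitude SNP loading is positive.
    """
    if k >= dosages.n_subjects:
        raise ValueError(f"k={k} must be smaller than n_subjects={dosages.n_subjects}")
    x = dosages.values.copy()
    freq = dosages.allele_freq()
    mean = 2.0 * freq
    x = np.where(np.isfinite(x), x, mean[None, :])
    sd = np.sqrt(2.0 * freq * (1.0 - freq))
    keep = sd > 0
    z = (x[:, keep] - mean[None, keep]) / sd[None, keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for c in range(k):
        lead = np.argmax(np.abs(vt[c]))
        if vt[c, lead] < 0:
            scores[:, c] *= -1.0
    return pd.DataFrame(scores, index=pd.Index(dosages.subject_ids, name="subject"),
                        columns=[f"PC{i + 1}" for i in range(k)])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_dosage_tsv(dosages: DosageMatrix, path) -> None:
    """Write a dosage TSV: map columns then one column per subject."""
    df = pd.DataFrame({
        "SNP": dosages.snp_ids, "CHR": dosages.chrom, "BP": dosages.pos,
        "A1": dosages.a1, "A2": dosages.a2,
    })
    for i, sid in enumerate(dosages.subject_ids):
        df[sid] = dosages.values[i, :]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    map_cols = ["SNP", "CHR", "BP", "A1", "A2"]
    subject_ids = [c for c in df.columns if c not in map_cols]
    return DosageMatrix(
        subject_ids=subject_ids,
        snp_ids=[str(s) for s in df["SNP"]],
        chrom=df["CHR"].astype(str).to_numpy(dtype=object),
        pos=df["BP"].to_numpy(),
        a1=df["A1"].astype(str).to_numpy(dtype=object),
        a2=df["A2"].astype(str).to_numpy(dtype=object),
        values=df[subject_ids].to_numpy(dtype=float).T,
    )


def read_dosage_vcf(path, dosage_field: str = "DS") -> DosageMatrix:
    """Read dosages from a VCF carrying a per-genotype dosage FORMAT field."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    snp_ids, chrom, pos, a1, a2, cols = [], [], [], [], [], []
    for variant in vcf:
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chrom.append(str(variant.CHROM))
        pos.append(variant.POS)
        # VCF ALT is the counted (dosage) allele
        a1.append(variant.ALT[0])
        a2.append(variant.REF)
        ds = np.asarray(variant.format(dosage_field), dtype=float).ravel()
        cols.append(ds)
    return DosageMatrix(
        subject_ids=subject_ids, snp_ids=snp_ids,
        chrom=np.array(chrom, dtype=object), pos=np.array(pos),
        a1=np.array(a1, dtype=object), a2=np.array(a2, dtype=object),
        values=np.vstack(cols).T,
    )
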