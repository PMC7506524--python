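"""Synthetic cohorts with the statistical structure the pipeline assumes.

Generates every pipeline input without any download: LD-blocked allele
dosages (Gaussian copula over per-SNP allele frequencies, then binomial(2)
thresholding), two overlapping sets of discovery GWAS summary statistics
(a primary disorder, "ASD", and a comparison disorder, "SCZ", with a
configurable fraction of shared causal SNPs), demographic covariates with
case-control shifts in the directions observed in schizophrenia cohorts
(controls older and more educated), facial-emotion recognition scores, head
motion summaries, and 90-region BOLD time series in which one target region
("left amygdala", AAL index 41) carries an in-band 0.04 Hz oscillation whose
amplitude grows linearly with the subject's true polygenic score.

The default configuration is the study condition the pipeline is validated
under: n = 328 subjects (116 cases / 212 controls) and planted effect sizes
calibrated so the end-to-end measured partial correlation is ~0.2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .alff import LEFT_AMYGDALA, N_REGIONS, MotionSummary, RegionSeries
from .genoqc import DosageMatrix, write_dosage_tsv
from .prs import SummaryStatTable

_STAGE_GENO, _STAGE_STATS, _STAGE_PHENO = 11, 13, 17

# non-ambiguous allele pairs only, so no synthetic SNP is strand-dropped
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]


@dataclass
class SimConfig:
    """Generator settings; defaults are the validated study conditions."""

    n_subjects: int = 328
    n_cases: int = 116
    n_snps: int = 800
    n_ld_blocks: int = 40
    block_r2: float = 0.8          # latent copula correlation within a block
    causal_fraction: float = 0.10
    effect_sd: float = 1.0         # per-SNP effect scale; GWAS se = effect_sd/sqrt(n)
    overlap_fraction: float = 0.5  # causal SNPs shared with the comparison disorder
    planted_region: int = LEFT_AMYGDALA
    planted_beta: float = 0.095    # oscillation-amplitude units per score SD
    emotion_beta: float = 0.52     # negative-emotion items per score SD
    n_timepoints: int = 225
    tr_seconds: float = 2.0
    seed: int = 0
    # discovery-sample sizes (cases+controls of the two source GWAS)
    n_discovery_asd: int = 18_381 + 27_969
    n_discovery_scz: int = 33_426 + 32_541
    gwas_ncp: float = 4.0          # causal-effect scale in units of the GWAS se
    base_amplitude: float = 1.0    # planted-region oscillation baseline
    noise_sd: float = 1.0          # BOLD white-noise scale
    planted_freq_hz: float = 0.04  # in-band oscillation frequency
    max_items: int = 20            # items per emotion category

    def __post_init__(self) -> None:
        if self.n_cases > self.n_subjects:
            raise ValueError("n_cases must be <= n_subjects")
        for name in ("causal_fraction", "overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.block_r2 < 1.0:
            raise ValueError("block_r2 must lie in [0, 1)")
        if not 1 <= self.planted_region <= N_REGIONS:
            raise ValueError(f"planted_region must lie in 1..{N_REGIONS}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_snps % self.n_ld_blocks != 0:
            raise ValueError("n_snps must be divisible by n_ld_blocks")


@dataclass
class SyntheticCohort:
    """All pipeline inputs for one simulated cohort, plus planted truth."""

    dosages: DosageMatrix
    asd_stats: SummaryStatTable
    scz_stats: SummaryStatTable
    covariates: pd.DataFrame        # subject, status, age, sex, education, handedness
    emotion: pd.DataFrame           # subject, positive, neutral, negative, total
    series: list[RegionSeries]
    motion: list[MotionSummary]
    truth: dict = field(default_factory=dict)


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stage]))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimConfig) -> DosageMatrix:
    """LD-blocked dosages via a Gaussian copula.

    Within each contiguous block of ``n_snps / n_ld_blocks`` SNPs the latent
    Gaussians share an equicorrelation of ``block_r2``; the latent value is
    thresholded into genotype counts {0,1,2} at the Hardy-Weinberg split of
    a per-SNP allele frequency drawn uniform in [0.05, 0.5].  Thresholding
    attenuates the dosage correlation below the latent one.  Blocks are
    placed far enough apart that no clumping window spans two blocks.
    """
    rng = _rng(cfg, _STAGE_GENO)
    block_size = cfg.n_snps // cfg.n_ld_blocks
    freqs = rng.uniform(0.05, 0.5, size=cfg.n_snps)

    values = np.empty((cfg.n_subjects, cfg.n_snps))
    sqrt_r = np.sqrt(cfg.block_r2)
    sqrt_1mr = np.sqrt(1.0 - cfg.block_r2)
    for b in range(cfg.n_ld_blocks):
        cols = slice(b * block_size, (b + 1) * block_size)
        common = rng.standard_normal((cfg.n_subjects, 1))
        indep = rng.standard_normal((cfg.n_subjects, block_size))
        latent = sqrt_r * common + sqrt_1mr * indep
        u = stats.norm.cdf(latent)
        p = freqs[cols]
        t0 = (1.0 - p) ** 2            # P(genotype 0)
        t1 = t0 + 2.0 * p * (1.0 - p)  # P(genotype <= 1)
        values[:, cols] = np.where(u < t0, 0.0, np.where(u < t1, 1.0, 2.0))

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=cfg.n_snps)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    chrom = np.array([str(b % 22 + 1) for b in np.arange(cfg.n_snps) // block_size],
                     dtype=object)
    block_of = np.arange(cfg.n_snps) // block_size
    within = np.arange(cfg.n_snps) % block_size
    pos = (block_of // 22) * 10_000_000 + within * 10_000 + 1

    return DosageMatrix(
        subject_ids=[f"S{i + 1:04d}" for i in range(cfg.n_subjects)],
        snp_ids=[f"rs{j + 1:06d}" for j in range(cfg.n_snps)],
        chrom=chrom, pos=pos, a1=a1, a2=a2, values=values,
    )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def planted_effects(cfg: SimConfig) -> dict:
    """Deterministic planted-truth draw shared by the stats and phenotype
    generators: causal SNP indices, their true log-odds effects, and the
    subset also causal for the comparison disorder."""
    rng = _rng(cfg, _STAGE_STATS)
    n_causal = int(round(cfg.causal_fraction * cfg.n_snps))
    causal = np.sort(rng.choice(cfg.n_snps, size=n_causal, replace=False))
    se_asd = cfg.effect_sd / np.sqrt(cfg.n_discovery_asd)
    beta_true = np.zeros(cfg.n_snps)
    beta_true[causal] = rng.normal(0.0, cfg.gwas_ncp * se_asd, size=n_causal)
    n_shared = int(round(cfg.overlap_fraction * n_causal))
    shared = np.sort(rng.choice(causal, size=n_shared, replace=False)) \
        if n_causal else np.array([], dtype=int)
    return {"causal": causal, "beta_true_asd": beta_true, "shared": shared}


def _observed_stats(beta_true: np.ndarray, se: float,
                    dosages: DosageMatrix, rng: np.random.Generator) -> SummaryStatTable:
    beta_obs = beta_true + rng.normal(0.0, se, size=len(beta_true))
    z = beta_obs / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return SummaryStatTable(pd.DataFrame({
        "SNP": dosages.snp_ids, "CHR": dosages.chrom, "BP": dosages.pos,
        "A1": dosages.a1, "A2": dosages.a2, "BETA": beta_obs, "P": p,
    }))


def simulate_summary_stats(cfg: SimConfig,
                           dosages: DosageMatrix) -> tuple[SummaryStatTable,
                                                           SummaryStatTable]:
    """Discovery summary statistics for both disorders.

    Each SNP's observed effect is its planted effect plus Gaussian noise of
    scale effect_sd/sqrt(n_discovery); P is the two-sided z-test of the
    observed effect against that standard error.  A ``causal_fraction`` of
    SNPs carries planted primary-disorder effects and an
    ``overlap_fraction`` of those is pleiotropic (the same log-odds effect
    also planted for the comparison disorder, rescaled to its own se).
    """
    truth = planted_effects(cfg)
    rng = _rng(cfg, _STAGE_STATS + 100)  # noise stream, separate from truth
    se_asd = cfg.effect_sd / np.sqrt(cfg.n_discovery_asd)
    se_scz = cfg.effect_sd / np.sqrt(cfg.n_discovery_scz)
    asd = _observed_stats(truth["beta_true_asd"], se_asd, dosages, rng)
    beta_true_scz = np.zeros(cfg.n_snps)
    if truth["shared"].size:
        # same standardized effect sizes on the comparison disorder's scale
        scale = se_scz / se_asd
        beta_true_scz[truth["shared"]] = truth["beta_true_asd"][truth["shared"]] * scale
    scz = _observed_stats(beta_true_scz, se_scz, dosages, rng)
    return asd, scz


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def true_score(cfg: SimConfig, dosages: DosageMatrix) -> np.ndarray:
    """Standardized dosage-weighted sum of the planted primary effects."""
    truth = planted_effects(cfg)
    raw = dosages.values @ truth["beta_true_asd"]
    sd = raw.std()
    return (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)


def simulate_phenotypes(cfg: SimConfig, dosages: DosageMatrix,
                        asd_stats: SummaryStatTable) -> SyntheticCohort:
    """Covariates, emotion scores, motion and BOLD series with planted effects.

    The planted region's series carries an in-band sinusoid (default
    0.04 Hz) whose amplitude is base_amplitude + planted_beta * score on top
    of white noise; every other region is pure noise.  The negative-emotion
    score is round(base - emotion_beta * score + noise) clipped to
    [0, max_items].  Covariates mimic the case-control directions of real
    cohorts: controls older and more educated.
    """
    rng = _rng(cfg, _STAGE_PHENO)
    n = cfg.n_subjects
    score = true_score(cfg, dosages)
    case = np.arange(n) < cfg.n_cases
    ids = list(dosages.subject_ids)

    age = np.where(case, rng.normal(24.24, 9.03, n), rng.normal(34.71, 12.69, n))
    age = np.clip(age, 16.0, 75.0).round(1)
    education = np.where(case, rng.normal(10.78, 2.92, n), rng.normal(13.76, 3.71, n))
    education = np.clip(education, 0.0, 22.0).round(1)
    p_male = np.where(case, 36 / 116, 83 / 212)
    sex = (rng.uniform(size=n) < p_male).astype(int)  # 1 = male
    handedness = np.where(rng.uniform(size=n) < 0.96, "R", "L")

    covariates = pd.DataFrame({
        "subject": ids, "status": case.astype(int), "age": age, "sex": sex,
        "education": education, "handedness": handedness,
    })

    m = cfg.max_items
    positive = np.clip(np.round(rng.normal(11.4, 2.0, n)), 0, m).astype(int)
    neutral = np.clip(np.round(rng.normal(14.0, 2.0, n)), 0, m).astype(int)
    negative = np.clip(np.round(12.8 - cfg.emotion_beta * score
                                + rng.normal(0.0, 2.0, n)), 0, m).astype(int)
    emotion = pd.DataFrame({
        "subject": ids, "positive": positive, "neutral": neutral,
        "negative": negative, "total": positive + neutral + negative,
    })

    t = np.arange(cfg.n_timepoints) * cfg.tr_seconds
    amplitude = np.maximum(0.0, cfg.base_amplitude + cfg.planted_beta * score)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n)
    region_col = cfg.planted_region - 1
    series = []
    for i in range(n):
        data = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_timepoints, N_REGIONS))
        data[:, region_col] += amplitude[i] * np.sin(
            2.0 * np.pi * cfg.planted_freq_hz * t + phase[i])
        series.append(RegionSeries(subject_id=ids[i], tr=cfg.tr_seconds, data=data))

    motion = [MotionSummary(subject_id=ids[i],
                            max_translation_mm=rng.uniform(0.0, 1.5, 3),
                            max_rotation_deg=rng.uniform(0.0, 1.5, 3))
              for i in range(n)]

    planted = planted_effects(cfg)
    truth = {
        "planted_region": cfg.planted_region,
        "planted_beta": cfg.planted_beta,
        "emotion_beta": cfg.emotion_beta,
        "causal_snps": [dosages.snp_ids[j] for j in planted["causal"]],
        "shared_snps": [dosages.snp_ids[j] for j in planted["shared"]],
        "true_score": score.tolist(),
        "config": asdict(cfg),
    }
    return SyntheticCohort(dosages=dosages, asd_stats=asd_stats,
                           scz_stats=None, covariates=covariates,
                           emotion=emotion, series=series, motion=motion,
                           truth=truth)


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Full generator chain: genotypes -> summary stats -> phenotypes."""
    dosages = simulate_genotypes(cfg)
    asd, scz = simulate_summary_stats(cfg, dosages)
    cohort = simulate_phenotypes(cfg, dosages, asd)
    cohort.scz_stats = scz
    return cohort


# ---------------------------------------------------------------------------
# on-disk form
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write a cohort in the pipeline's on-disk formats: dosage TSV, two
    summary-stat TSVs, covariate+emotion CSV, motion TSV, one series CSV per
    subject, and the planted truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_dosage_tsv(cohort.dosages, outdir / "dosages.tsv")
    cohort.asd_stats.write_tsv(outdir / "asd_sumstats.tsv")
    if cohort.scz_stats is not None:
        cohort.scz_stats.write_tsv(outdir / "scz_sumstats.tsv")
    pheno = cohort.covariates.merge(cohort.emotion, on="subject")
    pheno.to_csv(outdir / "phenotypes.csv", index=False)
    pd.DataFrame(
        [{"subject": m.subject_id,
          **{f"trans_{a}": m.max_translation_mm[k] for k, a in enumerate("xyz")},
          **{f"rot_{a}": m.max_rotation_deg[k] for k, a in enumerate("xyz")}}
         for m in cohort.motion]
    ).to_csv(outdir / "motion.tsv", sep="\t", index=False)
    series_dir = outdir / "series"
    series_dir.mkdir(exist_ok=True)
    for s in cohort.series:
        pd.DataFrame(s.data, columns=[str(i) for i in range(1, N_REGIONS + 1)]) \
            .to_csv(series_dir / f"{s.subject_id}.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
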