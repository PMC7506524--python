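"""End-to-end analysis: cohort -> QC -> PRS -> ALFF -> associations.

Chains the module stages the way the study design runs them: genotype QC
and ancestry PCs, P-informed clumping and PRS scoring of the discovery
statistics, motion screening and spectral ALFF of the region series, then
covariate-adjusted association of the PRS with each of the 90 regions
(Bonferroni family 90) and each of the four emotion scores (family 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alff as alff_mod
from . import assoc, genoqc, prs
from .syndata import SimConfig, SyntheticCohort, simulate_cohort


@dataclass
class CohortAnalysis:
    """Tidy outputs of one end-to-end run."""

    region_results: pd.DataFrame          # per-region association stats
    emotion_results: pd.DataFrame         # per-emotion-score association stats
    prs_values: pd.Series                 # the score used
    pcs: pd.DataFrame
    qc_counts: dict = field(default_factory=dict)


def analyze_cohort(cohort: SyntheticCohort, p_t: float = 0.1,
                   snp_subset: set[str] | None = None,
                   run_sample_qc: bool = False,
                   score_label: str = "ASD") -> CohortAnalysis:
    """Run the full association pipeline on one cohort at one threshold.

    ``run_sample_qc`` additionally applies missingness/relatedness sample
    filters (O(n^2) in subjects; synthetic cohorts are clean, so it is off
    by default in simulation loops).
    """
    dosages = cohort.dosages
    vqc = genoqc.variant_qc(dosages)
    keep = np.array([s in set(vqc.passing_snps()) for s in dosages.snp_ids])
    qc_counts = dict(vqc.removed_counts)
    if not keep.all():
        dosages = dosages.subset(snps=keep)
    if run_sample_qc:
        sqc = genoqc.sample_qc(dosages)
        keep_s = np.array([s in set(sqc.passing_samples())
                           for s in dosages.subject_ids])
        qc_counts.update(sqc.removed_counts)
        if not keep_s.all():
            dosages = dosages.subset(subjects=keep_s)

    pcs = genoqc.compute_pcs(dosages, k=4)

    stats_kept = prs.SummaryStatTable(
        cohort.asd_stats.table[
            cohort.asd_stats.table["SNP"].isin(dosages.snp_ids)].copy())
    clumped = prs.clump(stats_kept, dosages)
    score = prs.score(dosages, stats_kept, clumped, p_t, snp_subset=snp_subset)

    keep_subjects = [m.subject_id for m in cohort.motion
                     if alff_mod.motion_screen(m)]
    vectors = [alff_mod.alff_pipeline(s) for s in cohort.series
               if s.subject_id in set(keep_subjects)
               and s.subject_id in set(dosages.subject_ids)]
    alff_table = alff_mod.alff_matrix(vectors)

    ids = list(alff_table.index)
    cov = cohort.covariates.set_index("subject").loc[ids]
    covars = pd.concat([cov[["age", "sex", "education", "status"]],
                        pcs.loc[ids]], axis=1)
    score_vec = score.loc[ids].to_numpy()

    region_results = assoc.associate_regions(alff_table, score_vec, covars)

    emo = cohort.emotion.set_index("subject").loc[ids]
    emo_rows = []
    for col in ("positive", "neutral", "negative", "total"):
        r = assoc.fit_assoc(emo[col].to_numpy(), score_vec, covars,
                            outcome=col, m_tests=assoc.EMOTION_FAMILY)
        emo_rows.append((col, r.beta, r.t, r.partial_r,
                         r.p_uncorrected, r.p_corrected))
    emotion_results = pd.DataFrame(
        emo_rows, columns=["score", "beta", "t", "partial_r",
                           "p_uncorrected", "p_corrected"]).set_index("score")

    return CohortAnalysis(region_results=region_results,
                          emotion_results=emotion_results,
                          prs_values=score, pcs=pcs, qc_counts=qc_counts)


def recovery_run(cfg: SimConfig, p_t: float = 0.1) -> dict:
    """One simulate + analyze cycle, summarised for recovery/calibration.

    Returns the planted region's rank by uncorrected P, its partial r, the
    negative-emotion partial r, and whether any region survives Bonferroni.
    """
    cohort = simulate_cohort(cfg)
    res = analyze_cohort(cohort, p_t=p_t)
    regions = res.region_results
    planted = str(cfg.planted_region)
    order = regions["p_uncorrected"].sort_values(kind="mergesort")
    rank = int(np.flatnonzero(order.index == planted)[0]) + 1
    return {
        "planted_rank": rank,
        "planted_is_min": rank == 1,
        "planted_partial_r": float(regions.loc[planted, "partial_r"]),
        "planted_p": float(regions.loc[planted, "p_uncorrected"]),
        "planted_p_corrected": float(regions.loc[planted, "p_corrected"]),
        "any_bonferroni_region": bool((regions["p_corrected"] < 0.05).any()),
        "negative_partial_r": float(
            res.emotion_results.loc["negative", "partial_r"]),
        "negative_p": float(
            res.emotion_results.loc["negative", "p_uncorrected"]),
    }
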