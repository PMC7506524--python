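"""PRS tests: grid, clumping vs an independent greedy oracle, scoring
arithmetic and allele handling, Nagelkerke R^2, scan, partition."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from prsbrain import (DosageMatrix, PRSProfile, SimConfig, SummaryStatTable,
                      clump, make_grid, nagelkerke_r2, partition, scan, score,
                      score_profile, simulate_cohort)


def make_target(values, a1=None, a2=None, pos=None, chrom=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return DosageMatrix(
        subject_ids=[f"S{i}" for i in range(n)],
        snp_ids=[f"snp{j}" for j in range(m)],
        chrom=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, m + 1) * 1000),
        a1=np.array(a1 if a1 is not None else ["A"] * m, dtype=object),
        a2=np.array(a2 if a2 is not None else ["G"] * m, dtype=object),
        values=values,
    )


def make_stats(snp_ids, p, beta=None, pos=None, chrom=None,
               a1="A", a2="G"):
    m = len(snp_ids)
    return SummaryStatTable(pd.DataFrame({
        "SNP": snp_ids,
        "CHR": chrom if chrom is not None else ["1"] * m,
        "BP": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "A1": [a1] * m if isinstance(a1, str) else a1,
        "A2": [a2] * m if isinstance(a2, str) else a2,
        "BETA": beta if beta is not None else np.zeros(m),
        "P": p,
    }))


class TestGrid:
    def test_grid_has_103_thresholds(self):
        assert len(make_grid()) == 103

    def test_grid_endpoints_and_content(self):
        g = make_grid()
        assert g[0] == 1e-5 and g[-1] == 0.5
        assert 0.0 not in g
        assert np.all(np.diff(g) > 0)
        for extra in (1e-5, 1e-4, 1e-3, 0.005, 0.25, 0.5):
            assert np.any(np.isclose(g, extra))


def clump_oracle(stats_df, r2, positions, chrom, r2_cutoff=0.1,
                 window_bp=250_000):
    """Literal greedy rule, written independently of the implementation:
    visit by ascending (p, pos, id); index SNPs claim in-window neighbours
    with r^2 above the cutoff."""
    order = sorted(range(len(stats_df)),
                   key=lambda i: (stats_df["P"].iat[i], positions[i],
                                  stats_df["SNP"].iat[i]))
    claimed = set()
    retained = []
    for i in order:
        if i in claimed:
            continue
        claimed.add(i)
        retained.append(stats_df["SNP"].iat[i])
        for j in order:
            if j in claimed or chrom[j] != chrom[i]:
                continue
            if abs(positions[j] - positions[i]) <= window_bp \
                    and r2[i, j] > r2_cutoff:
                claimed.add(j)
    return set(retained)


class TestClump:
    def test_single_snp_retained(self):
        d = make_target(np.array([[0.0], [1.0], [2.0]]))
        c = clump(make_stats(["snp0"], [0.5]), d)
        assert c.retained == ["snp0"]

    def test_uncorrelated_snps_all_retained(self, rng):
        v = rng.integers(0, 3, size=(500, 8)).astype(float)
        d = make_target(v)
        c = clump(make_stats(d.snp_ids, rng.uniform(size=8)), d)
        assert set(c.retained) == set(d.snp_ids)

    def test_matches_independent_oracle_on_random_instances(self, rng):
        for _ in range(100):
            m = 10
            # correlated dosages via shared latent factors
            latent = rng.standard_normal((60, 3))
            load = rng.standard_normal((3, m))
            v = latent @ load + rng.standard_normal((60, m))
            v = np.clip((v - v.min()) / (v.max() - v.min()) * 2, 0, 2)
            pos = np.sort(rng.integers(1, 600_000, size=m))
            chrom = rng.choice(["1", "2"], size=m)
            p = rng.uniform(size=m)
            d = make_target(v, pos=pos, chrom=chrom)
            stats = make_stats(d.snp_ids, p, pos=pos, chrom=chrom)
            c = clump(stats, d)
            r = np.corrcoef(v.T) ** 2
            expected = clump_oracle(stats.table, r, pos, chrom)
            assert set(c.retained) == expected

    def test_no_retained_pair_in_ld_within_window(self, rng):
        cfg = SimConfig(n_subjects=300, n_snps=200, n_ld_blocks=10, seed=41)
        cohort = simulate_cohort(cfg)
        c = clump(cohort.asd_stats, cohort.dosages)
        d = cohort.dosages
        idx = [d.snp_index(s) for s in c.retained]
        for ai, a in enumerate(idx):
            for b in idx[ai + 1:]:
                if d.chrom[a] != d.chrom[b] or abs(d.pos[a] - d.pos[b]) > 250_000:
                    continue
                r = np.corrcoef(d.values[:, a], d.values[:, b])[0, 1]
                assert r * r <= 0.1 + 1e-12

    def test_absent_snp_errors_with_name(self):
        d = make_target(np.array([[1.0], [2.0]]))
        stats = make_stats(["snpX"], [0.1])
        with pytest.raises(KeyError, match="snpX"):
            clump(stats, d)


class TestScore:
    def test_zero_betas_zero_scores(self, rng):
        v = rng.integers(0, 3, size=(20, 5)).astype(float)
        d = make_target(v)
        stats = make_stats(d.snp_ids, rng.uniform(size=5))
        c = clump(stats, d)
        s = score(d, stats, c, 0.5)
        assert np.allclose(s, 0.0)

    def test_hand_computed_weighted_sum(self):
        d = make_target(np.array([[1.0, 2.0, 0.0]]))
        stats = make_stats(d.snp_ids, [0.01, 0.01, 0.01],
                           beta=[0.1, -0.2, 0.3])
        c = clump(stats, d)
        s = score(d, stats, c, 0.5)
        assert s.iloc[0] == pytest.approx(1 * 0.1 + 2 * -0.2 + 0 * 0.3)

    def test_empty_subset_errors(self):
        d = make_target(np.array([[1.0], [0.0]]))
        stats = make_stats(d.snp_ids, [0.01], beta=[0.5])
        c = clump(stats, d)
        with pytest.raises(ValueError, match="all SNPs dropped"):
            score(d, stats, c, 0.5, snp_subset=set())

    def test_swapped_alleles_complemented(self):
        d = make_target(np.array([[2.0], [0.0]]), a1=["G"], a2=["A"])
        stats = make_stats(d.snp_ids, [0.01], beta=[1.0])  # stats A1=A
        c = clump(stats, d)
        s = score(d, stats, c, 0.5)
        np.testing.assert_allclose(s, [0.0, 2.0])  # dosage of A is 2 - d

    def test_strand_ambiguous_snp_dropped(self):
        d = make_target(np.array([[1.0, 1.0]]), a1=["A", "A"], a2=["T", "G"])
        stats = make_stats(d.snp_ids, [0.01, 0.01], beta=[5.0, 1.0],
                           a1=["A", "A"], a2=["T", "G"])
        c = clump(stats, d)
        s = score(d, stats, c, 0.5)
        assert s.iloc[0] == pytest.approx(1.0)  # only the A/G SNP counts
        assert s.attrs["n_snps"] == 1

    def test_allele_flip_invariance(self, rng):
        v = rng.integers(0, 3, size=(30, 6)).astype(float)
        d = make_target(v)
        stats = make_stats(d.snp_ids, rng.uniform(0.001, 0.4, 6),
                           beta=rng.normal(size=6))
        c = clump(stats, d)
        base = score(d, stats, c, 0.5)
        # flip one target SNP's allele labels and complement its dosage
        d2 = make_target(v.copy())
        d2.a1[2], d2.a2[2] = d2.a2[2], d2.a1[2]
        d2.values[:, 2] = 2.0 - d2.values[:, 2]
        s2 = score(d2, stats, c, 0.5)
        np.testing.assert_allclose(s2.to_numpy(), base.to_numpy(), atol=1e-12)

    def test_monotone_snp_inclusion_over_grid(self, rng):
        cfg = SimConfig(n_subjects=100, n_cases=33, n_snps=200, n_ld_blocks=10, seed=43)
        cohort = simulate_cohort(cfg)
        c = clump(cohort.asd_stats, cohort.dosages)
        profile = score_profile(cohort.dosages, cohort.asd_stats, c)
        assert np.all(np.diff(profile.n_snps) >= 0)


class TestNagelkerke:
    def test_zero_when_no_improvement(self):
        assert nagelkerke_r2(-10.0, -10.0, 50) == pytest.approx(0.0)

    def test_perfect_two_point_fit(self):
        ll_null = 2 * np.log(0.5)
        assert nagelkerke_r2(ll_null, 0.0, 2) == pytest.approx(1.0)

    def test_matches_formula_on_real_fits(self, rng):
        for _ in range(20):
            n = 60
            x = rng.standard_normal(n)
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-x))).astype(float)
            if y.min() == y.max():
                continue
            full = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
            expected = (1 - np.exp(2 * (null.llf - full.llf) / n)) \
                / (1 - np.exp(2 * null.llf / n))
            assert nagelkerke_r2(null.llf, full.llf, n) == pytest.approx(
                expected, abs=1e-12)
            assert 0.0 <= nagelkerke_r2(null.llf, full.llf, n) <= 1.0

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(0.0, 0.0, 10)


class TestScan:
    def _profile(self, scores, thresholds):
        n_snps = np.arange(1, scores.shape[1] + 1)
        return PRSProfile(subject_ids=[f"S{i}" for i in range(len(scores))],
                          thresholds=np.asarray(thresholds, float),
                          scores=scores, n_snps=n_snps)

    def test_identical_columns_select_smallest_thresholds(self, rng):
        n = 200
        col = rng.standard_normal(n)
        scores = np.tile(col[:, None], (1, 6))
        profile = self._profile(scores, [0.01, 0.05, 0.1, 0.2, 0.3, 0.5])
        status = rng.integers(0, 2, n)
        res = scan(profile, status, top_k=3)
        ps = res.table["p"].dropna()
        assert np.allclose(ps, ps.iloc[0])
        assert res.selected == [0.01, 0.05, 0.1]

    def test_planted_shift_ranks_above_null_columns(self, rng):
        hits = 0
        n, reps = 600, 30
        for _ in range(reps):
            status = np.r_[np.ones(n // 2), np.zeros(n // 2)]
            scores = rng.standard_normal((n, 10))
            scores[:, :3] += 0.3 * status[:, None]  # planted 0.3 SD shift
            thresholds = np.linspace(0.05, 0.5, 10)
            profile = self._profile(scores, thresholds)
            res = scan(profile, status, top_k=3)
            if res.table["p"].idxmin() in set(thresholds[:3]):
                hits += 1
        assert hits >= int(0.9 * reps)

    def test_covariate_only_signal_calibrated(self, rng):
        small = 0
        reps = 200
        for _ in range(reps):
            n = 300
            age = rng.normal(30, 10, n)
            logit = -3 + 0.1 * age
            status = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
            scores = rng.standard_normal((n, 1))
            profile = self._profile(scores, [0.5])
            res = scan(profile, status,
                       covariates=pd.DataFrame({"age": age}), top_k=1)
            if res.table["p"].iloc[0] < 0.05:
                small += 1
        assert 0.02 * reps <= small <= 0.08 * reps

    def test_nagelkerke_r2_reported_in_range(self, rng):
        n = 300
        status = rng.integers(0, 2, n)
        scores = rng.standard_normal((n, 3))
        profile = self._profile(scores, [0.1, 0.2, 0.3])
        res = scan(profile, status)
        r2 = res.table["nagelkerke_r2"].dropna()
        assert ((r2 >= 0) & (r2 <= 1)).all()


class TestPartition:
    def _setup(self, rng, m=12):
        v = rng.integers(0, 3, size=(200, m)).astype(float)
        d = make_target(v, pos=np.arange(1, m + 1) * 1_000_000)
        asd = make_stats(d.snp_ids, rng.uniform(0.001, 0.4, m),
                         beta=rng.normal(size=m),
                         pos=np.arange(1, m + 1) * 1_000_000)
        c = clump(asd, d)
        return d, asd, c

    def test_empty_comparison_stats_all_specific(self, rng):
        d, asd, c = self._setup(rng)
        empty = SummaryStatTable(asd.table.iloc[:0].copy())
        shared, specific = partition(asd, empty, c, 0.3)
        sel = {s for s in c.retained
               if asd.table.set_index("SNP").loc[s, "P"] <= 0.3}
        assert shared == set() and specific == sel

    def test_identical_stats_all_shared(self, rng):
        d, asd, c = self._setup(rng)
        shared, specific = partition(asd, asd, c, 0.3)
        assert specific == set()
        sel = {s for s in c.retained
               if asd.table.set_index("SNP").loc[s, "P"] <= 0.3}
        assert shared == sel

    def test_toy_threshold_rule(self):
        d = make_target(np.array([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]]),
                        pos=[1_000_000, 2_000_000, 3_000_000])
        asd = make_stats(["snp0", "snp1", "snp2"], [0.01, 0.05, 0.3],
                         pos=[1_000_000, 2_000_000, 3_000_000])
        scz = make_stats(["snp0", "snp2"], [0.04, 0.5],
                         pos=[1_000_000, 3_000_000])
        c = clump(asd, d)
        shared, specific = partition(asd, scz, c, 0.1)
        assert shared == {"snp0"} and specific == {"snp1"}

    def test_presence_criterion_flag(self):
        d = make_target(np.array([[0.0, 1.0], [2.0, 1.0]]),
                        pos=[1_000_000, 2_000_000])
        asd = make_stats(["snp0", "snp1"], [0.01, 0.05],
                         pos=[1_000_000, 2_000_000])
        scz = make_stats(["snp0"], [0.9], pos=[1_000_000])
        c = clump(asd, d)
        shared_thr, _ = partition(asd, scz, c, 0.1)
        shared_any, _ = partition(asd, scz, c, 0.1, scz_criterion="any")
        assert shared_thr == set() and shared_any == {"snp0"}

    def test_score_additivity_of_partition(self, rng):
        cfg = SimConfig(n_subjects=150, n_snps=200, n_ld_blocks=10, seed=47)
        cohort = simulate_cohort(cfg)
        c = clump(cohort.asd_stats, cohort.dosages)
        p_t = 0.2
        shared, specific = partition(cohort.asd_stats, cohort.scz_stats, c, p_t)
        full = score(cohort.dosages, cohort.asd_stats, c, p_t)
        parts = np.zeros(len(full))
        for subset in (shared, specific):
            if subset:
                parts += score(cohort.dosages, cohort.asd_stats, c, p_t,
                               snp_subset=subset).to_numpy()
        np.testing.assert_allclose(full.to_numpy(), parts, atol=1e-10)
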