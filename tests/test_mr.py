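import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from vigimr import mr
from vigimr.errors import FitError, HarmonizationError, NoInstrumentsError
from vigimr.simulate import GwasSimConfig, simulate_gwas


def make_stats(snps, betas, ses, pvals=None, chrom=None, pos=None, eff="A", oth="G", eaf=0.3):
    n = len(snps)
    return pd.DataFrame(
        {
            "snp": snps,
            "chrom": chrom if chrom is not None else [1] * n,
            "pos": pos if pos is not None else np.arange(n) * 20_000_000 + 1,
            "effect_allele": [eff] * n if isinstance(eff, str) else eff,
            "other_allele": [oth] * n if isinstance(oth, str) else oth,
            "beta": betas,
            "se": ses,
            "pval": pvals if pvals is not None else [1e-10] * n,
            "eaf": [eaf] * n if isinstance(eaf, float) else eaf,
        }
    )


def make_harmonized(beta_exp, beta_out, se_exp=0.01, se_out=0.01):
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    n = beta_exp.size
    return mr.HarmonizedSet(
        snps=[f"rs{i}" for i in range(n)],
        beta_exp=beta_exp,
        se_exp=np.full(n, se_exp, dtype=float),
        beta_out=beta_out,
        se_out=np.full(n, se_out, dtype=float),
        dropped=pd.DataFrame(columns=["snp", "reason"]),
    )


class TestSelectInstruments:
    def test_distance_window_rule(self):
        stats = make_stats(
            ["a", "b", "c"],
            [0.1, 0.1, 0.1],
            [0.01, 0.01, 0.01],
            pvals=[1e-10, 1e-9, 1e-9],
            pos=[0, 5_000_000, 20_000_000],
        )
        assert mr.select_instruments(stats) == ["a", "c"]

    def test_no_instruments_error(self):
        stats = make_stats(["a", "b"], [0.01, 0.01], [0.01, 0.01], pvals=[0.5, 1e-7])
        with pytest.raises(NoInstrumentsError):
            mr.select_instruments(stats)

    def test_ld_matrix_pruning(self):
        stats = make_stats(
            ["a", "b"], [0.1, 0.1], [0.01, 0.01], pvals=[1e-10, 1e-9], chrom=[1, 2]
        )
        ld = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=["a", "b"], columns=["a", "b"])
        assert mr.select_instruments(stats, ld=ld) == ["a"]

    def test_simulated_instruments_all_selected_few_false(self):
        exp, _ = simulate_gwas(GwasSimConfig(n_snps=10_000, n_instruments=50, seed=42))
        kept = mr.select_instruments(exp)
        truth = {f"rs{i:04d}" for i in range(50)}
        assert truth <= set(kept)
        assert len(set(kept) - truth) <= 2  # expected false selections < 1


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        exp = make_stats(["a"], [0.1], [0.01], eff="A", oth="G")
        out = make_stats(["a"], [0.05], [0.01], eff="G", oth="A")
        h = mr.harmonize(exp, out, ["a"])
        assert h.beta_out[0] == pytest.approx(-0.05)

    def test_matching_alleles_unchanged(self):
        exp = make_stats(["a"], [0.1], [0.01])
        out = make_stats(["a"], [0.05], [0.01])
        assert mr.harmonize(exp, out, ["a"]).beta_out[0] == pytest.approx(0.05)

    def test_ambiguous_palindrome_dropped(self):
        exp = make_stats(["a", "b"], [0.1, 0.1], [0.01, 0.01], eff=["A", "A"], oth=["T", "G"],
                         eaf=[0.50, 0.30])
        out = make_stats(["a", "b"], [0.05, 0.05], [0.01, 0.01], eff=["A", "A"], oth=["T", "G"],
                         eaf=[0.50, 0.30])
        h = mr.harmonize(exp, out, ["a", "b"])
        assert h.snps == ["b"]
        assert list(h.dropped["reason"]) == ["ambiguous palindrome"]

    def test_missing_in_outcome_dropped(self):
        exp = make_stats(["a", "b"], [0.1, 0.1], [0.01, 0.01])
        out = make_stats(["a"], [0.05], [0.01])
        h = mr.harmonize(exp, out, ["a", "b"])
        assert h.snps == ["a"]
        assert "missing in outcome" in set(h.dropped["reason"])

    def test_zero_retained_raises(self):
        exp = make_stats(["a"], [0.1], [0.01])
        out = make_stats(["z"], [0.05], [0.01])
        with pytest.raises(HarmonizationError):
            mr.harmonize(exp, out, ["a"])

    def test_simulated_palindromes_mostly_retained(self):
        cfg = GwasSimConfig(n_snps=400, n_instruments=400, palindromic_rate=0.05, seed=3)
        exp, out = simulate_gwas(cfg)
        h = mr.harmonize(exp, out, list(exp["snp"]))
        assert 0.90 <= h.n_snps / 400 <= 0.99

    def test_sign_consistency_under_global_allele_flip(self):
        cfg = GwasSimConfig(n_snps=60, n_instruments=60, causal_beta=0.25,
                            palindromic_rate=0.0, seed=5)
        exp, out = simulate_gwas(cfg)
        flipped = exp.copy()
        flipped[["effect_allele", "other_allele"]] = exp[["other_allele", "effect_allele"]]
        flipped["beta"] = -exp["beta"]
        flipped["eaf"] = 1.0 - exp["eaf"]
        snps = list(exp["snp"])
        est1 = mr.ivw(mr.harmonize(exp, out, snps))
        est2 = mr.ivw(mr.harmonize(flipped, out, snps))
        assert est1.beta == pytest.approx(est2.beta, rel=1e-12)


class TestIvw:
    def test_exact_proportionality(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.05, 0.2, size=20)
        h = make_harmonized(bx, 0.3 * bx)
        est = mr.ivw(h)
        assert est.beta == pytest.approx(0.3, rel=1e-12)
        assert est.pval < 1e-10

    def test_refuses_single_snp(self):
        with pytest.raises(FitError):
            mr.ivw(make_harmonized([0.1], [0.03]))

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(5, 30)
            bx = rng.uniform(0.02, 0.2, size=n)
            by = 0.2 * bx + rng.normal(0, 0.01, size=n)
            se_out = rng.uniform(0.005, 0.02, size=n)
            h = make_harmonized(bx, by, se_out=0.01)
            h.se_out = se_out
            est = mr.ivw(h)
            oracle = sm.WLS(by, bx, weights=1.0 / se_out**2).fit()
            assert est.beta == pytest.approx(oracle.params[0], abs=1e-10)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.05, 0.2, size=15)
        by = 0.4 * bx + rng.normal(0, 0.01, size=15)
        h = make_harmonized(bx, by)
        perm = rng.permutation(15)
        hp = make_harmonized(bx[perm], by[perm])
        assert mr.ivw(h).beta == pytest.approx(mr.ivw(hp).beta, rel=1e-12)


class TestEgger:
    def test_two_snp_refusal(self):
        with pytest.raises(FitError):
            mr.mr_egger(make_harmonized([0.1, 0.2], [0.03, 0.06]))

    def test_recovers_slope_and_intercept(self):
        estimates = []
        intercepts = []
        for seed in range(20):
            cfg = GwasSimConfig(
                n_snps=50, n_instruments=50, causal_beta=0.3, pleiotropy_mean=0.1,
                palindromic_rate=0.0, seed=seed,
            )
            exp, out = simulate_gwas(cfg)
            h = mr.harmonize(exp, out, list(exp["snp"]))
            est = mr.mr_egger(h)
            estimates.append(est.beta)
            intercepts.append(est.egger_intercept)
        assert np.mean(estimates) == pytest.approx(0.3, abs=0.1)
        assert np.mean(intercepts) == pytest.approx(0.1, abs=0.03)

    def test_pleiotropy_detected_in_majority(self):
        hits = 0
        for seed in range(20):
            cfg = GwasSimConfig(
                n_snps=40, n_instruments=40, causal_beta=0.0, pleiotropy_mean=0.1,
                palindromic_rate=0.0, seed=100 + seed,
            )
            exp, out = simulate_gwas(cfg)
            est = mr.mr_egger(mr.harmonize(exp, out, list(exp["snp"])))
            hits += est.intercept_p < 0.05
        assert hits > 10


class TestMedianAndMode:
    def test_identical_ratios(self):
        bx = np.linspace(0.05, 0.2, 10)
        h = make_harmonized(bx, 0.3 * bx)
        assert mr.weighted_median(h).beta == pytest.approx(0.3, rel=1e-9)
        assert mr.weighted_mode(h).beta == pytest.approx(0.3, rel=1e-9)

    def test_weighted_median_equals_plain_median_equal_weights(self):
        ratios = np.array([0.1, 0.2, 0.3, 0.4, 0.9])
        bx = np.full(5, 0.1)
        h = make_harmonized(bx, ratios * bx, se_exp=1e-12)
        # equal beta_exp, negligible exposure noise -> equal ratio weights
        assert mr.weighted_median(h).beta == pytest.approx(np.median(ratios), abs=1e-9)

    def test_median_more_robust_than_ivw_under_invalid_instruments(self):
        rng = np.random.default_rng(11)
        ivw_err, med_err = [], []
        for _ in range(50):
            n = 30
            bx = rng.uniform(0.05, 0.2, size=n)
            by = 0.3 * bx + rng.normal(0, 0.01, size=n)
            by[: int(0.3 * n)] += 0.05  # 30% invalid with shifted ratios
            h = make_harmonized(bx, by)
            ivw_err.append(abs(mr.ivw(h).beta - 0.3))
            med_err.append(abs(mr.weighted_median(h, n_boot=50).beta - 0.3))
        assert np.mean(med_err) < np.mean(ivw_err)

    def test_bootstrap_seeded(self):
        rng = np.random.default_rng(13)
        bx = rng.uniform(0.05, 0.2, size=12)
        by = 0.2 * bx + rng.normal(0, 0.01, size=12)
        h = make_harmonized(bx, by)
        a = mr.weighted_median(h, seed=5)
        b = mr.weighted_median(h, seed=5)
        assert a.se == b.se


class TestPresso:
    def test_needs_four_snps(self):
        with pytest.raises(FitError):
            mr.mr_presso(make_harmonized([0.1, 0.2, 0.3], [0.03, 0.06, 0.09]))

    def test_clean_data_global_p_large(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            bx = rng.uniform(0.05, 0.2, size=20)
            by = 0.3 * bx + rng.normal(0, 0.01, size=20)
            est = mr.mr_presso(make_harmonized(bx, by), n_sim=300, seed=seed)
            ok += est.presso_global_p > 0.05
        assert ok >= 17

    def test_spike_in_outlier_detected_and_corrected(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.2, size=20)
        by = 0.3 * bx + rng.normal(0, 0.01, size=20)
        by[4] += 10 * 0.01  # ratio offset of 10 standard errors
        h = make_harmonized(bx, by)
        est = mr.mr_presso(h, n_sim=500, seed=1)
        assert est.outliers == ["rs4"]
        keep = np.arange(20) != 4
        manual = mr.ivw(make_harmonized(bx[keep], by[keep]))
        assert est.beta == pytest.approx(manual.beta, rel=1e-12)


class TestFdrAndSuite:
    def test_bh_matches_brute_force(self, rng):
        def brute_force_bh(p):
            p = np.asarray(p, dtype=float)
            m = p.size
            order = np.argsort(p)
            q_sorted = p[order] * m / np.arange(1, m + 1)
            q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
            q = np.empty(m)
            q[order] = np.minimum(q_sorted, 1.0)
            return q

        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert mr.bh_fdr(p) == pytest.approx(brute_force_bh(p), abs=1e-12)

    def test_single_pvalue_unchanged(self):
        assert mr.bh_fdr([0.031])[0] == pytest.approx(0.031)

    def test_printed_statistics_labeled_significant(self):
        res = mr.MRResult(
            exposure="MDD", outcome="peptic ulcer", method=mr.IVW,
            beta=np.log(1.27), se=(np.log(1.45) - np.log(1.11)) / (2 * 1.96),
            pval=0.0005, n_snps=30, fdr_q=0.002,
        )
        assert res.significant is True
        lo, hi = res.or_ci
        assert lo == pytest.approx(1.11, abs=0.01)
        assert hi == pytest.approx(1.45, abs=0.01)

    def test_bidirectional_suite_runs_and_flags(self):
        stats = {}
        for i, trait in enumerate(["gerd", "mdd"]):
            exp, out = simulate_gwas(
                GwasSimConfig(n_snps=80, n_instruments=40, causal_beta=0.3, seed=50 + i)
            )
            stats[trait] = exp if i == 0 else out
        # gerd -> mdd uses the same generative link; mdd has no instruments by
        # construction here, so that direction is recorded as a failure
        table, failures = mr.bidirectional_suite([("gerd", "mdd")], stats, n_presso=200)
        assert not table.empty
        ivw_rows = table[table["method"] == mr.IVW]
        assert ivw_rows["fdr_q"].notna().all()
        assert (table["or_ci_low"] <= table["or"]).all()
        directions = {(r["exposure"], r["outcome"]) for _, r in table.iterrows()}
        assert ("gerd", "mdd") in directions

    def test_or_ci_is_exp_of_beta_ci(self):
        rng = np.random.default_rng(21)
        bx = rng.uniform(0.05, 0.2, size=10)
        by = 0.2 * bx + rng.normal(0, 0.01, size=10)
        est = mr.ivw(make_harmonized(bx, by))
        lo, hi = est.or_ci
        assert lo == pytest.approx(np.exp(est.beta - 1.96 * est.se))
        assert hi == pytest.approx(np.exp(est.beta + 1.96 * est.se))
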