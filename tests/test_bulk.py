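import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stromapipe.bulk import (
    aggregate_regions,
    bulk_comparison,
    bulk_de,
    differential_methylation,
    fit_random_intercept,
    km_estimate,
    logrank,
    methylation_expression_correlation,
    optimal_cutoff,
    percentile_rank,
    representative_sample,
)
from stromapipe.simulate import simulate_bulk, simulate_methylation


class TestRandomInterceptLMM:
    def test_boundary_data_reduces_to_ols(self, rng):
        # seed chosen so REML lands on the sigma_u2 = 0 boundary
        for seed in range(40):
            r = np.random.default_rng(seed)
            n, m = 12, 3
            pid = np.repeat([f"p{i}" for i in range(n)], m)
            x = r.normal(size=n * m)
            y = 1.0 + 0.5 * x + r.normal(size=n * m)
            X = np.column_stack([np.ones(n * m), x])
            with pytest.warns(UserWarning) if _is_boundary(y, X, pid) else _noop():
                fit = fit_random_intercept(y, X, pid)
            if fit.boundary:
                bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
                assert np.allclose(fit.beta, bhat, atol=1e-6)
                assert fit.sigma_u2 == 0.0
                return
        pytest.fail("no boundary case found in 40 seeds")

    def test_one_sample_per_patient_equals_t_test(self, rng):
        n = 24
        g = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        y = rng.normal(size=n) + 0.8 * g
        X = np.column_stack([np.ones(n), g])
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_random_intercept(y, X, [f"p{i}" for i in range(n)])
        t, p = sps.ttest_ind(y[g == 1], y[g == 0], equal_var=True)
        assert fit.p == pytest.approx(p, abs=1e-9)
        assert fit.estimate == pytest.approx(y[g == 1].mean() - y[g == 0].mean(), abs=1e-9)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        tab, _ = simulate_bulk(patients=20, samples_per_patient=4, seed=3)
        fit = bulk_comparison(tab, "cancer_status", "non-cancer", "cancer")
        m = smf.mixedlm(
            "expression ~ C(stroma_category) + C(age_category) "
            "+ C(cancer_status, Treatment('non-cancer'))",
            tab,
            groups=tab["patient_id"],
        ).fit(reml=True)
        key = [k for k in m.params.index if "cancer_status" in k][0]
        assert fit.estimate == pytest.approx(float(m.params[key]), abs=1e-4)
        assert fit.estimate_se == pytest.approx(float(m.bse[key]), rel=2e-2)
        assert fit.sigma_u2 == pytest.approx(float(m.cov_re.iloc[0, 0]), rel=1e-2)

    def test_singular_design_raises(self, rng):
        X = np.ones((10, 2))
        with pytest.raises(ValueError):
            fit_random_intercept(rng.normal(size=10), X, ["a"] * 5 + ["b"] * 5)

    def test_needs_two_patients(self, rng):
        X = np.ones((5, 1))
        with pytest.raises(ValueError):
            fit_random_intercept(rng.normal(size=5), X, ["a"] * 5)

    def test_variances_non_negative(self):
        tab, _ = simulate_bulk(patients=12, samples_per_patient=3, seed=9)
        fit = bulk_comparison(tab, "cancer_status", "non-cancer", "cancer")
        assert fit.sigma_u2 >= 0 and fit.sigma_e2 > 0


class _noop:
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


def _is_boundary(y, X, pid):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_random_intercept(y, X, pid).boundary


class TestBulkDE:
    def test_planted_cancer_effect_significant(self):
        tab, truth = simulate_bulk(patients=30, samples_per_patient=5, seed=1)
        res = bulk_de(tab).set_index("comparison")
        row = res.loc["non-cancer vs cancer"]
        assert row["significant"]
        assert row["ci_low"] <= truth["marginal"]["non-cancer vs cancer"] <= row["ci_high"]
        assert set(res.index) == {
            "non-cancer vs cancer", "relapse-free vs relapse", "LG vs HG",
            "relapse-free cancer vs relapse cancer",
        }

    def test_empty_group_raises(self):
        tab, _ = simulate_bulk(patients=8, samples_per_patient=2, seed=0)
        tab["cancer_status"] = "cancer"
        with pytest.raises(ValueError, match="empty"):
            bulk_comparison(tab, "cancer_status", "non-cancer", "cancer")

    def test_patient_permutation_null_is_calibrated(self):
        # permuting a patient-level label should give a roughly uniform p
        rng = np.random.default_rng(5)
        tab, _ = simulate_bulk(
            patients=24, samples_per_patient=3,
            effects={"cancer": 0.0, "HG": 0.0, "relapse": 0.0}, seed=5,
        )
        ps = []
        patients = tab["patient_id"].unique()
        for _ in range(60):
            lab = dict(zip(patients, rng.permutation(
                ["cancer" if i % 2 else "non-cancer" for i in range(len(patients))])))
            tab2 = tab.assign(cancer_status=tab["patient_id"].map(lab))
            fit = bulk_comparison(tab2, "cancer_status", "non-cancer", "cancer",
                                  covariates=())
            ps.append(fit.p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestMethylationModels:
    def test_region_means(self):
        betas = pd.DataFrame(
            [[0.2, 0.6], [0.4, 0.8], [0.9, 0.1]],
            index=["c1", "c2", "c3"],
            columns=["s1", "s2"],
        )
        regions = pd.Series(["TSS200", "5'UTR", "Body"], index=betas.index)
        agg = aggregate_regions(betas, regions)
        assert agg.loc["s1", "promoter_mean"] == pytest.approx(0.3)
        assert agg.loc["s1", "body_mean"] == pytest.approx(0.9)
        # loop oracle
        manual = np.mean([betas.loc["c1", "s2"], betas.loc["c2", "s2"]])
        assert agg.loc["s2", "promoter_mean"] == pytest.approx(manual, abs=1e-15)

    def test_single_site_mean_is_identity(self):
        betas = pd.DataFrame([[0.35, 0.5]], index=["c"], columns=["a", "b"])
        agg = aggregate_regions(betas, pd.Series(["TSS1500"], index=["c"]))
        assert agg["promoter_mean"].tolist() == [0.35, 0.5]
        assert agg["body_mean"].isna().all()

    def test_anticorrelation_detected(self, rng):
        expr = pd.Series(rng.normal(5, 1, 64), index=[f"s{i}" for i in range(64)])
        betas, regions, _ = simulate_methylation(expr, slope=1.2, seed=2)
        res = methylation_expression_correlation(betas, regions, expr)
        prom_mean = res[res["site"] == "promoter_mean"].iloc[0]
        assert prom_mean["rho"] < -0.4 and prom_mean["p"] < 0.05
        prom_sites = res[res["region"].isin(["TSS1500", "TSS200", "5'UTR", "1stExon"])]
        assert (prom_sites["rho"] < 0).mean() == 1.0

    def test_constant_expression_reported_missing(self):
        betas = pd.DataFrame(
            np.random.default_rng(0).uniform(0.2, 0.8, (4, 10)),
            index=[f"c{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(10)],
        )
        regions = pd.Series(["TSS200"] * 4, index=betas.index)
        expr = pd.Series(1.0, index=betas.columns)
        res = methylation_expression_correlation(betas, regions, expr)
        assert res[res["site"] == "c0"]["rho"].isna().all()

    def test_differential_methylation_planted_sites(self):
        rng = np.random.default_rng(0)
        n = 64
        patients = np.repeat([f"p{i}" for i in range(n // 2)], 2)
        group = np.array(["non-cancer", "cancer"] * (n // 2))
        meta = pd.DataFrame(
            {
                "patient_id": patients,
                "cancer_status": group,
                "stroma_category": rng.choice(["<=35%", "36-64%", ">=65%"], n),
                "age_category": rng.choice(["51-58", "59-64", "65-73"], n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        base = rng.uniform(0.4, 0.6, 18)
        betas = np.clip(
            base[:, None] + rng.normal(0, 0.05, (18, n)), 0.01, 0.99
        )
        planted = list(range(5))
        for i in planted:
            betas[i, group == "cancer"] -= 0.15  # hypomethylated in cancer
        betas = pd.DataFrame(np.clip(betas, 0.01, 0.99),
                             index=[f"cg{i}" for i in range(18)], columns=meta.index)
        res = differential_methylation(
            betas, meta, "cancer_status", "non-cancer", "cancer"
        ).set_index("site")
        hits = res.loc[[f"cg{i}" for i in planted], "significant"]
        fps = res.loc[[f"cg{i}" for i in range(5, 18)], "significant"]
        assert hits.sum() >= 4 and fps.sum() == 0
        assert (res.loc[hits.index, "estimate"] < 0).all()

    def test_constant_site_flagged(self):
        meta = pd.DataFrame(
            {
                "patient_id": ["p0", "p0", "p1", "p1"],
                "cancer_status": ["non-cancer", "cancer"] * 2,
            },
            index=[f"s{i}" for i in range(4)],
        )
        betas = pd.DataFrame([[0.5] * 4], index=["cg0"], columns=meta.index)
        res = differential_methylation(betas, meta, "cancer_status", "non-cancer",
                                       "cancer", covariates=())
        assert res.iloc[0]["flag"] == "constant"


def km_hand(times, events):
    """Hand product-limit computation for a small sample."""
    order = np.argsort(times)
    t, e = np.asarray(times)[order], np.asarray(events)[order]
    s = 1.0
    out = {}
    for ti in np.unique(t[e.astype(bool)]):
        at_risk = (t >= ti).sum()
        d = ((t == ti) & e.astype(bool)).sum()
        s *= 1 - d / at_risk
        out[ti] = s
    return out


class TestSurvival:
    def test_km_no_censoring_equals_empirical(self):
        times = [3.0, 1.0, 4.0, 1.0, 5.0]
        km = km_estimate(times, [1] * 5)
        for t in times:
            emp = np.mean(np.asarray(times) > t)
            assert km(t)[0] == pytest.approx(emp)

    def test_km_all_censored_stays_at_one(self):
        km = km_estimate([2.0, 3.0, 4.0], [0, 0, 0])
        assert km(10.0)[0] == 1.0

    def test_km_matches_hand_product_limit(self):
        times = [1, 2, 2, 3, 5, 6]
        events = [1, 1, 0, 1, 0, 1]
        km = km_estimate(times, events)
        hand = km_hand(times, events)
        for t, s in hand.items():
            assert km(float(t))[0] == pytest.approx(s)

    def test_logrank_identical_groups(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 0, 1]
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_logrank_matches_tabulation_oracle(self):
        # brute-force O-E tabulation on a 6-subject example
        ta, ea = [1.0, 3.0, 5.0], [1, 1, 1]
        tb, eb = [2.0, 4.0, 6.0], [1, 1, 0]
        all_t = sorted({t for t, e in zip(ta + tb, ea + eb) if e})
        O = E = V = 0.0
        for t in all_t:
            n1 = sum(x >= t for x in ta)
            n2 = sum(x >= t for x in tb)
            d1 = sum(x == t and e for x, e in zip(ta, ea))
            d2 = sum(x == t and e for x, e in zip(tb, eb))
            n, d = n1 + n2, d1 + d2
            O += d1
            E += d * n1 / n
            if n > 1:
                V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
        chi2_oracle = (O - E) ** 2 / V
        chi2, p = logrank(ta, ea, tb, eb)
        assert chi2 == pytest.approx(chi2_oracle, abs=1e-9)
        assert p == pytest.approx(sps.chi2.sf(chi2_oracle, 1), abs=1e-9)

    def test_representative_sample_rules(self):
        tab = pd.DataFrame(
            {
                "patient_id": ["p1", "p1", "p2", "p2"],
                "sample_id": ["a", "b", "c", "d"],
                "expression": [3.1, 5.2, 7.0, 7.0],
            }
        )
        rep = representative_sample(tab).set_index("patient_id")
        assert rep.loc["p1", "expression"] == 5.2
        assert rep.loc["p2", "sample_id"] == "c"  # tie: first sample id
        # brute-force group max oracle
        assert rep["expression"].to_dict() == tab.groupby("patient_id")["expression"].max().to_dict()

    def test_optimal_cutoff_separates_planted_clusters(self, rng):
        # two expression clusters; high cluster relapses four times faster
        lo = rng.normal(2.0, 0.3, 15)
        hi = rng.normal(6.0, 0.3, 15)
        expr = np.r_[lo, hi]
        t = np.r_[np.linspace(4.0, 12.0, 15), np.linspace(1.0, 3.0, 15)]
        res = optimal_cutoff(expr, t, np.ones(30, bool))
        assert lo.max() < res.cutoff < hi.min()
        assert res.p < 0.01

    def test_optimal_cutoff_equals_exhaustive_oracle(self, rng):
        expr = rng.normal(size=20)
        t = np.clip(rng.exponential(3.0, 20), 0.01, None)
        e = rng.random(20) < 0.8
        res = optimal_cutoff(expr, t, e, min_group=3)
        # recompute every candidate by hand
        uniq = np.sort(np.unique(expr))
        best_p, best_c = np.inf, None
        for c in (uniq[:-1] + uniq[1:]) / 2:
            hi = expr > c
            if hi.sum() < 3 or (~hi).sum() < 3:
                continue
            _, p = logrank(t[hi], e[hi], t[~hi], e[~hi])
            if p < best_p:
                best_p, best_c = p, c
        assert res.cutoff == pytest.approx(best_c)
        assert res.p == pytest.approx(best_p)
        assert len(res.scan) >= 1 and "overfitting" in res.warning or "unadjusted" in res.warning

    def test_constant_expression_raises(self):
        with pytest.raises(ValueError):
            optimal_cutoff(np.ones(20), np.arange(1, 21.0), np.ones(20, bool), min_group=3)

    def test_km_curves_non_increasing(self, rng):
        t = np.clip(rng.exponential(3.0, 40), 0.01, None)
        e = rng.random(40) < 0.7
        km = km_estimate(t, e)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km(0.0)[0] == 1.0


class TestPercentileRank:
    def test_largest_of_four(self):
        sums = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        assert percentile_rank(sums, "d") == 100.0

    def test_middle_of_odd_list(self):
        sums = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        assert abs(percentile_rank(sums, "c") - 50.0) <= 100.0 / 5

    def test_matches_sort_and_count_with_ties(self, rng):
        vals = rng.integers(0, 10, 50).astype(float)
        sums = pd.Series(vals, index=[f"f{i}" for i in range(50)])
        target = "f7"
        x = sums[target]
        oracle = 100.0 * ((vals < x).sum() + ((vals == x).sum() + 1) / 2) / 50
        assert percentile_rank(sums, target) == pytest.approx(oracle)

    def test_missing_feature(self):
        with pytest.raises(KeyError):
            percentile_rank(pd.Series([1.0], index=["a"]), "b")
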