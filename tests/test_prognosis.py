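"""Logistic models, LRT, FDR adjustment, burden and per-probe/gene scans."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cnvprog.prognosis import (
    adjust_pvalues,
    build_design,
    burden_association,
    fit_logistic,
    likelihood_ratio_test,
    map_genes_to_status,
    per_gene_scan,
    per_probe_scan,
)


def _two_by_two(n11, n10, n01, n00):
    """Outcome/exposure vectors for a 2x2 table (exposed cases etc.)."""
    y = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    x = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
    return y, x


class TestFitLogistic:
    def test_saturated_2x2_matches_cross_product_or(self):
        y, x = _two_by_two(8, 2, 2, 8)
        fit = fit_logistic(y, np.column_stack([np.ones(20), x]), ["intercept", "x"])
        assert fit.odds_ratio("x") == pytest.approx(16.0, rel=1e-6)

    def test_independent_predictor_or_one(self):
        y, x = _two_by_two(5, 5, 5, 5)
        fit = fit_logistic(y, np.column_stack([np.ones(20), x]), ["intercept", "x"])
        assert fit.odds_ratio("x") == pytest.approx(1.0, abs=1e-8)

    def test_large_sample_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 2000)
        p = 1 / (1 + np.exp(-(-0.3 + 0.5 * x)))
        y = (rng.random(2000) < p).astype(float)
        fit = fit_logistic(y, np.column_stack([np.ones(2000), x]), ["intercept", "x"])
        assert fit.coef[1] == pytest.approx(0.5, abs=0.1)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(200), rng.normal(size=200), rng.binomial(1, 0.4, 200)])
        p = 1 / (1 + np.exp(-(X @ np.array([-0.5, 0.8, -0.6]))))
        y = (rng.random(200) < p).astype(float)
        ours = fit_logistic(y, X)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(ours.coef, ref.params, atol=1e-6)
        assert np.allclose(ours.se, ref.bse, atol=1e-5)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_separation_flagged(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.r_[np.ones(10), np.zeros(10)]
        fit = fit_logistic(y, np.column_stack([np.ones(20), x]))
        assert fit.separated

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(10), np.ones((10, 1)))


class TestLRT:
    def test_constant_added_column_gives_zero_statistic(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        y = (rng.random(100) < 0.5).astype(float)
        X0 = np.column_stack([np.ones(100), x])
        X1 = np.column_stack([X0, np.ones(100)])  # redundant constant
        full = fit_logistic(y, X1, ["intercept", "x", "c"])
        red = fit_logistic(y, X0, ["intercept", "x"])
        stat, df, p = likelihood_ratio_test(full, red)
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_power_on_true_predictor(self):
        rng = np.random.default_rng(3)
        hits = 0
        for rep in range(50):
            x = rng.normal(size=500)
            p = 1 / (1 + np.exp(-(0.2 + 1.0 * x)))
            y = (rng.random(500) < p).astype(float)
            full = fit_logistic(y, np.column_stack([np.ones(500), x]), ["i", "x"])
            red = fit_logistic(y, np.ones((500, 1)), ["i"])
            _, _, pv = likelihood_ratio_test(full, red)
            hits += pv < 1e-4
        assert hits >= 49

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        p = 1 / (1 + np.exp(-0.7 * x))
        y = (rng.random(300) < p).astype(float)
        red = fit_logistic(y, np.ones((300, 1)), ["i"])

        def lrt_with(xs):
            full = fit_logistic(y, np.column_stack([np.ones(300), xs]), ["i", "x"])
            return likelihood_ratio_test(full, red)[0]

        assert lrt_with(x) == pytest.approx(lrt_with(10 * x + 3), abs=1e-5)

    def test_non_nested_rejected(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        a = fit_logistic(y, np.column_stack([np.ones(10), np.arange(10)]), ["i", "a"])
        b = fit_logistic(y, np.column_stack([np.ones(10), np.arange(10) ** 2]), ["i", "b"])
        with pytest.raises(ValueError):
            likelihood_ratio_test(a, b)


def _brute_force_stepup(p, factor):
    """Textbook step-up adjustment: sort, scale by m/i * factor, cumulative min."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank * factor)
        adj[i] = running
    return np.minimum(adj, 1.0)


class TestAdjustPvalues:
    def test_by_hand_example(self):
        out = adjust_pvalues(np.array([0.01, 0.02, 0.03]), "BY")
        assert np.allclose(out, 0.055)  # c(3) = 11/6

    def test_bh_hand_example(self):
        out = adjust_pvalues(np.array([0.01, 0.02, 0.04, 0.05]), "BH")
        assert np.allclose(out, [0.04, 0.04, 0.05, 0.05])

    def test_single_p_unchanged(self):
        for method in ("BH", "BY"):
            assert adjust_pvalues(np.array([0.123]), method)[0] == pytest.approx(0.123)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = int(rng.integers(1, 51))
            p = rng.random(m)
            c_m = np.sum(1.0 / np.arange(1, m + 1))
            assert np.allclose(adjust_pvalues(p, "BH"), _brute_force_stepup(p, 1.0))
            assert np.allclose(adjust_pvalues(p, "BY"), _brute_force_stepup(p, c_m))

    def test_by_dominates_bh_and_both_dominate_raw(self):
        rng = np.random.default_rng(6)
        p = rng.random(30)
        bh = adjust_pvalues(p, "BH")
        by = adjust_pvalues(p, "BY")
        assert (by >= bh - 1e-12).all()
        assert (bh >= p - 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues(np.array([0.5, 1.5]), "BH")


def _toy_cohort(n=120, seed=0, burden_or=1.3):
    rng = np.random.default_rng(seed)
    counts = np.where(rng.random(n) < 0.2, 0,
                      np.exp(rng.uniform(np.log(10), np.log(5000), n))).astype(int)
    x = np.log2(counts + 1)
    age = rng.normal(47, 14, n).clip(18, 85)
    eta = -1.5 + np.log(burden_or) * x + np.log(0.6) * (age - 47) / 10
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    clinical = pd.DataFrame({
        "tumor_type": "lactotroph",
        "grade": rng.choice(["1a", "1b", "2a", "2b"], n, p=[0.3, 0.05, 0.45, 0.2]),
        "age": age, "sex": rng.choice(["F", "M"], n), "recurrence": y,
    }, index=[f"s{i}" for i in range(n)])
    summaries = pd.DataFrame({
        "altered_frac": counts / 10_000, "gained_frac": counts / 10_000,
        "deleted_frac": 0.0, "loh_frac": 0.0,
        "altered_with_loh_frac": counts / 10_000,
    }, index=clinical.index)
    return summaries, clinical


class TestBurdenAssociation:
    def test_constant_burden_gives_null(self):
        summaries, clinical = _toy_cohort(seed=1)
        summaries["altered_frac"] = 0.5
        summaries["altered_with_loh_frac"] = 0.5
        r = burden_association(summaries, clinical, 10_000, scope="lactotroph")
        assert r.lrt_stat == 0.0 and r.p_value == 1.0
        assert "constant_burden" in r.flags

    def test_planted_effect_recovered(self):
        summaries, clinical = _toy_cohort(n=2000, seed=2)
        r = burden_association(summaries, clinical, 10_000, scope="lactotroph",
                               adjusted=True)
        assert 1.25 <= r.odds_ratio <= 1.35
        assert r.ci_low <= 1.3 <= r.ci_high
        assert r.p_value < 1e-6

    def test_cnloh_inclusion_identity_when_no_loh(self):
        summaries, clinical = _toy_cohort(seed=3)
        a = burden_association(summaries, clinical, 10_000, include_cnloh=False)
        b = burden_association(summaries, clinical, 10_000, include_cnloh=True)
        assert a.odds_ratio == pytest.approx(b.odds_ratio)
        assert a.p_value == pytest.approx(b.p_value)

    def test_small_scope_flagged_low_power(self):
        summaries, clinical = _toy_cohort(n=9, seed=8)
        if clinical["recurrence"].nunique() < 2:
            pytest.skip("degenerate draw")
        r = burden_association(summaries, clinical, 10_000, scope="lactotroph")
        assert "low_power" in r.flags


class TestPerProbeScan:
    def _scan_setup(self, seed=0, n=80, n_probes=30):
        rng = np.random.default_rng(seed)
        _, clinical = _toy_cohort(n=n, seed=seed)
        mat = pd.DataFrame(
            rng.choice([-1, 0, 1], p=[0.15, 0.6, 0.25], size=(n, n_probes)),
            index=clinical.index, columns=[f"p{j}" for j in range(n_probes)])
        return mat, clinical

    def test_constant_probe_skipped(self):
        mat, clinical = self._scan_setup()
        mat["p0"] = 0
        out = per_probe_scan(mat, clinical, scope="lactotroph")
        assert out.loc["p0", "flag"] == "constant"
        assert np.isnan(out.loc["p0", "p_value"])

    def test_separable_probe_flagged_with_finite_p(self):
        mat, clinical = self._scan_setup(seed=4)
        mat["p1"] = np.where(clinical["recurrence"] == 1, 1, 0)
        out = per_probe_scan(mat, clinical, scope="lactotroph")
        assert out.loc["p1", "flag"] == "separation"
        assert np.isfinite(out.loc["p1", "p_value"])
        assert out.loc["p1", "p_value"] < 0.01

    def test_adjustment_over_tested_probes_only(self):
        mat, clinical = self._scan_setup(seed=5)
        mat["p2"] = 0
        out = per_probe_scan(mat, clinical, scope="lactotroph")
        tested = out["p_value"].notna()
        assert np.isnan(out.loc["p2", "adjusted_p"])
        assert (out.loc[tested, "adjusted_p"] >= out.loc[tested, "p_value"] - 1e-12).all()

    def test_two_state_probe_has_one_df(self):
        mat, clinical = self._scan_setup(seed=6)
        mat["p3"] = np.where(np.arange(len(mat)) % 2 == 0, 1, 0)  # gain/normal only
        out = per_probe_scan(mat, clinical, scope="lactotroph")
        assert out.loc["p3", "lrt_df"] == 1


class TestGeneMapping:
    def _segments(self, rows):
        cols = ["sample_id", "chrom", "start_idx", "end_idx", "start", "end",
                "n_probes", "mean_l2r", "state"]
        return pd.DataFrame(rows, columns=cols)

    def _genes(self):
        return pd.DataFrame({
            "gene": ["GA", "GB", "GC"],
            "chrom": [1, 1, 2],
            "start": [1_000_000, 50_000_000, 5_000_000],
            "end": [1_500_000, 51_000_000, 6_000_000],
        })

    def test_gene_inside_gain_and_gene_untouched(self):
        segs = self._segments([
            ("s1", 1, 0, 9, 500_000, 2_000_000, 10, 0.6, "gain"),
        ])
        status, amb = map_genes_to_status(segs, self._genes(), samples=["s1"])
        assert status.loc["GA", "s1"] == 1
        assert status.loc["GB", "s1"] == 0
        assert status.loc["GC", "s1"] == 0
        assert not amb.to_numpy().any()

    def test_mixed_overlap_majority_wins_tie_flagged(self):
        # GA: 60% covered by loss, 40% by gain -> loss
        segs = self._segments([
            ("s1", 1, 0, 9, 900_000, 1_300_000, 10, -0.6, "loss"),
            ("s1", 1, 10, 19, 1_300_001, 1_500_000, 10, 0.6, "gain"),
        ])
        status, amb = map_genes_to_status(segs, self._genes(), samples=["s1"])
        assert status.loc["GA", "s1"] == -1
        assert not amb.loc["GA", "s1"]
        # exact tie (250,000 bp each) -> flagged ambiguous, resolved to loss
        segs2 = self._segments([
            ("s1", 1, 0, 9, 999_999, 1_249_999, 10, -0.6, "loss"),
            ("s1", 1, 10, 19, 1_250_000, 1_499_999, 10, 0.6, "gain"),
        ])
        status2, amb2 = map_genes_to_status(segs2, self._genes(), samples=["s1"])
        assert status2.loc["GA", "s1"] == -1
        assert amb2.loc["GA", "s1"]


class TestPerGeneScan:
    def test_planted_gene_survives_bh(self):
        rng = np.random.default_rng(7)
        n = 200
        _, clinical = _toy_cohort(n=n, seed=9)
        y = clinical["recurrence"].to_numpy()
        genes = {}
        for j in range(40):
            genes[f"g{j}"] = rng.choice([0, 1], size=n, p=[0.7, 0.3])
        # planted gene: alteration probability strongly tracks recurrence (OR ~ 8)
        p_alt = np.where(y == 1, 0.62, 0.17)
        genes["g_hit"] = (rng.random(n) < p_alt).astype(int)
        status = pd.DataFrame(genes, index=clinical.index).T
        out = per_gene_scan(status, clinical, scope="lactotroph", adjusted=False)
        assert out.loc["g_hit", "adjusted_p"] < 0.05
        assert out["adjustment"].iloc[0] == "BH"

    def test_null_gene_false_positive_rate(self):
        rng = np.random.default_rng(10)
        n = 150
        _, clinical = _toy_cohort(n=n, seed=11)
        perm = rng.permutation(n)
        clinical["recurrence"] = clinical["recurrence"].to_numpy()[perm]
        status = pd.DataFrame(
            rng.choice([0, 1], size=(300, n), p=[0.6, 0.4]),
            columns=clinical.index, index=[f"g{j}" for j in range(300)])
        out = per_gene_scan(status, clinical, scope="lactotroph", adjusted=False)
        frac = (out["p_value"] < 0.05).mean()
        assert frac < 0.1
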