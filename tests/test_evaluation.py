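import itertools

import numpy as np
import pandas as pd
import pytest

from pairsig.errors import InputError
from pairsig.evaluation import (
    association_suite,
    clinical_cox,
    correlation,
    time_dependent_roc,
    tmb,
    youden_cutoff,
)
from pairsig.signature import RiskScoreTable, stratify
from tests.conftest import random_survival


def score_table(values, prefix="s"):
    return RiskScoreTable(
        scores=pd.Series(
            np.asarray(values, dtype=float),
            index=[f"{prefix}{i}" for i in range(len(values))],
            name="risk_score",
        )
    )


def clin_frame(time, event, index):
    return pd.DataFrame({"os_days": time, "event": event}, index=index)


def binary_roc_points(score, label):
    """Uncensored oracle: direct sweep over thresholds."""
    out = []
    for c in np.unique(score):
        pos = score > c
        tp = (pos & label).sum() / label.sum()
        fp = (pos & ~label).sum() / (~label).sum()
        out.append((c, tp, 1 - fp))
    return out


class TestTimeDependentRoc:
    def test_constant_score_auc_half(self, rng):
        time, event = random_survival(rng, 30)
        st = score_table(np.zeros(30))
        roc = time_dependent_roc(st, clin_frame(time, event, st.sample_ids), 50.0)
        assert roc.auc == pytest.approx(0.5)

    def test_perfect_marker_auc_one(self, rng):
        time = np.concatenate([np.arange(1, 11), np.arange(200, 210)]).astype(float)
        event = np.ones(20, dtype=int)
        st = score_table(np.concatenate([np.ones(10), np.zeros(10)]))
        roc = time_dependent_roc(st, clin_frame(time, event, st.sample_ids), 100.0)
        assert roc.auc == pytest.approx(1.0)

    def test_uncensored_equals_binary_auc(self, rng):
        """[DERIVED] oracle: rank-sum AUC for the event-by-horizon label."""
        from sklearn.metrics import roc_auc_score

        for _ in range(5):
            n = 40
            time = rng.exponential(80.0, size=n)
            event = np.ones(n, dtype=int)
            score = rng.normal(size=n)
            horizon = float(np.median(time))
            label = time <= horizon
            if label.all() or not label.any():
                continue
            st = score_table(score)
            roc = time_dependent_roc(st, clin_frame(time, event, st.sample_ids), horizon)
            assert roc.auc == pytest.approx(roc_auc_score(label, score), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        time, event = random_survival(rng, 60, censor_frac=0.3)
        score = rng.normal(size=60)
        st = score_table(score)
        clin = clin_frame(time, event, st.sample_ids)
        a1 = time_dependent_roc(st, clin, 70.0).auc
        st2 = score_table(np.exp(2.0 * score))
        a2 = time_dependent_roc(st2, clin, 70.0).auc
        assert a2 == pytest.approx(a1, abs=1e-12)

    def test_sign_reversal_flips_auc_uncensored(self, rng):
        n = 50
        time = rng.exponential(60.0, size=n)
        event = np.ones(n, dtype=int)
        score = rng.normal(size=n)
        st = score_table(score)
        clin = clin_frame(time, event, st.sample_ids)
        a = time_dependent_roc(st, clin, float(np.median(time))).auc
        b = time_dependent_roc(
            score_table(-score), clin, float(np.median(time))
        ).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_no_events_before_horizon_rejected(self, rng):
        time = np.full(10, 100.0) + rng.random(10)
        event = np.ones(10, dtype=int)
        st = score_table(rng.normal(size=10))
        with pytest.raises(InputError):
            time_dependent_roc(st, clin_frame(time, event, st.sample_ids), 10.0)


class TestYoudenCutoff:
    def test_perfect_marker_j_one(self, rng):
        time = np.concatenate([np.arange(1, 11), np.arange(200, 210)]).astype(float)
        event = np.ones(20, dtype=int)
        st = score_table(np.concatenate([np.ones(10), np.zeros(10)]))
        roc = time_dependent_roc(st, clin_frame(time, event, st.sample_ids), 100.0)
        cutoff, j = youden_cutoff(roc)
        assert j == pytest.approx(1.0)
        assert cutoff == pytest.approx(0.0)

    def test_uninformative_marker_j_zero(self, rng):
        time, event = random_survival(rng, 20)
        st = score_table(np.zeros(20))
        roc = time_dependent_roc(st, clin_frame(time, event, st.sample_ids), 50.0)
        _, j = youden_cutoff(roc)
        assert j == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_sweep_uncensored(self, rng):
        """Brute-force oracle on ≤50 uncensored subjects."""
        for _ in range(10):
            n = int(rng.integers(6, 51))
            time = rng.exponential(50.0, size=n)
            event = np.ones(n, dtype=int)
            score = rng.normal(size=n)
            horizon = float(np.median(time))
            label = time <= horizon
            if label.all() or not label.any():
                continue
            st = score_table(score)
            roc = time_dependent_roc(st, clin_frame(time, event, st.sample_ids), horizon)
            cutoff, j = youden_cutoff(roc)
            sweep = binary_roc_points(score, label)
            best_j = max(tp + sp - 1 for _, tp, sp in sweep)
            best_c = min(c for c, tp, sp in sweep if tp + sp - 1 >= best_j - 1e-12)
            assert j == pytest.approx(best_j, abs=1e-12)
            assert cutoff == pytest.approx(best_c, abs=1e-12)


class TestClinicalCox:
    def make_cohort(self, rng, n=300, score_driven=True):
        score = rng.normal(size=n)
        eta = 1.2 * score if score_driven else np.zeros(n)
        u = rng.uniform(size=n)
        time = 100.0 * (-np.log(u) * np.exp(-eta))
        event = np.ones(n, dtype=int)
        ids = [f"s{i}" for i in range(n)]
        clinical = pd.DataFrame(
            {
                "os_days": time,
                "event": event,
                "age_years": rng.normal(65, 8, size=n).round(1),
                "gender": rng.choice(["male", "female"], size=n),
                "histology": rng.choice(["LUAD", "LUSC"], size=n),
                "stage": rng.choice(["I", "II", "III", "IV"], size=n),
            },
            index=ids,
        )
        scores = RiskScoreTable(scores=pd.Series(score, index=ids, name="risk_score"))
        return scores, clinical

    def test_score_driven_cohort_score_significant(self, rng):
        scores, clinical = self.make_cohort(rng)
        result = clinical_cox(scores, clinical, clinical)
        assert result.independent
        multi = result.multivariate.summary()
        assert multi.loc["risk_score", "p"] < 1e-6
        clinical_rows = [r for r in multi.index if r != "risk_score"]
        assert (multi.loc[clinical_rows, "p"] > 1e-4).all()  # covariates are null

    def test_empty_covariates_reduce_to_univariate(self, rng):
        scores, clinical = self.make_cohort(rng, n=120)
        result = clinical_cox(scores, clinical, clinical, covariates=[])
        np.testing.assert_allclose(
            result.multivariate.coef, result.univariate.coef, atol=1e-10
        )

    def test_collinear_covariate_rejected(self, rng):
        scores, clinical = self.make_cohort(rng, n=80)
        clinical = clinical.copy()
        clinical["dup_score"] = scores.scores
        with pytest.raises(InputError, match="collinear"):
            clinical_cox(
                scores, clinical, clinical, covariates=["age_years", "dup_score"]
            )


class TestAssociations:
    def make_stratified(self, rng, n=200):
        ids = [f"s{i}" for i in range(n)]
        score = rng.normal(size=n)
        clinical = pd.DataFrame(
            {
                "gender": rng.choice(["male", "female"], size=n),
                "stage": rng.choice(["I", "II", "III", "IV"], size=n),
                "t_stage": rng.choice(["T1", "T2", "T3", "T4"], size=n),
                "n_stage": rng.choice(["N0", "N1", "N2", "N3"], size=n),
                "m_stage": rng.choice(["M0", "M1"], size=n),
                "histology": rng.choice(["LUAD", "LUSC"], size=n),
            },
            index=ids,
        )
        scores = RiskScoreTable(scores=pd.Series(score, index=ids, name="risk_score"))
        return stratify(scores, 0.0), clinical

    def test_suite_covers_expected_tests(self, rng):
        stratified, clinical = self.make_stratified(rng)
        results = association_suite(stratified, clinical)
        chi = {r.variable for r in results if r.test == "chi-square"}
        wil = {r.variable for r in results if r.test == "wilcoxon"}
        assert chi == {"gender", "stage", "t_stage", "n_stage", "m_stage", "histology"}
        assert wil == {"stage", "t_stage", "n_stage", "m_stage"}
        assert all(0 < r.p <= 1 for r in results)

    def test_unstratified_rejected(self, rng):
        stratified, clinical = self.make_stratified(rng)
        with pytest.raises(InputError):
            association_suite(
                RiskScoreTable(scores=stratified.scores), clinical
            )

    def test_chi_square_balanced_table_is_null(self):
        from scipy.stats import chi2_contingency

        chi2, p, _, _ = chi2_contingency([[10, 10], [10, 10]], correction=False)
        assert chi2 == 0.0 and p == 1.0

    def test_chi_square_hand_formula(self):
        # [[20,5],[5,20]]: all expected counts 12.5 → chi2 = 4 * 7.5^2/12.5 = 18
        from scipy.stats import chi2, chi2_contingency

        stat, p, _, _ = chi2_contingency([[20, 5], [5, 20]], correction=False)
        assert stat == pytest.approx(18.0)
        assert p == pytest.approx(float(chi2.sf(18.0, 1)))

    def test_chi_square_permutation_invariance(self, rng):
        from scipy.stats import chi2_contingency

        table = rng.integers(1, 30, size=(3, 4))
        base, _, _, _ = chi2_contingency(table, correction=False)
        shuffled = table[rng.permutation(3)][:, rng.permutation(4)]
        alt, _, _, _ = chi2_contingency(shuffled, correction=False)
        assert alt == pytest.approx(base)

    def test_wilcoxon_matches_exact_permutation(self, rng):
        """Full 20-arrangement oracle for (1,2,3) vs (4,5,6)."""
        from scipy.stats import mannwhitneyu

        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        stat, p = mannwhitneyu(x, y, alternative="two-sided", method="auto")
        pooled = x + y
        observed = stat
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(6) if i not in combo]
            u, _ = mannwhitneyu(xs, ys, alternative="two-sided", method="exact")
            # two-sided: as or more extreme in either direction
            n1n2 = 9
            if min(u, n1n2 - u) <= min(observed, n1n2 - observed):
                count += 1
            total += 1
        assert total == 20
        assert p == pytest.approx(count / total)


class TestCorrelation:
    def test_pearson_perfect_linear(self, rng):
        x = rng.normal(size=20)
        res = correlation(x, 2 * x + 1, method="pearson")
        assert res.effect == pytest.approx(1.0)

    def test_spearman_monotone_nonlinear(self, rng):
        x = rng.normal(size=20)
        rho = correlation(x, np.exp(x), method="spearman")
        r = correlation(x, np.exp(x), method="pearson")
        assert rho.effect == pytest.approx(1.0)
        assert r.effect < 1.0

    def test_spearman_ties_vs_hand_ranks(self):
        # hand-ranked oracle: average ranks, then Pearson on the ranks
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0])
        rank_x = np.array([1.0, 2.5, 2.5, 4.0, 5.0])
        rank_y = np.array([2.0, 1.0, 3.5, 3.5, 5.0])
        expected = np.corrcoef(rank_x, rank_y)[0, 1]
        res = correlation(x, y, method="spearman")
        assert res.effect == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            correlation([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            correlation([1, 2], [3, 4])


class TestTmb:
    def test_arithmetic(self):
        counts = pd.Series({"a": 380, "b": 0, "c": 19})
        out = tmb(counts, exome_megabases=38.0)
        assert out["a"] == 10.0
        assert out["b"] == 0.0
        assert out["c"] == 0.5

    def test_negative_count_rejected(self):
        with pytest.raises(InputError):
            tmb(pd.Series({"a": -1}))

    def test_bad_denominator_rejected(self):
        with pytest.raises(InputError):
            tmb(pd.Series({"a": 1}), exome_megabases=0.0)
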