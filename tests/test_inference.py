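"""Mixed-model contrasts, SVR prediction, lag decoding, FDR."""

import numpy as np
import pandas as pd
import pytest

from btbc.coupling import BtBCSummary, LagGrid, LagProfile
from btbc.inference import (
    _auc_rows,
    _cv_scores_batch,
    adjust_fdr,
    build_analysis_table,
    build_individual_motion_table,
    decode_condition_by_lag,
    fit_condition_model,
    predict_outcome_svr,
)
from btbc.simulate import SimulationConfig, generate_cohort


# ---------------------------------------------------------------------------
# FDR


class TestFdr:
    def test_step_up_oracle(self):
        # hand-computed: thresholds 0.0125, 0.025, 0.0375, 0.05
        reject, q = adjust_fdr([0.01, 0.02, 0.03, 0.9])
        assert list(reject) == [True, True, True, False]

    def test_all_small_all_significant(self):
        reject, q = adjust_fdr([0.001] * 251)
        assert reject.all()
        assert np.allclose(q, 0.001)

    def test_single_p_identity(self):
        reject, q = adjust_fdr([0.04])
        assert q[0] == pytest.approx(0.04)
        assert reject[0]

    def test_q_monotone_after_sorting(self, rng):
        p = rng.uniform(1e-4, 1, 100)
        _, q = adjust_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            adjust_fdr([])
        with pytest.raises(ValueError, match="in \\(0, 1\\]"):
            adjust_fdr([0.0, 0.5])


# ---------------------------------------------------------------------------
# analysis tables


def _fake_summaries(cohort, values=None):
    out = []
    for i, rec in enumerate(cohort):
        v = 0.1 if values is None else values[i]
        out.append(
            BtBCSummary(
                overall=v, learner_leading=v, instructor_leading=v,
                zero_lag=v, peak_lag=0.0,
                dyad_id=rec.dyad_id, condition=rec.condition,
            )
        )
    return out


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(SimulationConfig(duration=60.0, n_dyads=4, seed=9))


class TestAnalysisTable:
    def test_structure_and_score_identity(self, small_cohort):
        table = build_analysis_table(small_cohort, _fake_summaries(small_cohort))
        assert len(table) == 8
        assert np.allclose(table["outcome"], table["post"] - table["pre"])
        assert set(table["condition"]) == {"scaffolding", "explanation"}
        assert (table.groupby("dyad_id").size() == 2).all()

    def test_missing_summary_rejected(self, small_cohort):
        with pytest.raises(KeyError):
            build_analysis_table(small_cohort, _fake_summaries(small_cohort)[:-1])

    def test_individual_table_has_two_rows_per_record(self, small_cohort):
        t = build_individual_motion_table(small_cohort)
        assert len(t) == 16
        assert set(t["role"]) == {"instructor", "learner"}


# ---------------------------------------------------------------------------
# mixed models


def _synthetic_table(rng, n_dyads=24, effect=0.0, dyad_sd=0.5, noise_sd=0.5):
    """Known-truth repeated-measures table (no coupling computation)."""
    rows = []
    for d in range(n_dyads):
        intercept = rng.normal(0, dyad_sd)
        pers = "personalized" if d % 2 == 0 else "nonpersonalized"
        for cond in ("scaffolding", "explanation"):
            y = 1.0 + intercept + (effect if cond == "scaffolding" else 0.0)
            rows.append(
                {
                    "dyad_id": f"d{d}",
                    "condition": cond,
                    "personalization": pers,
                    "response": y + rng.normal(0, noise_sd),
                }
            )
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_null_effect_within_two_se(self, rng):
        hits = 0
        for _ in range(30):
            table = _synthetic_table(rng, effect=0.0)
            ms = fit_condition_model(table, "response")
            row = ms.coef("condition")
            if abs(row["beta"]) <= 2 * row["se"]:
                hits += 1
        assert hits >= 27  # ~95% coverage, generous slack

    def test_known_effect_recovered(self, rng):
        betas = []
        for _ in range(30):
            table = _synthetic_table(rng, effect=0.4)
            betas.append(fit_condition_model(table, "response").coef("condition")["beta"])
        mean = np.mean(betas)
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(mean - 0.4) < 4 * mc_se

    def test_treatment_coding_sign(self, rng):
        # scaffolding raises the response => positive beta vs explanation ref
        table = _synthetic_table(rng, effect=1.0, noise_sd=0.1)
        row = fit_condition_model(table, "response").coef("condition")
        assert row["beta"] > 0
        assert row["t"] == pytest.approx(row["beta"] / row["se"], rel=1e-6)

    def test_summary_and_validation(self, rng):
        table = _synthetic_table(rng)
        ms = fit_condition_model(table, "response")
        text = ms.summary()
        assert "random effects" in text and "condition" in text
        one_level = table[table.condition == "scaffolding"]
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            fit_condition_model(one_level, "response")

    def test_nested_participant_model_runs(self, small_cohort):
        t = build_individual_motion_table(small_cohort)
        ms = fit_condition_model(
            t, "motion", fixed=("condition", "personalization"),
            random=("dyad", "participant"),
        )
        assert "participant" in ms.random_effects
        assert len(ms.terms) == 4  # intercept + 2 mains + interaction


# ---------------------------------------------------------------------------
# SVR prediction


class TestSvr:
    def test_noise_free_linear_limit(self, rng):
        x = rng.uniform(0.05, 0.3, 24)
        y = 3.0 + 5.0 * x
        res = predict_outcome_svr(x, y, seed=0)
        assert res.r > 0.99
        assert res.r2 == pytest.approx(res.r**2)
        assert len(res.chosen_c) == 24

    def test_covariate_adds_residual_correlation(self, rng):
        x = rng.uniform(0.05, 0.3, 24)
        cond = np.tile(["scaffolding", "explanation"], 12)
        y = 3.0 + 5.0 * x + 2.0 * (cond == "scaffolding") + rng.normal(0, 0.2, 24)
        res = predict_outcome_svr(x, y, covariate=cond, seed=0)
        assert res.residual_r is not None
        assert -1 <= res.residual_r <= 1
        assert res.r > 0.5

    def test_group_outer_cv_keeps_dyads_together(self, rng):
        x = rng.uniform(0, 1, 24)
        y = 2 * x + rng.normal(0, 0.1, 24)
        groups = np.repeat([f"d{i}" for i in range(12)], 2)
        res = predict_outcome_svr(x, y, outer_groups=groups, seed=1)
        assert np.isfinite(res.r)

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            predict_outcome_svr(rng.uniform(size=5), rng.uniform(size=5))
        with pytest.raises(ValueError, match="constant"):
            predict_outcome_svr(rng.uniform(size=24), np.ones(24))

    def test_deterministic_given_seed(self, rng):
        x = rng.uniform(0.05, 0.3, 24)
        y = 3 + 5 * x + rng.normal(0, 1, 24)
        a = predict_outcome_svr(x, y, seed=5)
        b = predict_outcome_svr(x, y, seed=5)
        assert np.array_equal(a.predictions, b.predictions)


# ---------------------------------------------------------------------------
# decoding


def _profiles_from_matrix(M, grid):
    out, labels, dyads = [], [], []
    n_dyads = M.shape[0] // 2
    for i in range(M.shape[0]):
        d = f"d{i // 2}"
        c = "scaffolding" if i % 2 == 0 else "explanation"
        out.append(LagProfile(grid, M[i], np.ones(grid.n_lags, int), d, c))
        labels.append(c)
        dyads.append(d)
    return out, labels, dyads


class TestDecoding:
    grid = LagGrid(1.0, 0.2)  # 11 lags

    def test_separable_lag_found_and_survives_fdr(self, rng):
        n_rec = 24
        M = np.abs(rng.normal(0.1, 0.02, size=(n_rec, self.grid.n_lags)))
        sep = 5  # zero lag index
        M[::2, sep] += 0.5  # scaffolding records cleanly higher
        profs, labels, dyads = _profiles_from_matrix(M, self.grid)
        res = decode_condition_by_lag(profs, labels, dyads, n_permutations=500, seed=0)
        assert res.auc[sep] == 1.0
        assert res.significant[sep]
        assert not res.significant[[0, 1, 2, 8, 9, 10]].any()

    def test_random_labels_yield_no_detections(self, rng):
        clean = 0
        reps = 10
        for rep in range(reps):
            M = np.abs(rng.normal(0.1, 0.02, size=(16, self.grid.n_lags)))
            profs, labels, dyads = _profiles_from_matrix(M, self.grid)
            res = decode_condition_by_lag(profs, labels, dyads, n_permutations=100,
                                          seed=rep)
            if res.significant.sum() == 0:
                clean += 1
        assert clean >= 9

    def test_add_one_lower_bound(self, rng):
        M = np.abs(rng.normal(0.1, 0.05, size=(12, self.grid.n_lags)))
        profs, labels, dyads = _profiles_from_matrix(M, self.grid)
        res = decode_condition_by_lag(profs, labels, dyads, n_permutations=50, seed=3)
        assert np.all(res.p >= 1 / 51)
        assert np.all(res.p <= 1.0)

    def test_auc_invariant_under_monotone_transform(self, rng):
        # a fitted logistic score is monotone in its single feature, so the
        # AUC of any one model cannot change under a strictly increasing
        # transform of that feature (pooling scores across CV folds can
        # shuffle near-ties between folds, so the exact check is in-sample)
        M = np.abs(rng.normal(0.2, 0.05, size=(16, self.grid.n_lags)))
        profs, labels, dyads = _profiles_from_matrix(M, self.grid)
        a = decode_condition_by_lag(profs, labels, dyads, n_permutations=20,
                                    seed=1, cv="in-sample")
        profs2, _, _ = _profiles_from_matrix(np.exp(3 * M), self.grid)
        b = decode_condition_by_lag(profs2, labels, dyads, n_permutations=20,
                                    seed=1, cv="in-sample")
        assert np.allclose(a.auc, b.auc, atol=1e-9)

    def test_best_lags_reported_per_direction(self, rng):
        M = np.abs(rng.normal(0.1, 0.02, size=(20, self.grid.n_lags)))
        M[::2, 2] += 0.4   # negative lag -0.6
        M[::2, 8] += 0.3   # positive lag +0.6
        profs, labels, dyads = _profiles_from_matrix(M, self.grid)
        res = decode_condition_by_lag(profs, labels, dyads, n_permutations=20, seed=2)
        assert res.best_negative[0] == pytest.approx(-0.6)
        assert res.best_positive[0] == pytest.approx(0.6)

    def test_agrees_with_sklearn_logistic_cv(self, rng):
        # dual route: batched IRLS vs sklearn, pooled LODO scores
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score

        diffs = []
        for trial in range(20):
            n_dyads = 8
            y = np.tile([1, 0], n_dyads)
            dyads = np.repeat(np.arange(n_dyads), 2)
            x = rng.normal(size=2 * n_dyads) + 0.8 * y
            xs = (x - x.mean()) / x.std()
            mine = _auc_rows(_cv_scores_batch(xs, y[None, :], dyads, False), y[None, :])[0]
            clf = LogisticRegression(C=1e6, max_iter=5000)
            scores = np.empty(len(y))
            for g in range(n_dyads):
                te = dyads == g
                clf.fit(xs[~te][:, None], y[~te])
                scores[te] = clf.decision_function(xs[te][:, None])
            diffs.append(abs(mine - roc_auc_score(y, scores)))
        # identical up to an occasional single rank swap of near-tied scores
        assert np.median(diffs) == 0.0
        assert max(diffs) <= 1.5 / 64

    def test_dyad_records_never_split_across_folds(self, rng):
        # the fold id IS the dyad id: check scores for a dyad's two records
        # are produced by a model that saw neither record
        M = np.abs(rng.normal(0.1, 0.05, size=(12, self.grid.n_lags)))
        profs, labels, dyads = _profiles_from_matrix(M, self.grid)
        res = decode_condition_by_lag(profs, labels, dyads, n_permutations=10, seed=0)
        assert np.isfinite(res.auc).all()
        # in-sample switch exists and gives (possibly) different AUC
        res_in = decode_condition_by_lag(profs, labels, dyads, n_permutations=10,
                                         seed=0, cv="in-sample")
        assert np.isfinite(res_in.auc).all()
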