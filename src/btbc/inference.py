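"""Group-level statistics on dyadic coupling.

Three analyses hang off the per-dyad coupling summaries:

* **Condition contrasts** — linear mixed-effects models (REML, via
  statsmodels) with instructional approach and personalization as fixed
  factors (treatment coding; explanation / nonpersonalized reference) and
  a random intercept per dyad (optionally participant nested in dyad for
  individual-level motion models).
* **Outcome prediction** — linear support vector regression with nested
  cross-validation: an outer leave-one-out loop estimates generalization
  while an inner 10-fold loop picks the regularization constant from
  powers of two (2⁻¹⁰ … 2¹⁰); performance is the Pearson correlation
  between predicted and actual outcomes.
* **Lag-resolved decoding** — at each lag of the coupling profile, a
  univariate logistic classifier is scored by cross-validated AUC;
  dyad-paired label permutations give per-lag p-values, corrected across
  lags by Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from statsmodels.stats.multitest import multipletests
import statsmodels.formula.api as smf

from .conventions import (
    CONDITION_EXPLANATION,
    CONDITION_SCAFFOLDING,
    NONPERSONALIZED,
)
from .coupling import LagGrid, LagProfile

__all__ = [
    "build_analysis_table",
    "build_individual_motion_table",
    "ModelSummary",
    "fit_condition_model",
    "PredictionResult",
    "predict_outcome_svr",
    "DecodingResult",
    "decode_condition_by_lag",
    "adjust_fdr",
]

DEFAULT_C_GRID = 2.0 ** np.arange(-10, 11)


# ---------------------------------------------------------------------------
# analysis tables


def build_analysis_table(cohort, summaries) -> pd.DataFrame:
    """One row per dyad-condition: coupling summaries + motion + scores.

    ``summaries`` are :class:`~btbc.coupling.BtBCSummary` objects carrying
    dyad_id/condition; motion quantities are the mean raw motion energy of
    each person.  The score identity ``outcome = post - pre`` is checked.
    """
    by_key = {(s.dyad_id, s.condition): s for s in summaries}
    rows = []
    for rec in cohort:
        s = by_key.get((rec.dyad_id, rec.condition))
        if s is None:
            raise KeyError(f"no coupling summary for {rec.dyad_id}/{rec.condition}")
        rows.append(
            {
                "dyad_id": rec.dyad_id,
                "condition": rec.condition,
                "personalization": rec.personalization,
                "overall": s.overall,
                "learner_leading": s.learner_leading,
                "instructor_leading": s.instructor_leading,
                "instructor_motion": float(rec.instructor.values.mean()),
                "learner_motion": float(rec.learner.values.mean()),
                "pre": rec.pre,
                "post": rec.post,
                "outcome": rec.outcome,
            }
        )
    table = pd.DataFrame(rows)
    if not np.allclose(table["outcome"], table["post"] - table["pre"]):
        raise ValueError("outcome must equal post - pre")
    return table


def build_individual_motion_table(cohort) -> pd.DataFrame:
    """Individual-level motion rows: one per participant per condition."""
    rows = []
    for rec in cohort:
        for role, series in (("instructor", rec.instructor), ("learner", rec.learner)):
            rows.append(
                {
                    "dyad_id": rec.dyad_id,
                    "participant_id": f"{rec.dyad_id}-{role}",
                    "role": role,
                    "condition": rec.condition,
                    "personalization": rec.personalization,
                    "motion": float(series.values.mean()),
                    "pre": rec.pre,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed models


@dataclass
class ModelSummary:
    """Fixed-effect table of a fitted mixed model."""

    terms: pd.DataFrame  # columns: term, beta, se, t, p
    random_effects: str
    formula: str
    converged: bool
    warnings: list = field(default_factory=list)

    def coef(self, pattern: str) -> pd.Series:
        """First fixed-effect row whose term name contains ``pattern``."""
        hit = self.terms[self.terms["term"].str.contains(pattern, regex=False)]
        if hit.empty:
            raise KeyError(f"no term matching {pattern!r}")
        return hit.iloc[0]

    def summary(self) -> str:
        lines = [
            "Linear mixed-effects model (REML)",
            f"  {self.formula}",
            f"  random effects: {self.random_effects}",
        ]
        if not self.converged:
            lines.append("  WARNING: fit did not converge / near-singular")
        for w in self.warnings:
            lines.append(f"  WARNING: {w}")
        lines.append(self.terms.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


_TREATMENT_REFS = {
    "condition": CONDITION_EXPLANATION,
    "personalization": NONPERSONALIZED,
}


def _fixed_term(name: str, table: pd.DataFrame) -> str:
    if name in _TREATMENT_REFS and table[name].dtype == object:
        return f"C({name}, Treatment('{_TREATMENT_REFS[name]}'))"
    if table[name].dtype == object:
        return f"C({name})"
    return name


def fit_condition_model(
    table: pd.DataFrame,
    response: str,
    fixed=("condition", "personalization"),
    random: str | tuple = "dyad",
    interaction: bool = True,
) -> ModelSummary:
    """REML mixed model of ``response`` on the fixed factors.

    ``random='dyad'`` fits a random intercept per dyad;
    ``random=('dyad', 'participant')`` adds a participant intercept nested
    within dyad (for individual-level motion models).  Categorical fixed
    factors use treatment coding with explanation / nonpersonalized as
    reference levels.
    """
    fixed = [fixed] if isinstance(fixed, str) else list(fixed)
    for f in fixed:
        if table[f].dtype == object and table[f].nunique() < 2:
            raise ValueError(f"fixed factor {f!r} has fewer than 2 levels")
    if not np.all(np.isfinite(table[response])):
        raise ValueError("response contains non-finite values")
    terms = [_fixed_term(f, table) for f in fixed]
    rhs = " * ".join(terms) if (interaction and len(terms) > 1) else " + ".join(terms)
    formula = f"{response} ~ {rhs}"

    if isinstance(random, str):
        random = (random,)
    vc = None
    if "participant" in random:
        vc = {"participant": "0 + C(participant_id)"}
        re_desc = "intercepts: dyad, participant nested in dyad"
    else:
        re_desc = "intercept: dyad"

    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data=table, groups=table["dyad_id"], vc_formula=vc)
        fit = model.fit(reml=True)
        for w in wlist:
            msg = str(w.message)
            if "singular" in msg.lower() or "converge" in msg.lower():
                caught.append(msg)
    fe = fit.fe_params
    out = pd.DataFrame(
        {
            "term": fe.index,
            "beta": fe.values,
            "se": fit.bse_fe.values,
            "t": fit.tvalues[fe.index].values,
            "p": fit.pvalues[fe.index].values,
        }
    )
    return ModelSummary(
        terms=out,
        random_effects=re_desc,
        formula=formula,
        converged=bool(getattr(fit, "converged", True)) and not caught,
        warnings=caught,
    )


# ---------------------------------------------------------------------------
# SVR outcome prediction


@dataclass
class PredictionResult:
    """Nested-CV prediction of the learning outcome."""

    predictions: np.ndarray
    actual: np.ndarray
    r: float
    p: float
    r2: float
    residual_r: float | None
    residual_p: float | None
    chosen_c: np.ndarray  # per outer fold
    seed: int | None = None

    def summary(self) -> str:
        lines = [
            "SVR outcome prediction (outer leave-one-out, inner 10-fold)",
            f"  n = {len(self.actual)} records",
            f"  predicted-vs-actual r = {self.r:.3f} (p = {self.p:.4g}, R^2 = {self.r2:.3f})",
        ]
        if self.residual_r is not None:
            lines.append(
                f"  after covariate control: residual r = {self.residual_r:.3f} "
                f"(p = {self.residual_p:.4g})"
            )
        return "\n".join(lines)


def _encode_covariate(cov) -> np.ndarray:
    cov = np.asarray(cov)
    if cov.dtype.kind in "fiu":
        return cov.astype(float)
    levels = sorted(pd.unique(cov))
    if len(levels) != 2:
        raise ValueError(f"covariate must be two-level or numeric, got {levels}")
    return (cov == levels[1]).astype(float)


def _residualize(v: np.ndarray, cov: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones_like(cov), cov])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def predict_outcome_svr(
    features,
    outcome,
    covariate=None,
    inner_folds: int = 10,
    seed: int | None = None,
    *,
    outer_groups=None,
    c_grid=None,
) -> PredictionResult:
    """Nested-CV linear SVR of outcome on overall coupling.

    The outer loop leaves one record out (or one group via
    ``outer_groups``); the inner 10-fold loop selects C from powers of two
    on training data only, and features are standardized with
    training-fold statistics.  If ``covariate`` is given (e.g. the
    condition label) it is added as a feature, and ``residual_r``
    additionally reports the predicted-vs-actual correlation after both
    are residualized on the covariate.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError(f"need at least 10 records, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")
    cov = None
    if covariate is not None:
        cov = _encode_covariate(covariate)
        X = np.column_stack([X, cov])
    c_grid = DEFAULT_C_GRID if c_grid is None else np.asarray(c_grid, dtype=float)

    if outer_groups is None:
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        groups = np.asarray(outer_groups)
        folds = []
        for g in pd.unique(groups):
            test = np.flatnonzero(groups == g)
            folds.append((np.flatnonzero(groups != g), test))

    rng = np.random.default_rng(seed)
    preds = np.empty(n)
    chosen = np.empty(len(folds))
    for f_idx, (tr, te) in enumerate(folds):
        if len(tr) < inner_folds:
            raise ValueError("training folds smaller than the inner CV fold count")
        Xtr, ytr = X[tr], y[tr]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr_s = (Xtr - mu) / sd
        inner = KFold(n_splits=inner_folds, shuffle=True,
                      random_state=int(rng.integers(2**31)))
        splits = list(inner.split(Xtr_s))
        if any(len(va) < 2 for _, va in splits):
            raise ValueError("inner validation folds smaller than 2 records")
        # C is selected by the metric the analysis reports: Pearson r of the
        # pooled inner-validation predictions.  (Inner MSE would prefer the
        # near-constant model whenever the within-cohort signal is weak, and
        # pooled leave-one-out predictions of near-constant models are
        # anti-correlated with the held-out outcome.)
        inner_preds = np.empty((len(c_grid), len(ytr)))
        for itr, iva in splits:
            for ci, c in enumerate(c_grid):
                m = SVR(kernel="linear", C=c)
                m.fit(Xtr_s[itr], ytr[itr])
                inner_preds[ci, iva] = m.predict(Xtr_s[iva])
        score = np.full(len(c_grid), -np.inf)
        for ci in range(len(c_grid)):
            if np.ptp(inner_preds[ci]) > 0:
                score[ci] = stats.pearsonr(inner_preds[ci], ytr)[0]
        best = c_grid[int(np.argmax(score))]
        chosen[f_idx] = best
        final = SVR(kernel="linear", C=best)
        final.fit(Xtr_s, ytr)
        preds[te] = final.predict((X[te] - mu) / sd)

    r, p = stats.pearsonr(preds, y)
    residual_r = residual_p = None
    if cov is not None:
        rr, rp = stats.pearsonr(_residualize(preds, cov), _residualize(y, cov))
        residual_r, residual_p = float(rr), float(rp)
    return PredictionResult(
        predictions=preds,
        actual=y,
        r=float(r),
        p=float(p),
        r2=float(r) ** 2,
        residual_r=residual_r,
        residual_p=residual_p,
        chosen_c=chosen,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# lag-resolved decoding


@dataclass
class DecodingResult:
    """Per-lag AUC with permutation p-values and FDR mask."""

    lags: np.ndarray
    auc: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    n_permutations: int
    best_positive: tuple  # (lag_s, auc)
    best_negative: tuple
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_s": self.lags,
                "auc": self.auc,
                "p": self.p,
                "q": self.q,
                "significant": self.significant,
            }
        )

    def summary(self) -> str:
        nsig = int(self.significant.sum())
        return "\n".join(
            [
                "Lag-resolved decoding of instructional approach (logistic / AUC)",
                f"  {len(self.lags)} lags, {self.n_permutations} label permutations",
                f"  FDR-significant lags: {nsig}",
                f"  best learner-leading lag: {self.best_positive[0]:+.2f} s "
                f"(AUC = {self.best_positive[1]:.3f})",
                f"  best instructor-leading lag: {self.best_negative[0]:+.2f} s "
                f"(AUC = {self.best_negative[1]:.3f})",
            ]
        )


def adjust_fdr(p_values, alpha: float = 0.05):
    """Benjamini–Hochberg step-up correction.

    Returns ``(reject, q_values)``; q-values are monotone non-decreasing
    after sorting by p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, q


def _fit_logistic_batch(x: np.ndarray, Y: np.ndarray, ridge: float = 1e-6,
                        max_iter: int = 60, tol: float = 1e-10) -> np.ndarray:
    """Newton-IRLS fit of ``logit P(y=1) = a + b x`` for many label vectors.

    ``Y`` is (n_problems, n_obs); returns coefficients (n_problems, 2) as
    columns (a, b).  A tiny ridge keeps the Hessian invertible and bounds
    the divergence on separable data (which leaves the score ranking, and
    hence AUC, unaffected).  Fully vectorized so thousands of permutation
    refits cost one pass of array arithmetic.
    """
    M, n = Y.shape
    a = np.zeros(M)
    b = np.zeros(M)
    for _ in range(max_iter):
        eta = np.clip(a[:, None] + b[:, None] * x[None, :], -30.0, 30.0)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p) + 1e-12
        resid = Y - p
        g0 = resid.sum(axis=1) - ridge * a
        g1 = resid @ x - ridge * b
        h00 = w.sum(axis=1) + ridge
        h01 = w @ x
        h11 = w @ (x * x) + ridge
        det = h00 * h11 - h01 * h01
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        # damp oversized Newton steps (separable data)
        scale = np.maximum(1.0, np.sqrt(da * da + db * db) / 10.0)
        a += da / scale
        b += db / scale
        if max(np.abs(da).max(), np.abs(db).max()) < tol:
            break
    return np.column_stack([a, b])


def _cv_scores_batch(x: np.ndarray, Y: np.ndarray, fold_of: np.ndarray,
                     in_sample: bool) -> np.ndarray:
    """Pooled (out-of-fold) logistic decision scores for each label row."""
    M, n = Y.shape
    scores = np.zeros((M, n))
    if in_sample:
        coef = _fit_logistic_batch(x, Y)
        return coef[:, [0]] + coef[:, [1]] * x[None, :]
    for f in np.unique(fold_of):
        te = fold_of == f
        tr = ~te
        ytr = Y[:, tr]
        coef = _fit_logistic_batch(x[tr], ytr)
        s = coef[:, [0]] + coef[:, [1]] * x[None, te]
        # single-class training folds give no usable classifier
        degenerate = (ytr.min(axis=1) == ytr.max(axis=1))
        if degenerate.any():
            warnings.warn(f"fold {f}: single-class training set, skipped")
            s[degenerate] = 0.0
        scores[:, te] = s
    return scores


def _auc_rows(scores: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise ROC AUC via the rank formula (ties get average ranks)."""
    ranks = stats.rankdata(scores, axis=1)
    npos = Y.sum(axis=1)
    nneg = Y.shape[1] - npos
    rpos = (ranks * Y).sum(axis=1)
    return (rpos - npos * (npos + 1) / 2.0) / (npos * nneg)


def decode_condition_by_lag(
    profiles,
    labels,
    dyads,
    n_permutations: int = 1000,
    cv: str = "lodo",
    seed: int | None = None,
    alpha: float = 0.05,
) -> DecodingResult:
    """Decode the instructional approach from coupling, lag by lag.

    At each lag the single coupling value is the feature of a logistic
    classifier scored by leave-one-dyad-out cross-validated AUC
    (``cv='in-sample'`` skips the CV).  The permutation null re-runs the
    identical procedure with dyad-paired shuffled labels — a dyad's two
    records swap or keep their labels together, respecting the
    repeated-measures exchangeability — and per-lag add-one p-values are
    FDR-corrected across lags.
    """
    profiles = list(profiles)
    if hasattr(profiles[0], "values") and hasattr(profiles[0], "grid"):
        lags = profiles[0].offsets
        M = np.vstack([p.values for p in profiles])
    else:
        raise TypeError("profiles must be LagProfile objects")
    labels = np.asarray(labels)
    dyads = np.asarray(dyads)
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly two condition labels, got {classes}")
    positive = CONDITION_SCAFFOLDING if CONDITION_SCAFFOLDING in classes else classes[1]
    y = (labels == positive).astype(int)
    if cv not in ("lodo", "in-sample"):
        raise ValueError("cv must be 'lodo' or 'in-sample'")
    in_sample = cv == "in-sample"

    rng = np.random.default_rng(seed)
    unique_dyads = pd.unique(dyads)
    # pre-draw dyad-paired label flips, shared across lags (label
    # permutations are drawn once per rendition, then scored at every lag)
    flips = rng.integers(0, 2, size=(n_permutations, len(unique_dyads))).astype(bool)
    dyad_index = {d: i for i, d in enumerate(unique_dyads)}
    rec_dyad_idx = np.array([dyad_index[d] for d in dyads])
    fold_of = rec_dyad_idx
    # row 0 = true labels, rows 1.. = dyad-paired permutations
    Y = np.vstack([y[None, :],
                   np.where(flips[:, rec_dyad_idx], 1 - y[None, :], y[None, :])])

    n_lags = len(lags)
    auc = np.empty(n_lags)
    pvals = np.empty(n_lags)
    for li in range(n_lags):
        x = M[:, li]
        sd = x.std()
        xs = (x - x.mean()) / sd if sd > 0 else x - x.mean()
        scores = _cv_scores_batch(xs, Y, fold_of, in_sample)
        aucs = _auc_rows(scores, Y)
        auc[li] = aucs[0]
        pvals[li] = (1 + int(np.sum(aucs[1:] >= aucs[0]))) / (1 + n_permutations)
    reject, q = adjust_fdr(pvals, alpha=alpha)

    pos = lags > 0
    neg = lags < 0
    bp = (float(lags[pos][np.argmax(auc[pos])]), float(auc[pos].max())) if pos.any() else (np.nan, np.nan)
    bn = (float(lags[neg][np.argmax(auc[neg])]), float(auc[neg].max())) if neg.any() else (np.nan, np.nan)
    return DecodingResult(
        lags=lags,
        auc=auc,
        p=pvals,
        q=q,
        significant=reject,
        n_permutations=n_permutations,
        best_positive=bp,
        best_negative=bn,
        seed=seed,
    )
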