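"""Predictor evaluation: logistic screening, ROC/AUC, cutoffs, AUC comparison.

The battery mirrors standard clinical-predictor methodology: univariate
binary logistic regression per indicator (Wald odds ratios, 95% CIs,
p-values), stepwise multivariate logistic regression over the univariately
significant candidates, ROC curves with Youden-index cutoffs, and DeLong's
paired test for comparing correlated AUCs.  Missing indicator values are
handled complete-case per model, with the n used reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class LogisticResult:
    variable: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    analysis: str = "univariate"      # univariate | multivariate
    n: int = 0
    status: str = "ok"                # ok | separated | degenerate

    def as_dict(self) -> dict:
        return dict(variable=self.variable, odds_ratio=self.odds_ratio,
                    ci_low=self.ci_low, ci_high=self.ci_high,
                    p_value=self.p_value, analysis=self.analysis,
                    n=self.n, status=self.status)


@dataclass
class ROCResult:
    variable: str
    auc: float
    cutoff: float
    sensitivity: float    # percent, at the cutoff
    specificity: float    # percent
    n_pos: int
    n_neg: int

    def as_dict(self) -> dict:
        return dict(variable=self.variable, auc=self.auc, cutoff=self.cutoff,
                    sensitivity=self.sensitivity, specificity=self.specificity,
                    n_pos=self.n_pos, n_neg=self.n_neg)


def _complete_cases(*arrays):
    cols = [np.asarray(a, dtype=float) for a in arrays]
    mask = np.ones(len(cols[0]), dtype=bool)
    for c in cols:
        mask &= np.isfinite(c)
    return [c[mask] for c in cols]


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    if len(classes) < 2:
        raise ValueError("outcome has a single class; logistic fit undefined")
    return y


def _fit_logit(X: np.ndarray, y: np.ndarray):
    """ML logistic fit; returns (result, separated_flag)."""
    model = sm.Logit(y, X)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            res = model.fit(disp=0, method="bfgs", maxiter=500)
        p = res.predict(X)
    # fitted probabilities at the boundary, or exploding SEs -> separation
    if np.all((p > 0.999) == (y > 0.5)) or not np.all(np.isfinite(res.bse)):
        separated = True
    if np.any(np.abs(res.params) > 25):
        separated = True
    return res, separated


def univariate_logistic(x: Sequence, y: Sequence,
                        variable: str = "x") -> LogisticResult:
    """Fit logit P(y=1) = b0 + b1*x and report OR = exp(b1) with Wald CI/p.

    Complete-case: rows with a missing predictor are dropped.  A constant
    predictor yields the null result (OR 1, p 1) with status ``degenerate``;
    complete separation is flagged, not silently reported.
    """
    x, y = _complete_cases(x, y)
    y = _check_binary(y)
    n = len(y)
    if np.ptp(x) == 0:
        return LogisticResult(variable, 1.0, np.nan, np.nan, 1.0,
                              n=n, status="degenerate")
    X = sm.add_constant(np.asarray(x, dtype=float))
    res, separated = _fit_logit(X, y)
    ci = res.conf_int()
    beta = res.params[1]
    return LogisticResult(
        variable=variable,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(ci[1, 0])),
        ci_high=float(np.exp(ci[1, 1])),
        p_value=float(res.pvalues[1]),
        n=n,
        status="separated" if separated else "ok",
    )


def _drop_redundant_columns(X: pd.DataFrame) -> pd.DataFrame:
    """Drop columns that do not increase design rank (duplicates, constants)."""
    keep = []
    base = np.ones((len(X), 1))
    for col in X.columns:
        trial = np.column_stack([base] + [X[c].to_numpy() for c in keep]
                                + [X[col].to_numpy()])
        if np.linalg.matrix_rank(trial) > len(keep) + 1:
            keep.append(col)
    return X[keep]


def multivariate_stepwise(
    X: pd.DataFrame,
    y: Sequence,
    direction: str = "backward",
    alpha: float = 0.05,
) -> list[LogisticResult]:
    """Stepwise multivariate logistic regression over candidate predictors.

    Backward (default): start from the full candidate model and repeatedly
    drop the least significant variable with Wald p > ``alpha``.  Forward:
    repeatedly add the candidate with the smallest p-value-on-entry <=
    ``alpha``.  Collinear/duplicate candidates are pruned before fitting.
    Complete-case over the candidate set.
    """
    if X.shape[1] == 0:
        raise ValueError("need at least one candidate predictor")
    df = X.astype(float).copy()
    df["__y__"] = np.asarray(y, dtype=float)
    df = df.dropna()
    yv = _check_binary(df.pop("__y__").to_numpy())
    df = _drop_redundant_columns(df)

    def fit(cols):
        Xm = sm.add_constant(df[cols].to_numpy())
        return _fit_logit(Xm, yv)

    cols = list(df.columns)
    if direction == "backward":
        while cols:
            res, _ = fit(cols)
            pvals = dict(zip(cols, res.pvalues[1:]))
            worst = max(pvals, key=pvals.get)
            if pvals[worst] <= alpha:
                break
            cols.remove(worst)
    elif direction == "forward":
        remaining, cols = list(df.columns), []
        while remaining:
            trials = {}
            for c in remaining:
                res, _ = fit(cols + [c])
                trials[c] = res.pvalues[-1]
            best = min(trials, key=trials.get)
            if trials[best] > alpha:
                break
            cols.append(best)
            remaining.remove(best)
    else:
        raise ValueError("direction must be 'backward' or 'forward'")

    if not cols:
        return []
    res, separated = fit(cols)
    ci = res.conf_int()
    out = []
    for k, c in enumerate(cols, start=1):
        out.append(LogisticResult(
            variable=c,
            odds_ratio=float(np.exp(res.params[k])),
            ci_low=float(np.exp(ci[k, 0])),
            ci_high=float(np.exp(ci[k, 1])),
            p_value=float(res.pvalues[k]),
            analysis="multivariate",
            n=len(yv),
            status="separated" if separated else "ok",
        ))
    return out


# ---------------------------------------------------------------------------
# ROC


def roc_analysis(score: Sequence, y: Sequence,
                 variable: str = "score") -> ROCResult:
    """AUC, Youden-optimal cutoff, and sensitivity/specificity at the cutoff.

    The AUC is the probability that a positive outranks a negative (ties half
    counted); orientation is taken as given — an inversely oriented predictor
    reports AUC < 0.5.  The cutoff maximizes Youden's J = sens + spec - 1
    over all observed thresholds, predicting positive when score >= cutoff;
    on J ties the higher (more specific) cutoff wins.
    """
    score, y = _complete_cases(score, y)
    y = _check_binary(y)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    auc = float(roc_auc_score(y, score))
    fpr, tpr, thresholds = roc_curve(y, score, drop_intermediate=False)
    # the first row is the degenerate predict-nothing rule (threshold +inf,
    # J = 0); the cutoff is chosen among observed score values only
    fpr, tpr, thresholds = fpr[1:], tpr[1:], thresholds[1:]
    j = tpr - fpr
    best = int(np.argmax(j))          # thresholds descend: first max = highest cutoff
    cutoff = float(thresholds[best])
    return ROCResult(variable=variable, auc=auc, cutoff=cutoff,
                     sensitivity=float(100.0 * tpr[best]),
                     specificity=float(100.0 * (1.0 - fpr[best])),
                     n_pos=n_pos, n_neg=n_neg)


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def compare_aucs(score_a: Sequence, score_b: Sequence, y: Sequence) -> float:
    """DeLong's paired two-sided test of H0: AUC_a = AUC_b.

    Both scores must be measured on the same subjects with the same outcome,
    so the AUC estimates are correlated; the test accounts for the pairing
    through the covariance of the placement values.  Identical (or rank
    identical) predictors return p = 1.
    """
    a, b, y = _complete_cases(score_a, score_b, y)
    y = _check_binary(y)
    pos = y == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("need both outcome classes")
    if m < 2 or n < 2:
        return 1.0          # covariance of placements undefined; no evidence

    aucs, v10, v01 = [], [], []
    for s in (a, b):
        x, z = s[pos], s[~pos]
        rx = _midrank(np.concatenate([x, z]))
        r1, r0 = _midrank(x), _midrank(z)
        auc = (rx[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        aucs.append(auc)
        v10.append((rx[:m] - r1) / n)           # placements of positives
        v01.append(1.0 - (rx[m:] - r0) / m)     # placements of negatives
    aucs = np.array(aucs)
    v10, v01 = np.array(v10), np.array(v01)

    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = aucs[0] - aucs[1]
    if var <= 0 or np.isclose(var, 0.0):
        return 1.0 if np.isclose(diff, 0.0) else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# group comparisons


def paired_comparison(x: Sequence, y: Sequence) -> dict:
    """Paired-sample t-test between two matched measurement vectors."""
    x, y = _complete_cases(x, y)
    if np.allclose(x, y):
        return {"t": 0.0, "p": 1.0, "n": len(x)}
    t, p = sps.ttest_rel(x, y)
    return {"t": float(t), "p": float(p), "n": len(x)}


def anova_oneway(*groups) -> dict:
    """One-way ANOVA across three or more groups."""
    clean = [np.asarray(g, dtype=float) for g in groups]
    clean = [g[np.isfinite(g)] for g in clean]
    if len(clean) < 3:
        raise ValueError("one-way ANOVA here requires >= 3 groups")
    if np.ptp(np.concatenate(clean)) == 0:
        return {"F": 0.0, "p": 1.0}
    f, p = sps.f_oneway(*clean)
    if not np.isfinite(f):
        return {"F": 0.0, "p": 1.0}
    return {"F": float(f), "p": float(p)}


def group_comparisons(audiometry: pd.DataFrame) -> pd.DataFrame:
    """Audiometric group contrasts on a cohort table.

    Expects columns: patient_id, pta_pre, pta_post, wrs_pre, wrs_post,
    healthy_pta_pre, healthy_pta_post, healthy_wrs_pre, healthy_wrs_post.
    Reports paired t-tests (affected pre vs post, healthy pre vs post,
    affected vs healthy change) and a one-way ANOVA of the affected-side
    changes across preoperative AAO-HNS classes when a ``aao_pre`` column
    is present.
    """
    rows = []

    def add(contrast, res):
        rows.append({"contrast": contrast, **res})

    add("affected PTA pre vs post",
        paired_comparison(audiometry["pta_pre"], audiometry["pta_post"]))
    add("affected WRS pre vs post",
        paired_comparison(audiometry["wrs_pre"], audiometry["wrs_post"]))
    add("healthy PTA pre vs post",
        paired_comparison(audiometry["healthy_pta_pre"],
                          audiometry["healthy_pta_post"]))
    add("healthy WRS pre vs post",
        paired_comparison(audiometry["healthy_wrs_pre"],
                          audiometry["healthy_wrs_post"]))
    d_pta_aff = audiometry["pta_post"] - audiometry["pta_pre"]
    d_pta_hea = audiometry["healthy_pta_post"] - audiometry["healthy_pta_pre"]
    add("PTA change affected vs healthy", paired_comparison(d_pta_aff, d_pta_hea))
    d_wrs_aff = audiometry["wrs_post"] - audiometry["wrs_pre"]
    d_wrs_hea = audiometry["healthy_wrs_post"] - audiometry["healthy_wrs_pre"]
    add("WRS change affected vs healthy", paired_comparison(d_wrs_aff, d_wrs_hea))

    if "aao_pre" in audiometry.columns:
        groups = [g["pta_post"] - g["pta_pre"]
                  for _, g in audiometry.groupby("aao_pre")]
        if len(groups) >= 3:
            res = anova_oneway(*groups)
            add("PTA change across preop AAO-HNS classes",
                {"F": res["F"], "p": res["p"]})
    return pd.DataFrame(rows)
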