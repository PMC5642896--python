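"""Risk-model ROC analysis: AUC, paired AUC comparison, Youden optimum.

Risk models are in-sample logistic fits of case status on clinical
covariates (age, sex, self-reported ethnicity indicators with the largest
stratum as reference) optionally augmented with genetic features
(slow-acetylator status or a single coded genotype).  AUC uses the exact
pairwise (Mann-Whitney) statistic; curves for plotting use the distinct
observed scores as thresholds.  Two models fitted on the same samples are
compared by the paired placement-value method: per-case and per-control
placement values give the covariance of the two AUC estimates, a normal
z-test of the AUC difference follows.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import SampleRecord, samples_to_frame

CLINICAL_FEATURES = ("age", "sex", "ethnicity")


@dataclass
class RiskModel:
    """A fitted risk model with per-sample scores."""

    name: str
    features: tuple[str, ...]
    params: pd.Series
    scores: pd.Series            # fitted probabilities, indexed by sample_id
    labels: pd.Series            # 1 = case, aligned with scores
    separation: bool = False

    def auc(self) -> float:
        return auc(self.scores.to_numpy(), self.labels.to_numpy())


def _design_matrix(
    frame: pd.DataFrame,
    features: tuple[str, ...],
    genetic: dict[str, pd.Series] | None,
) -> pd.DataFrame:
    cols = {}
    for f in features:
        if f == "age":
            cols["age"] = frame["age"].astype(float)
        elif f == "sex":
            cols["female"] = (frame["sex"] == "F").astype(float)
        elif f == "ethnicity":
            ref = frame["ethnicity"].value_counts().idxmax()
            for lev in sorted(frame["ethnicity"].unique()):
                if lev != ref:
                    cols[f"eth_{lev}"] = (frame["ethnicity"] == lev).astype(float)
        elif genetic is not None and f in genetic:
            cols[f] = genetic[f].reindex(frame.index).astype(float)
        else:
            raise KeyError(f"unknown feature {f!r}")
    return pd.DataFrame(cols, index=frame.index)


_CAP = 15.0  # coefficient cap used when a fit separates


def fit_risk_model(
    samples: list[SampleRecord],
    features: tuple[str, ...] = CLINICAL_FEATURES,
    genetic: dict[str, pd.Series] | None = None,
    name: str | None = None,
) -> RiskModel:
    """Fit a logistic risk model and score every complete-case sample.

    On separation or non-convergence the coefficients are capped at
    +/- ``_CAP`` and the model is still scored, with ``separation=True``.
    """
    import statsmodels.api as sm

    frame = samples_to_frame(samples).set_index("sample_id")
    y = (frame["status"] == "case").astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    X = _design_matrix(frame, features, genetic)
    ok = ~X.isna().any(axis=1)
    Xc, yc = X.loc[ok], y.loc[ok]
    design = np.column_stack([np.ones(len(Xc)), Xc.to_numpy()])
    separation = False
    try:
        fit = sm.Logit(yc.to_numpy(), design).fit(disp=0, maxiter=200)
        params = fit.params
        if not fit.mle_retvals.get("converged", True) or np.abs(params).max() > _CAP:
            separation = True
    except Exception:
        separation = True
        params = None
    if separation:
        fit = sm.Logit(yc.to_numpy(), design).fit(
            disp=0, maxiter=500, method="bfgs", start_params=np.zeros(design.shape[1])
        )
        params = np.clip(fit.params, -_CAP, _CAP)
    lin = design @ params
    scores = 1.0 / (1.0 + np.exp(-lin))
    return RiskModel(
        name=name or "+".join(features),
        features=tuple(features),
        params=pd.Series(params, index=["intercept", *Xc.columns]),
        scores=pd.Series(scores, index=Xc.index, name="score"),
        labels=yc,
        separation=separation,
    )


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the exact pairwise statistic with 0.5 credit for ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    cases, controls = s[y], s[~y]
    # rank formula: identical to pairwise comparison with tie credit
    r = stats.rankdata(np.concatenate([cases, controls]))
    n1, n0 = len(cases), len(controls)
    return float((r[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-case and per-control placement values (DeLong V10, V01)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    cases, controls = s[y], s[~y]
    cmp = (cases[:, None] > controls[None, :]).astype(float)
    cmp += 0.5 * (cases[:, None] == controls[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


@dataclass
class RocComparison:
    model_a: str
    model_b: str
    auc_a: float
    auc_b: float
    delta: float
    variance: float
    p: float
    youden_a: float | None = None
    youden_b: float | None = None


def delong_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    name_a: str = "A",
    name_b: str = "B",
) -> RocComparison:
    """Paired comparison of two AUCs on the same samples.

    The variance of the AUC difference combines the placement-value
    covariances over cases and over controls; identical scores give a zero
    variance and p = 1 by convention.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("score vectors and labels must be aligned")
    auc_a_, auc_b_ = auc(sa, y), auc(sb, y)
    v10a, v01a = _placements(sa, y)
    v10b, v01b = _placements(sb, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a_ - auc_b_
    if var <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    ja = youden_optimal(sa, y)
    jb = youden_optimal(sb, y)
    return RocComparison(
        model_a=name_a, model_b=name_b,
        auc_a=auc_a_, auc_b=auc_b_,
        delta=float(delta), variance=float(max(var, 0.0)), p=p,
        youden_a=ja[1], youden_b=jb[1],
    )


def youden_optimal(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float]:
    """Maximise J over all distinct-score thresholds.

    A sample is called positive when its score >= threshold; thresholds are
    the distinct scores plus a +inf sentinel (nothing positive).  Ties in J
    break toward higher specificity (the higher threshold).  Returns
    (threshold, J, sensitivity, specificity) at the optimum.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    thresholds = np.concatenate([np.unique(s), [np.inf]])
    best = (-np.inf, -np.inf, 0.0, 0.0, 0.0)
    n1, n0 = y.sum(), (~y).sum()
    for t in thresholds:
        pos = s >= t
        sens = (pos & y).sum() / n1
        spec = (~pos & ~y).sum() / n0
        j = sens + spec - 1
        # strict improvement, or equal J at higher threshold (higher spec)
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and t > best[1]):
            best = (j, t, sens, spec)
    j, t, sens, spec = best
    return float(t), float(j), float(sens), float(spec)


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC curve points (FPR, TPR) at every distinct-score threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1], [-np.inf]])
    rows = []
    n1, n0 = y.sum(), (~y).sum()
    for t in thresholds:
        pos = s >= t
        rows.append(
            {
                "threshold": t,
                "fpr": float((pos & ~y).sum() / n0),
                "tpr": float((pos & y).sum() / n1),
            }
        )
    return pd.DataFrame(rows)


def compare_models(
    samples: list[SampleRecord],
    genetic: dict[str, pd.Series],
    base_features: tuple[str, ...] = CLINICAL_FEATURES,
) -> tuple[dict[str, RiskModel], pd.DataFrame]:
    """Fit the clinical model and clinical+genetic variants; compare each
    augmented model against the clinical baseline by the paired AUC test."""
    models: dict[str, RiskModel] = {}
    clinical = fit_risk_model(samples, base_features, name="clinical")
    models["clinical"] = clinical
    rows = []
    for feat in genetic:
        m = fit_risk_model(
            samples, (*base_features, feat), genetic=genetic, name=f"clinical+{feat}"
        )
        models[m.name] = m
        shared = clinical.scores.index.intersection(m.scores.index)
        cmp = delong_test(
            m.scores.loc[shared].to_numpy(),
            clinical.scores.loc[shared].to_numpy(),
            clinical.labels.loc[shared].to_numpy(),
            name_a=m.name,
            name_b="clinical",
        )
        rows.append(
            {
                "model_a": cmp.model_a, "model_b": cmp.model_b,
                "auc_a": cmp.auc_a, "auc_b": cmp.auc_b,
                "delta": cmp.delta, "p": cmp.p,
                "youden_a": cmp.youden_a, "youden_b": cmp.youden_b,
            }
        )
    return models, pd.DataFrame(rows)
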