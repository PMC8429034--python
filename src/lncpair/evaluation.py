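"""Time-dependent ROC, optimal cutoff, risk groups and KM validation.

The ROC at horizon t uses the cumulative-case / dynamic-control
definition: cases experienced an event by t, controls are still at risk
beyond t.  Subjects censored before t drop out of both sets, and case
contributions are reweighted by the inverse Kaplan-Meier estimate of the
censoring survival function so that censoring before the horizon does
not bias the curve.  With no censoring before the horizon the AUC
reduces to the Mann-Whitney probability that a case outranks a control.

The cutoff splitting the cohort into high/low risk is chosen either by
minimizing the AIC of a one-covariate Cox model on the dichotomized
score over all candidate midpoints (default), or by maximizing Youden's
J on the horizon ROC.  Ties at the cutoff go to the low-risk group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from ._cox import breslow_loglik, cox1_fit


def cox1_loglik_null(time, event) -> float:
    """Partial log-likelihood of the covariate-free (null) Cox model."""
    return breslow_loglik(np.zeros(len(time)), time, event)

logger = logging.getLogger("lncpair")


@dataclass
class TimedROC:
    horizon: float
    thresholds: np.ndarray  # descending, leading +inf
    sens: np.ndarray
    spec: np.ndarray
    auc: float


@dataclass
class CutoffResult:
    cutoff: float
    method: str
    criterion_value: float
    unstable: bool = False


def _align(scores: pd.Series, clinical: pd.DataFrame):
    common = [s for s in scores.index if s in clinical.index]
    sc = scores.loc[common]
    time = clinical.loc[common, "os_time"].to_numpy(float)
    event = clinical.loc[common, "os_event"].to_numpy(float)
    ok = np.isfinite(time) & np.isfinite(event)
    return sc.to_numpy(float)[ok], time[ok], event[ok]


def _censoring_survival(time, event):
    """KM estimate of the censoring distribution G(t)."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - event)
    return kmf


def timed_roc(scores: pd.Series, clinical: pd.DataFrame,
              horizon: float) -> TimedROC:
    """KM-weighted cumulative/dynamic ROC of the score at a fixed horizon."""
    s, time, event = _align(scores, clinical)
    case = (time <= horizon) & (event == 1)
    control = time > horizon
    if case.sum() == 0:
        raise ValueError(f"no events observed before horizon {horizon}")
    if control.sum() == 0:
        raise ValueError(f"no subjects at risk beyond horizon {horizon}")

    G = _censoring_survival(time, event)
    g_case = G.survival_function_at_times(time[case] - 1e-9).to_numpy(float)
    g_case = np.clip(g_case, 1e-12, None)
    w_case = 1.0 / g_case

    s_case, s_ctrl = s[case], s[control]
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    sens = np.array([(w_case * (s_case >= c)).sum() / w_case.sum()
                     for c in thresholds])
    fpr = np.array([(s_ctrl >= c).mean() for c in thresholds])
    auc = float(np.trapezoid(sens, fpr))
    return TimedROC(horizon=float(horizon), thresholds=thresholds,
                    sens=sens, spec=1.0 - fpr, auc=auc)


def find_cutoff(roc: TimedROC | None, scores: pd.Series,
                clinical: pd.DataFrame, method: str = "aic") -> CutoffResult:
    """Optimal dichotomization cutoff of the risk score.

    ``aic``: candidate cutoffs are midpoints between consecutive distinct
    scores; each dichotomization is scored by the AIC of a one-covariate
    Cox fit and the minimizer wins (first minimum on ties).  The result
    is flagged unstable when even the best split's likelihood-ratio
    statistic stays below 10 — about the expected maximum over the many
    correlated candidate splits when the score carries no survival
    signal.  ``youden``: maximizes sens + spec - 1 on the horizon ROC;
    the reported cutoff is the midpoint below the winning threshold so
    that "score > cutoff" reproduces the ROC's "score >= threshold"
    positive set.
    """
    s, time, event = _align(scores, clinical)
    distinct = np.unique(s)
    if distinct.size < 2:
        raise ValueError("need at least 2 distinct scores")
    if method == "aic":
        candidates = (distinct[:-1] + distinct[1:]) / 2.0
        null_ll = cox1_loglik_null(time, event)
        aics = np.full(candidates.size, np.inf)
        lls = np.full(candidates.size, -np.inf)
        for i, c in enumerate(candidates):
            x = (s > c).astype(float)
            if x.std() == 0:
                continue  # degenerate dichotomization
            fit = cox1_fit(x, time, event)
            if fit.converged:
                aics[i] = fit.aic
                lls[i] = fit.loglik
        best = int(np.argmin(aics))
        lr_best = 2.0 * (lls[best] - null_ll)
        return CutoffResult(cutoff=float(candidates[best]), method="aic",
                            criterion_value=float(aics[best]),
                            unstable=bool(lr_best < 10.0))
    if method == "youden":
        if roc is None:
            raise ValueError("youden method requires a TimedROC")
        j = roc.sens + roc.spec - 1.0
        finite = np.isfinite(roc.thresholds)
        best = int(np.argmax(np.where(finite, j, -np.inf)))
        thr = roc.thresholds[best]
        below = distinct[distinct < thr]
        cutoff = (thr + below[-1]) / 2.0 if below.size else thr - 1e-9
        return CutoffResult(cutoff=float(cutoff), method="youden",
                            criterion_value=float(j[best]))
    raise ValueError(f"unknown cutoff method {method!r}")


def assign_groups(scores: pd.Series, cutoff: float):
    """score > cutoff -> high risk; score <= cutoff -> low risk."""
    from .signature import RiskProfile

    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    groups = pd.Series(np.where(scores > cutoff, "high", "low"),
                       index=scores.index, name="risk_group")
    return RiskProfile(scores=scores, groups=groups, cutoff=float(cutoff))


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]
    statistic: float
    p: float
    group_sizes: dict[str, int] = field(default_factory=dict)


def km_logrank(groups: pd.Series, clinical: pd.DataFrame) -> KMResult:
    """Per-group Kaplan-Meier curves and the two-sample log-rank test."""
    common = [s for s in groups.index if s in clinical.index]
    g = groups.loc[common]
    time = clinical.loc[common, "os_time"].to_numpy(float)
    event = clinical.loc[common, "os_event"].to_numpy(float)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")
    curves = {}
    for lab in labels:
        m = (g == lab).to_numpy()
        if event[m].sum() == 0:
            logger.warning("group %s has zero events", lab)
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event_observed=event[m])
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame({
            "time": sf.index.to_numpy(float),
            "survival": sf.iloc[:, 0].to_numpy(float),
        })
    res = multivariate_logrank_test(time, g.to_numpy(), event)
    return KMResult(curves=curves, statistic=float(res.test_statistic),
                    p=float(res.p_value),
                    group_sizes={lab: int((g == lab).sum()) for lab in labels})


# --- clinical comparator ROC ----------------------------------------------

GRADE_CODE = {"G1": 1, "G2": 2, "G3": 3, "G4": 4}
STAGE_CODE = {"I": 1, "II": 2, "III": 3, "IV": 4,
              "Stage I": 1, "Stage II": 2, "Stage III": 3, "Stage IV": 4}


def encode_clinical_ordinal(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric 1-dimensional scores for age/gender/grade/stage comparators.

    Grade and stage use ordinal integer coding; unknown levels become
    missing.  Gender is coded female=0, male=1.
    """
    out = pd.DataFrame(index=clinical.index)
    if "age" in clinical:
        out["age"] = pd.to_numeric(clinical["age"], errors="coerce")
    if "gender" in clinical:
        out["gender"] = clinical["gender"].map({"female": 0.0, "male": 1.0})
    if "grade" in clinical:
        out["grade"] = clinical["grade"].map(GRADE_CODE)
    if "stage" in clinical:
        out["stage"] = clinical["stage"].map(STAGE_CODE)
    return out


def clinical_roc_comparison(scores: pd.Series, clinical: pd.DataFrame,
                            horizon: float) -> pd.DataFrame:
    """Horizon AUC of the risk score next to each clinical comparator."""
    rows = [{"variable": "risk_score",
             "auc": timed_roc(scores, clinical, horizon).auc}]
    codes = encode_clinical_ordinal(clinical)
    for var in codes.columns:
        v = codes[var].dropna()
        if v.nunique() < 2:
            continue
        rows.append({"variable": var,
                     "auc": timed_roc(v, clinical.loc[v.index], horizon).auc})
    return pd.DataFrame(rows)
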