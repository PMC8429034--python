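"""Three-stage signature construction and the risk score.

1. Univariate Cox screen: a one-covariate proportional-hazards fit per
   pair indicator, keeping pairs with Wald p < alpha.
2. L1-penalized (LASSO) Cox over the retained pairs with seeded,
   event-stratified k-fold cross-validation; the penalty minimizing the
   cross-validated partial-likelihood deviance (lambda.min) defines the
   active set.
3. Bidirectional stepwise multivariable Cox over the active set,
   minimizing AIC = 2k - 2 log PL starting from the full model.  AIC, not
   per-term significance, decides retention, so non-significant pairs can
   stay in the final model.

The risk score of a sample is the plain linear predictor
``sum_i value_i * coef_i`` over the N retained pairs — no intercept, no
normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._cox import breslow_loglik, cox1_fit

logger = logging.getLogger("lncpair")


@dataclass
class SignatureModel:
    """Ordered retained pairs with their multivariable Cox coefficients."""

    pairs: list[str]
    coefs: np.ndarray

    def __post_init__(self) -> None:
        self.coefs = np.asarray(self.coefs, dtype=float)
        if len(self.pairs) != len(self.coefs) or len(self.pairs) < 1:
            raise ValueError("pairs and coefs must align and be non-empty")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class RiskProfile:
    """Per-sample risk score, optional risk group, and the cutoff used."""

    scores: pd.Series
    groups: pd.Series | None = None
    cutoff: float | None = None


def _align_survival(sample_ids, clinical: pd.DataFrame):
    miss = [s for s in sample_ids if s not in clinical.index]
    if miss:
        raise ValueError(f"samples missing from clinical table: {miss[:5]}")
    sub = clinical.loc[list(sample_ids)]
    if sub["os_time"].isna().any() or sub["os_event"].isna().any():
        raise ValueError("all samples must carry os_time and os_event")
    return sub["os_time"].to_numpy(float), sub["os_event"].to_numpy(float)


def unicox_screen(pm, clinical: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Univariate Cox per pair; returns the table of pairs with p < alpha.

    Columns: pair_id, coef, hr, hr_low, hr_high, p.  Pairs without
    variation, or with monotone-likelihood (non-convergent) fits, are
    excluded with a warning.
    """
    time, event = _align_survival(pm.sample_ids, clinical)
    rows = []
    for pair_id, x in zip(pm.pair_ids, pm.values.to_numpy()):
        if x.std() == 0:
            logger.warning("pair %s has no variation; skipped", pair_id)
            continue
        fit = cox1_fit(x.astype(float), time, event)
        if not fit.converged:
            logger.warning("pair %s: non-convergent uni-Cox fit; excluded",
                           pair_id)
            continue
        rows.append({"pair_id": pair_id, "coef": fit.coef, "hr": fit.hr,
                     "hr_low": fit.hr_low, "hr_high": fit.hr_high,
                     "p": fit.p})
    table = pd.DataFrame(rows, columns=["pair_id", "coef", "hr", "hr_low",
                                        "hr_high", "p"])
    return table[table["p"] < alpha].reset_index(drop=True)


def _cv_partial_loglik(X, time, event, alphas, n_folds, seed):
    """Verweij & van Houwelingen cross-validated partial log-likelihood.

    cvpl(lambda) = sum_folds [ logPL(all; beta_train) - logPL(train; beta_train) ].
    """
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cvpl = np.zeros(len(alphas))
    y_tpl = Surv.from_arrays(event=event.astype(bool), time=time)
    for train, _test in skf.split(X, event):
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                       fit_baseline_model=False)
        model.fit(X[train], y_tpl[train])
        fitted = {round(a, 12): model.coef_[:, j]
                  for j, a in enumerate(model.alphas_)}
        for j, a in enumerate(alphas):
            beta = fitted.get(round(a, 12))
            if beta is None:
                cvpl[j] = -np.inf
                continue
            full = breslow_loglik(X @ beta, time, event)
            tr = breslow_loglik(X[train] @ beta, time[train], event[train])
            cvpl[j] += full - tr
    return cvpl


def lasso_cox_select(pm, clinical: pd.DataFrame, n_folds: int = 10,
                     seed: int = 0, alphas: np.ndarray | None = None,
                     ) -> list[str]:
    """Pairs with nonzero coefficient at the CV-optimal L1 penalty.

    The penalty path descends geometrically from the smallest penalty
    nulling every coefficient; lambda.min maximizes the cross-validated
    partial log-likelihood (equivalently minimizes the CV deviance) over
    event-stratified folds.
    """
    if len(pm.pair_ids) < 2:
        raise ValueError("need at least 2 candidate pairs for selection")
    time, event = _align_survival(pm.sample_ids, clinical)
    if event.sum() < n_folds:
        raise ValueError("need at least n_folds observed events")
    X = pm.values.to_numpy().T.astype(float)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    if alphas is None:
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=50,
                                      alpha_min_ratio=0.01,
                                      fit_baseline_model=False)
        path.fit(X, y)
        alphas = path.alphas_
    else:
        alphas = np.asarray(alphas, dtype=float)

    cvpl = _cv_partial_loglik(X, time, event, alphas, n_folds, seed)
    best = int(np.argmax(cvpl))
    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                   fit_baseline_model=False)
    final.fit(X, y)
    j = int(np.argmin(np.abs(final.alphas_ - alphas[best])))
    beta = final.coef_[:, j]
    selected = [p for p, b in zip(pm.pair_ids, beta) if b != 0]
    if not selected:
        raise ValueError(
            "no pair has a nonzero coefficient at lambda.min; weaken the "
            "penalty or extend the path")
    return selected


def _fit_multicox(df: pd.DataFrame, covariates: list[str]) -> CoxPHFitter | None:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[covariates + ["os_time", "os_event"]],
                    duration_col="os_time", event_col="os_event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return None
    return cph


def stepwise_multicox(selected: list[str], pm, clinical: pd.DataFrame,
                      ) -> tuple[SignatureModel, pd.DataFrame]:
    """Bidirectional AIC-stepwise multivariable Cox over the selected pairs.

    Starts from the full model; at each step the single add/drop giving
    the largest AIC decrease is applied until none improves.  Exactly
    duplicated pair columns are collapsed beforehand (first id kept).
    Returns the final model and a per-pair table (coef, hr, Wald CI, p).
    """
    if not selected:
        raise ValueError("need at least 1 selected pair")
    time, event = _align_survival(pm.sample_ids, clinical)
    sub = pm.subset(selected)
    X = sub.values.T.astype(float)
    # collapse exact duplicate columns, tie broken by input order
    seen: dict[tuple, str] = {}
    keep = []
    for pid in selected:
        key = tuple(X[pid].to_numpy())
        if key in seen:
            logger.warning("pair %s duplicates %s; dropped", pid, seen[key])
            continue
        seen[key] = pid
        keep.append(pid)
    df = X[keep].copy()
    df["os_time"], df["os_event"] = time, event

    current = list(keep)
    cph = _fit_multicox(df, current)
    while cph is None and len(current) > 1:
        dropped = current.pop()  # drop offending covariate, continue
        logger.warning("full model non-convergent; dropping %s", dropped)
        cph = _fit_multicox(df, current)
    if cph is None:
        raise ValueError("multivariable Cox model could not be fitted")
    best_aic = cph.AIC_partial_

    improved = True
    while improved:
        improved = False
        candidates: list[tuple[float, list[str]]] = []
        for pid in current:
            if len(current) > 1:
                candidates.append((0.0, [p for p in current if p != pid]))
        for pid in keep:
            if pid not in current:
                candidates.append((0.0, current + [pid]))
        best_step = None
        for _, cset in candidates:
            fit = _fit_multicox(df, cset)
            if fit is None:
                continue
            if fit.AIC_partial_ < best_aic - 1e-9:
                if best_step is None or fit.AIC_partial_ < best_step[0]:
                    best_step = (fit.AIC_partial_, cset, fit)
        if best_step is not None:
            best_aic, current, cph = best_step
            improved = True

    summary = cph.summary
    table = pd.DataFrame({
        "pair_id": current,
        "coef": summary.loc[current, "coef"].to_numpy(),
        "hr": summary.loc[current, "exp(coef)"].to_numpy(),
        "hr_low": np.exp(summary.loc[current, "coef lower 95%"].to_numpy()),
        "hr_high": np.exp(summary.loc[current, "coef upper 95%"].to_numpy()),
        "p": summary.loc[current, "p"].to_numpy(),
    })
    model = SignatureModel(pairs=list(current),
                           coefs=summary.loc[current, "coef"].to_numpy())
    return model, table


def compute_risk_scores(model: SignatureModel, pm) -> RiskProfile:
    """riskScore_s = sum_i value_i(s) * coef_i over the signature pairs."""
    missing = [p for p in model.pairs if p not in pm.values.index]
    if missing:
        raise ValueError(f"pair matrix lacks signature pairs: {missing}")
    V = pm.values.loc[model.pairs].to_numpy().astype(float)
    scores = pd.Series(model.coefs @ V, index=pm.sample_ids,
                       name="risk_score")
    return RiskProfile(scores=scores)
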