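"""Clinical, immune, checkpoint and drug-sensitivity associations.

Contingency tests of risk group against clinical categories use the
Pearson chi-square statistic with unknown/not-assessable levels (GX, NX,
MX, Unknown, ...) excluded from the test but reported in the summary.
Risk-score comparisons between two independent clinical subgroups use
the two-sample Wilcoxon rank-sum (Mann-Whitney) test with tie-corrected
normal approximation and no continuity correction; a signed-rank test
would require paired observations, which these comparisons are not.
Immune-infiltration associations are Spearman correlations of each cell
type's fraction with the risk score, screened at raw p < 0.05 by
default (a BH option is available); checkpoint expression and the
IC50-like drug score are compared between risk groups with the same
rank-sum test, reporting the direction as the high-minus-low median
difference.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import km_logrank
from .io import UNKNOWN_LEVELS
from .screening import bh_adjust

logger = logging.getLogger("lncpair")

DEFAULT_CHECKPOINTS = ("PDCD1", "CD247", "CTLA4", "TIGIT", "LAG3")

#: paper-style dichotomizations of the clinical covariates
SUBGROUP_RULES: dict[str, tuple[str, str, object]] = {
    "age": ("age>65", "age<=65", lambda c: c["age"] > 65),
    "gender": ("female", "male", lambda c: c["gender"] == "female"),
    "grade": ("G1-2", "G3-4", lambda c: c["grade"].isin(["G1", "G2"])),
    "stage": ("stage I-II", "stage III-IV",
              lambda c: c["stage"].isin(["I", "II", "Stage I", "Stage II"])),
    "t_stage": ("T1-2", "T3-4",
                lambda c: c["t_stage"].astype(str).str[:2].isin(["T1", "T2"])),
    "n_stage": ("N0", "N1", lambda c: c["n_stage"] == "N0"),
    "m_stage": ("M0", "M1", lambda c: c["m_stage"] == "M0"),
}

#: covariates whose dichotomization admits an unknown level to drop
_SUBGROUP_VALID = {
    "age": lambda c: c["age"].notna(),
    "gender": lambda c: c["gender"].isin(["female", "male"]),
    "grade": lambda c: c["grade"].isin(["G1", "G2", "G3", "G4"]),
    "stage": lambda c: c["stage"].isin(
        ["I", "II", "III", "IV", "Stage I", "Stage II", "Stage III", "Stage IV"]),
    "t_stage": lambda c: c["t_stage"].astype(str).str[:2].isin(
        ["T1", "T2", "T3", "T4"]),
    "n_stage": lambda c: c["n_stage"].isin(["N0", "N1"]),
    "m_stage": lambda c: c["m_stage"].isin(["M0", "M1"]),
}


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U with tie-corrected normal approximation."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def summarize_counts(counts: pd.DataFrame,
                     group_cols: tuple[str, ...] = ("overall_n", "high_n", "low_n"),
                     ) -> pd.DataFrame:
    """Add within-column percentages (one decimal) to a count table.

    Column totals are taken per (column) across all levels of each
    variable block, so pct = round(100 * n / column_total, 1).
    """
    out = counts.copy()
    for col in group_cols:
        # every variable block spans the whole column, so any block's sum
        # is the column total (the group size)
        full = out.groupby("variable")[col].sum().iloc[0]
        out[col.replace("_n", "_pct")] = np.round(100.0 * out[col] / full, 1)
    return out


def chisq_clinical(groups: pd.Series, clinical: pd.DataFrame,
                   variables: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Risk-group x level chi-square per clinical variable, plus summary.

    Unknown/X levels are excluded from the test but included in the
    per-level count summary.  Levels with an all-zero row or column are
    dropped from the test with a warning.
    """
    common = [s for s in groups.index if s in clinical.index]
    g = groups.loc[common]
    cl = clinical.loc[common]
    assoc_rows, summary_rows = [], []
    for var in variables:
        col = cl[var].astype(str).where(cl[var].notna(), "Unknown")
        for level in sorted(col.unique()):
            m = col == level
            summary_rows.append({
                "variable": var, "level": level,
                "overall_n": int(m.sum()),
                "high_n": int((m & (g == "high")).sum()),
                "low_n": int((m & (g == "low")).sum()),
            })
        test_mask = ~col.isin(UNKNOWN_LEVELS) & (col != "nan")
        tab = pd.crosstab(g[test_mask], col[test_mask])
        tab = tab.loc[:, tab.sum(axis=0) > 0]
        tab = tab.loc[tab.sum(axis=1) > 0]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            logger.warning("variable %s: degenerate table, test skipped", var)
            stat, p = np.nan, np.nan
        else:
            stat, p, _, _ = stats.chi2_contingency(tab.to_numpy(),
                                                   correction=False)
        assoc_rows.append({"variable": var, "test": "chisq",
                           "statistic": float(stat), "p": float(p),
                           "effect": np.nan})
    summary = pd.DataFrame(summary_rows)
    totals = {"overall_n": len(g), "high_n": int((g == "high").sum()),
              "low_n": int((g == "low").sum())}
    for col, full in totals.items():
        summary[col.replace("_n", "_pct")] = np.round(
            100.0 * summary[col] / full, 1)
    return pd.DataFrame(assoc_rows), summary


def ranksum_by_subgroup(scores: pd.Series, clinical: pd.DataFrame,
                        variable: str) -> dict:
    """Rank-sum test of the risk score across a dichotomized covariate."""
    if variable not in SUBGROUP_RULES:
        raise ValueError(f"no dichotomization rule for {variable!r}")
    lab_a, lab_b, rule = SUBGROUP_RULES[variable]
    common = [s for s in scores.index if s in clinical.index]
    cl = clinical.loc[common]
    valid = _SUBGROUP_VALID[variable](cl)
    in_a = rule(cl) & valid
    in_b = ~rule(cl) & valid
    xa = scores.loc[common][in_a.to_numpy()].to_numpy()
    xb = scores.loc[common][in_b.to_numpy()].to_numpy()
    if len(xa) == 0 or len(xb) == 0:
        empty = lab_a if len(xa) == 0 else lab_b
        raise ValueError(f"subgroup {empty!r} of {variable!r} is empty")
    stat, p = _ranksum(xa, xb)
    return {"variable": variable, "test": "ranksum", "statistic": stat,
            "p": p, "effect": float(np.median(xa) - np.median(xb)),
            "group_a": lab_a, "group_b": lab_b,
            "n_a": len(xa), "n_b": len(xb)}


def cox_independence(scores: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    """Univariate and multivariable Cox models of score + clinical covariates.

    Age enters as years, gender as female=0/male=1, grade and stage as
    ordinal integers (unknown levels dropped); the risk score is
    continuous.  Exactly collinear covariates are reported with a
    warning and inflated intervals rather than silently dropped.
    """
    from lifelines import CoxPHFitter

    from .evaluation import encode_clinical_ordinal

    common = [s for s in scores.index if s in clinical.index]
    cl = clinical.loc[common]
    X = encode_clinical_ordinal(cl)
    X["risk_score"] = scores.loc[common]
    X["os_time"] = cl["os_time"]
    X["os_event"] = cl["os_event"]
    X = X.dropna()
    covs = [c for c in X.columns if c not in ("os_time", "os_event")]

    rows = []
    for model_type, sets in (("univariate", [[c] for c in covs]),
                             ("multivariate", [covs])):
        for cset in sets:
            corr = X[cset].corr().abs()
            if len(cset) > 1 and (corr.to_numpy()[np.triu_indices(len(cset), 1)]
                                  > 0.999).any():
                logger.warning("collinear covariates in multivariable model")
            import warnings as _w

            from lifelines.exceptions import ConvergenceError

            cph = CoxPHFitter()
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                try:
                    cph.fit(X[cset + ["os_time", "os_event"]],
                            duration_col="os_time", event_col="os_event")
                except ConvergenceError:
                    # singular information matrix (exact collinearity):
                    # refit with a light ridge so intervals stay reportable
                    logger.warning("collinear covariates: refitting with a "
                                   "small ridge penalty")
                    cph = CoxPHFitter(penalizer=0.01)
                    cph.fit(X[cset + ["os_time", "os_event"]],
                            duration_col="os_time", event_col="os_event")
            s = cph.summary
            for var in cset:
                rows.append({
                    "variable": var, "model": model_type,
                    "hr": float(s.loc[var, "exp(coef)"]),
                    "hr_low": float(np.exp(s.loc[var, "coef lower 95%"])),
                    "hr_high": float(np.exp(s.loc[var, "coef upper 95%"])),
                    "p": float(s.loc[var, "p"]),
                })
    return pd.DataFrame(rows)


def subgroup_survival(groups: pd.Series, clinical: pd.DataFrame,
                      variables: list[str] | None = None) -> pd.DataFrame:
    """Risk-group log-rank test inside each clinical subgroup.

    The default subgroups are both sides of each paper-style
    dichotomization (age, gender, stage, grade, T, N, M: 14 subgroups).
    Subgroups empty in either risk group, or with fewer than two events,
    are skipped with a note.
    """
    if variables is None:
        variables = list(SUBGROUP_RULES)
    common = [s for s in groups.index if s in clinical.index]
    g = groups.loc[common]
    cl = clinical.loc[common]
    rows = []
    for var in variables:
        lab_a, lab_b, rule = SUBGROUP_RULES[var]
        valid = _SUBGROUP_VALID[var](cl)
        for lab, mask in ((lab_a, rule(cl) & valid),
                          (lab_b, ~rule(cl) & valid)):
            m = mask.to_numpy()
            sub_g, sub_cl = g[m], cl.loc[m]
            note = ""
            if sub_g.nunique() < 2:
                note = "one risk group empty"
            elif sub_cl["os_event"].sum() < 2:
                note = "fewer than 2 events"
            if note:
                rows.append({"subgroup": lab, "n": int(m.sum()),
                             "statistic": np.nan, "p": np.nan, "note": note})
                continue
            res = km_logrank(sub_g, sub_cl)
            rows.append({"subgroup": lab, "n": int(m.sum()),
                         "statistic": res.statistic, "p": res.p, "note": ""})
    return pd.DataFrame(rows)


def immune_drug_correlations(scores: pd.Series, groups: pd.Series,
                             infiltration: pd.DataFrame | None = None,
                             checkpoint_expr: pd.DataFrame | None = None,
                             drug_scores: pd.Series | None = None,
                             p_max: float = 0.05,
                             bh: bool = False) -> pd.DataFrame:
    """Immune-infiltration, checkpoint and drug associations of the score."""
    rows = []
    high = groups.index[groups == "high"]
    low = groups.index[groups == "low"]

    if infiltration is not None:
        common = [s for s in scores.index if s in infiltration.columns]
        if len(common) < 3:
            raise ValueError("fewer than 3 samples overlap the infiltration table")
        if len(common) < len(scores):
            logger.info("infiltration overlap: %d of %d samples",
                        len(common), len(scores))
        for ct, frac in infiltration[common].iterrows():
            rho, p = stats.spearmanr(scores.loc[common], frac)
            rows.append({"variable": ct, "test": "spearman",
                         "statistic": float(rho), "p": float(p),
                         "effect": float(rho)})
        if bh:
            mask = [r["test"] == "spearman" for r in rows]
            ps = np.array([r["p"] for r in rows])[mask]
            adj = bh_adjust(ps)
            k = 0
            for r in rows:
                if r["test"] == "spearman":
                    r["p_adj"] = float(adj[k])
                    k += 1

    if checkpoint_expr is not None:
        common = [s for s in scores.index if s in checkpoint_expr.columns]
        if len(common) < 3:
            raise ValueError("fewer than 3 samples overlap the checkpoint table")
        hi = [s for s in common if s in set(high)]
        lo = [s for s in common if s in set(low)]
        for gene, expr in checkpoint_expr[common].iterrows():
            stat, p = _ranksum(expr[hi].to_numpy(), expr[lo].to_numpy())
            rows.append({"variable": gene, "test": "ranksum",
                         "statistic": stat, "p": p,
                         "effect": float(np.median(expr[hi]) - np.median(expr[lo]))})

    if drug_scores is not None:
        common = [s for s in scores.index if s in drug_scores.index]
        if len(common) < 3:
            raise ValueError("fewer than 3 samples overlap the drug table")
        hi = [s for s in common if s in set(high)]
        lo = [s for s in common if s in set(low)]
        stat, p = _ranksum(drug_scores[hi].to_numpy(), drug_scores[lo].to_numpy())
        rows.append({"variable": drug_scores.name or "drug_score",
                     "test": "ranksum", "statistic": stat, "p": p,
                     "effect": float(np.median(drug_scores[hi])
                                     - np.median(drug_scores[lo]))})

    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = out["p"] < p_max
    return out
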