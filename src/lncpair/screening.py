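"""Coexpression and differential-expression screens.

Stage one retains immune-related lncRNAs (irlncRNAs): lncRNAs whose
Pearson correlation with at least one immune gene reaches |r| >= 0.8 at
a Benjamini-Hochberg adjusted p < 0.001, the adjustment taken over the
full lncRNA x immune-gene test family.  Stage two flags differentially
expressed irlncRNAs (DEirlncRNAs) between tumor and normal samples:
|log2 fold change| >= 1 (tumor minus normal means on the log2 scale)
and BH FDR < 0.05, with a per-feature Wilcoxon rank-sum test supplying
the p-values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger("lncpair")


def pearson_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlations of two feature x sample matrices."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    an = np.sqrt((az * az).sum(axis=1))
    bn = np.sqrt((bz * bz).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / np.outer(an, bn)
    return r


def pearson_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson r via the exact t-transform (n-2 df)."""
    df = n - 2
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt(df / (1.0 - rr * rr))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(rr), 1.0)] = 0.0
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    ok = np.isfinite(flat)
    out = np.full_like(flat, np.nan)
    out[ok] = stats.false_discovery_control(flat[ok], method="bh")
    return out.reshape(p.shape)


def correlate_immune(lnc_expr: ExpressionMatrix, irgene_expr: ExpressionMatrix,
                     r_min: float = 0.8, p_adj_max: float = 0.001,
                     ) -> tuple[list[str], pd.DataFrame]:
    """Retain lncRNAs strongly coexpressed with at least one immune gene.

    Returns the retained lncRNA ids (input order) and the table of
    correlation hits meeting |r| >= r_min (columns lnc_id, irgene_id, r,
    p, p_adj).  Zero-variance features are excluded from testing with a
    warning.
    """
    if lnc_expr.sample_ids != irgene_expr.sample_ids:
        raise ValueError("lncRNA and immune-gene matrices must share samples")
    n = len(lnc_expr.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation testing")

    lv = lnc_expr.values.to_numpy()
    gv = irgene_expr.values.to_numpy()
    lnc_ok = lv.std(axis=1) > 0
    irg_ok = gv.std(axis=1) > 0
    if not lnc_ok.all() or not irg_ok.all():
        logger.warning(
            "excluding %d lncRNA / %d immune-gene zero-variance features",
            int((~lnc_ok).sum()), int((~irg_ok).sum()))

    r = pearson_matrix(lv[lnc_ok], gv[irg_ok])
    p = pearson_pvalues(r, n)
    p_adj = bh_adjust(p)

    keep = (np.abs(r) >= r_min) & (p_adj < p_adj_max)
    lnc_ids = np.array(lnc_expr.feature_ids)[lnc_ok]
    irg_ids = np.array(irgene_expr.feature_ids)[irg_ok]
    li, gi = np.nonzero(np.abs(r) >= r_min)
    hits = pd.DataFrame({
        "lnc_id": lnc_ids[li],
        "irgene_id": irg_ids[gi],
        "r": r[li, gi],
        "p": p[li, gi],
        "p_adj": p_adj[li, gi],
    })
    retained_mask = keep.any(axis=1)
    retained = [f for f, k in zip(lnc_ids, retained_mask) if k]
    return retained, hits


def differential_expression(expr: ExpressionMatrix,
                            logfc_min: float = 1.0, fdr_max: float = 0.05,
                            two_sided_logfc: bool = True) -> pd.DataFrame:
    """Tumor-vs-normal differential expression per feature.

    log2 fold change is the tumor-minus-normal mean difference of the
    (log2-scale) expression; p-values come from the two-sample Wilcoxon
    rank-sum test with BH adjustment across features.  A feature is
    flagged DE when |logFC| >= logfc_min (or logFC >= logfc_min when
    ``two_sided_logfc=False``) and FDR < fdr_max.
    """
    tum = expr.tumor_samples
    nor = expr.normal_samples
    if len(tum) < 2 or len(nor) < 2:
        raise ValueError("each group needs at least 2 samples")
    tv = expr.values[tum].to_numpy()
    nv = expr.values[nor].to_numpy()
    logfc = tv.mean(axis=1) - nv.mean(axis=1)
    res = stats.mannwhitneyu(tv, nv, axis=1, alternative="two-sided",
                             method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    fdr = bh_adjust(p)
    if two_sided_logfc:
        fc_pass = np.abs(logfc) >= logfc_min
    else:
        fc_pass = logfc >= logfc_min
    out = pd.DataFrame({
        "lnc_id": expr.feature_ids,
        "logFC": logfc,
        "p": p,
        "fdr": fdr,
        "direction": np.where(logfc >= 0, "up", "down"),
        "de": fc_pass & (fdr < fdr_max),
    })
    return out
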