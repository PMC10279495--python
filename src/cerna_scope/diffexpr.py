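"""Differential expression screening by Welch t-test, fold change and BH-FDR.

The test statistic is computed on log(x+1) values while the fold change
(case mean over control mean) is computed on the linear TPM scale.  Genes
and lncRNAs are corrected as separate Benjamini–Hochberg families because
they are screened and reported as separate feature classes.  A feature is
significant when FDR < alpha; an optional fold-change cutoff can be added
on top but is off by default because FDR is the only stated criterion.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cerna_scope.io import FEATURE_KINDS, ExpressionMatrix

logger = logging.getLogger(__name__)


def fold_change(mean_case: float, mean_control: float, pseudocount: float = 0.0) -> float:
    """(mean_case + c) / (mean_control + c) on the linear TPM scale.

    Returns NaN when both terms are zero (undefined ratio); such features
    are never called significant downstream.
    """
    if mean_case < 0 or mean_control < 0:
        raise ValueError("TPM means must be non-negative")
    num = mean_case + pseudocount
    den = mean_control + pseudocount
    if den == 0.0:
        return math.nan if num == 0.0 else math.inf
    return num / den


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch unequal-variance t statistic with two-sided p-value.

    Degenerate inputs follow a fixed convention: zero variance in both
    groups gives p = 1 for equal means and p = 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        logger.debug("zero variance with unequal means; p set to 0 by convention")
        return math.copysign(math.inf, x.mean() - y.mean()), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return fdr


def differential_expression(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    fc_cutoff: float | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Screen every feature for case/control differential expression.

    Returns one row per feature with TPM-scale group means, fold change,
    log2 fold change, Welch t, raw p, BH FDR (adjusted within each feature
    kind) and the significance call.
    """
    matrix.require_group_sizes(2)
    log_mat = matrix.to_log()
    tpm_mat = matrix.to_tpm()
    case = matrix.samples_in("case")
    control = matrix.samples_in("control")

    log_vals = log_mat.values
    tpm_vals = tpm_mat.values
    rows = []
    for fid in matrix.feature_ids:
        x = log_vals.loc[fid, case].to_numpy(dtype=float)
        y = log_vals.loc[fid, control].to_numpy(dtype=float)
        t, p = welch_t(x, y)
        mean_case = float(tpm_vals.loc[fid, case].mean())
        mean_control = float(tpm_vals.loc[fid, control].mean())
        fc = fold_change(mean_case, mean_control, pseudocount)
        log2_fc = math.log2(fc) if fc and math.isfinite(fc) and fc > 0 else math.nan
        rows.append(
            {
                "feature_id": fid,
                "kind": matrix.feature_kind[fid],
                "mean_case": mean_case,
                "mean_control": mean_control,
                "fold_change": fc,
                "log2_fc": log2_fc,
                "t_statistic": t,
                "p_value": p,
            }
        )
    result = pd.DataFrame(rows).set_index("feature_id")

    result["fdr"] = np.nan
    for kind in FEATURE_KINDS:
        mask = result["kind"] == kind
        if mask.any():
            result.loc[mask, "fdr"] = bh_adjust(result.loc[mask, "p_value"])

    sig = result["fdr"] < alpha
    if fc_cutoff is not None:
        if fc_cutoff <= 0:
            raise ValueError("fc_cutoff must be positive")
        sig &= np.abs(result["log2_fc"]) >= abs(math.log2(fc_cutoff))
    sig &= result["fold_change"].notna()  # undefined FC is never significant
    result["is_significant"] = sig

    n_deg = int((sig & (result["kind"] == "gene")).sum())
    n_del = int((sig & (result["kind"] == "lncRNA")).sum())
    logger.info("differential expression: %d DEGs, %d DELs at FDR<%g", n_deg, n_del, alpha)
    return result
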