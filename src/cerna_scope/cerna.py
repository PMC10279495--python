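"""Shared-miRNA ceRNA inference and the differential-coexpression filter.

A lncRNA and an mRNA are candidate ceRNA partners when their miRNA
regulator sets overlap more than chance predicts.  With m miRNAs in the
universe, t of them targeting the mRNA, n targeting the lncRNA and r
shared, the p-value is the upper tail of the hypergeometric distribution:

    P = 1 - sum_{i=0}^{r-1} C(t, i) C(m - t, n - i) / C(m, n)

i.e. the probability of drawing >= r of the mRNA's t regulators when n
regulators are drawn at random from the universe.  Candidates are then
screened for lncRNA-mRNA coexpression (Pearson, computed per group on
log-scale values); a pair is accepted when its shared-miRNA FDR clears
0.05 and the coexpression criterion passes.

Because the source study states the coexpression criterion ambiguously
(per-group thresholds in prose, a case-minus-control difference in its
formula), three explicit modes are provided:

``both_groups``
    cor > 0.5 and p < 0.05 in the case group AND in the control group.
``case_only``
    cor > 0.5 and p < 0.05 in the case group alone — the natural choice
    when coexpression is expected to be gained in disease.
``delta``
    cor_case - cor_control > 0.5 and case p < 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from cerna_scope.diffexpr import bh_adjust
from cerna_scope.io import ExpressionMatrix, InteractionTable

logger = logging.getLogger(__name__)

COEXPRESSION_MODES = ("both_groups", "case_only", "delta")


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class SharedMirnaTest:
    """Hypergeometric shared-miRNA test counts and result for one pair."""

    m: int  # miRNA universe size
    t: int  # miRNAs targeting the mRNA
    n: int  # miRNAs targeting the lncRNA
    r: int  # miRNAs shared
    p_value: float = math.nan
    fdr: float = math.nan


@dataclass
class CoexpressionRecord:
    """Per-group Pearson correlations for one lncRNA-mRNA pair."""

    cor_case: float = math.nan
    cor_control: float = math.nan
    p_case: float = math.nan
    p_control: float = math.nan
    passes: bool = False

    @property
    def delta(self) -> float:
        return self.cor_case - self.cor_control


@dataclass
class CeRNACandidate:
    """One lncRNA-mRNA pair with its test, coexpression and verdict."""

    lncrna_id: str
    mrna_id: str
    shared_mirna_ids: frozenset[str]
    test: SharedMirnaTest
    coexpr: CoexpressionRecord = field(default_factory=CoexpressionRecord)
    accepted: bool = False


# ---------------------------------------------------------------------------
# hypergeometric kernel
# ---------------------------------------------------------------------------

def _log_comb(a: int, b: int) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    N balls, K marked, n drawn without replacement.  Summing the upper
    tail directly (rather than 1 minus the lower tail) keeps small
    p-values accurate.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k <= max(0, n + K - N):
        return 1.0
    log_den = _log_comb(N, n)
    total = 0.0
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        total += math.exp(_log_comb(K, i) + _log_comb(N - K, n - i) - log_den)
    return min(total, 1.0)


def shared_mirna_pvalue(t: int, n: int, r: int, m: int) -> float:
    """Upper-tail probability of >= r shared miRNAs between an mRNA
    (t regulators) and a lncRNA (n regulators) out of m total miRNAs."""
    if t > m or n > m:
        raise ValueError(f"t={t} and n={n} must not exceed universe m={m}")
    if r > min(t, n):
        raise ValueError(f"r={r} exceeds min(t={t}, n={n})")
    if min(t, n, r, m) < 0:
        raise ValueError("counts must be non-negative")
    return hypergeom_upper_tail(r, m, t, n)


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_candidates(
    dels: set[str],
    degs: set[str],
    mirna_mrna: InteractionTable,
    mirna_lncrna: InteractionTable,
    universe_mode: str = "union",
    universe_size: int | None = None,
) -> list[CeRNACandidate]:
    """Test every (DEL, DEG) pair with >= 1 shared miRNA.

    The universe m defaults to the number of distinct miRNAs in the union
    of the two interaction tables (``universe_mode='union'``); pass
    ``universe_mode='fixed'`` with ``universe_size`` to use an external
    constant.  Pairs with no shared miRNA are dropped before testing so
    they do not dilute the BH family; p-values are adjusted jointly over
    all enumerated pairs.
    """
    if universe_mode == "union":
        m = len(mirna_mrna.mirnas | mirna_lncrna.mirnas)
    elif universe_mode == "fixed":
        if not universe_size or universe_size <= 0:
            raise ValueError("universe_mode='fixed' requires a positive universe_size")
        m = int(universe_size)
    else:
        raise ValueError(f"unknown universe_mode {universe_mode!r}")

    if not dels or not degs:
        logger.warning("empty DEL or DEG set; no candidates enumerated")
        return []

    mrna_regs = mirna_mrna.mirnas_by_target()
    lnc_regs = mirna_lncrna.mirnas_by_target()

    candidates: list[CeRNACandidate] = []
    for lnc in sorted(dels):
        lnc_set = lnc_regs.get(lnc)
        if not lnc_set:
            continue
        for gene in sorted(degs):
            gene_set = mrna_regs.get(gene)
            if not gene_set:
                continue
            shared = lnc_set & gene_set
            if not shared:
                continue
            t, n, r = len(gene_set), len(lnc_set), len(shared)
            p = shared_mirna_pvalue(t=t, n=n, r=r, m=m)
            candidates.append(
                CeRNACandidate(
                    lncrna_id=lnc,
                    mrna_id=gene,
                    shared_mirna_ids=frozenset(shared),
                    test=SharedMirnaTest(m=m, t=t, n=n, r=r, p_value=p),
                )
            )
    if candidates:
        fdrs = bh_adjust([c.test.p_value for c in candidates])
        for cand, q in zip(candidates, fdrs):
            cand.test.fdr = float(q)
    logger.info(
        "enumerated %d candidate pairs (universe m=%d) from %d DELs x %d DEGs",
        len(candidates), m, len(dels), len(degs),
    )
    return candidates


# ---------------------------------------------------------------------------
# coexpression
# ---------------------------------------------------------------------------

def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p-value on k-2 df.

    Constant input yields (nan, nan) rather than an exception so a single
    flat feature cannot abort a batch; callers treat NaN as a failed
    filter.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 values")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        logger.debug("constant vector in correlation; returning NaN")
        return math.nan, math.nan
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def coexpression_filter(
    candidates: list[CeRNACandidate],
    expr: ExpressionMatrix,
    mode: str = "both_groups",
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
    alpha: float = 0.05,
) -> list[CeRNACandidate]:
    """Fill per-group correlations and set each candidate's verdict.

    Correlations are computed on log-scale values within the case and the
    control group separately.  ``accepted`` is True when the shared-miRNA
    FDR < alpha and the mode's coexpression criterion passes.  Candidates
    whose features are absent from the matrix are dropped with a warning.
    """
    if mode not in COEXPRESSION_MODES:
        raise ValueError(f"unknown coexpression mode {mode!r}")
    log_vals = expr.to_log().values
    case = expr.samples_in("case")
    control = expr.samples_in("control")
    for grp, ids in (("case", case), ("control", control)):
        if len(ids) < 8:
            logger.warning(
                "%s group has only %d samples; correlation p-values have %d df",
                grp, len(ids), len(ids) - 2,
            )
            break

    kept: list[CeRNACandidate] = []
    for cand in candidates:
        if cand.lncrna_id not in log_vals.index or cand.mrna_id not in log_vals.index:
            logger.warning(
                "dropping pair (%s, %s): feature missing from expression matrix",
                cand.lncrna_id, cand.mrna_id,
            )
            continue
        lx = log_vals.loc[cand.lncrna_id]
        mx = log_vals.loc[cand.mrna_id]
        cc, pc = pearson_with_p(lx[case], mx[case])
        cn, pn = pearson_with_p(lx[control], mx[control])
        rec = CoexpressionRecord(cor_case=cc, cor_control=cn, p_case=pc, p_control=pn)
        case_ok = (cc > r_threshold) and (pc < p_threshold)
        control_ok = (cn > r_threshold) and (pn < p_threshold)
        if mode == "both_groups":
            rec.passes = bool(case_ok and control_ok)
        elif mode == "case_only":
            rec.passes = bool(case_ok)
        else:  # delta
            rec.passes = bool((cc - cn > r_threshold) and (pc < p_threshold))
        # NaN correlations never pass (comparisons above are already False)
        cand.coexpr = rec
        cand.accepted = bool(cand.test.fdr < alpha and rec.passes)
        kept.append(cand)
    n_acc = sum(c.accepted for c in kept)
    logger.info(
        "coexpression filter (%s): %d of %d candidates accepted", mode, n_acc, len(kept)
    )
    return kept


def candidates_to_frame(candidates: list[CeRNACandidate]):
    """Flatten candidates into a DataFrame (one row per pair)."""
    import pandas as pd

    rows = []
    for c in candidates:
        rows.append(
            {
                "lncrna_id": c.lncrna_id,
                "mrna_id": c.mrna_id,
                "shared_mirnas": ",".join(sorted(c.shared_mirna_ids)),
                "m": c.test.m,
                "t": c.test.t,
                "n": c.test.n,
                "r": c.test.r,
                "p_value": c.test.p_value,
                "fdr": c.test.fdr,
                "cor_case": c.coexpr.cor_case,
                "cor_control": c.coexpr.cor_control,
                "p_case": c.coexpr.p_case,
                "p_control": c.coexpr.p_control,
                "delta_cor": c.coexpr.delta,
                "coexpr_passes": c.coexpr.passes,
                "accepted": c.accepted,
            }
        )
    cols = [
        "lncrna_id", "mrna_id", "shared_mirnas", "m", "t", "n", "r",
        "p_value", "fdr", "cor_case", "cor_control", "p_case", "p_control",
        "delta_cor", "coexpr_passes", "accepted",
    ]
    return pd.DataFrame(rows, columns=cols)
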