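"""Genetic-interaction scoring against a multiplicative independence model.

In a fitness plot (control-background fitness x vs query-background fitness
y, one point per gene deletion), genetic independence predicts a line
through the origin, y = m x: the query mutation multiplies every strain's
fitness by a common factor m.  Genes whose query fitness lies significantly
above the line suppress the query defect; genes below it enhance.  The
genetic interaction strength (GIS) of a gene is the deviation
F_query − m · F_control, in doublings²/day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateScreenError,
    InsufficientOverlapError,
    InvalidInputError,
    InvalidParameterError,
)
from .growth import ScreenFitnessTable

MIN_SHARED_ORFS = 10
TUKEY_C = 4.685  # bisquare tuning constant (95 % Gaussian efficiency)


def _shared_means(control: ScreenFitnessTable, query: ScreenFitnessTable):
    x = control.mean_by_orf
    y = query.mean_by_orf
    shared = x.index.intersection(y.index)
    if len(shared) < MIN_SHARED_ORFS:
        raise InsufficientOverlapError(
            f"only {len(shared)} ORFs shared between screens; "
            f"at least {MIN_SHARED_ORFS} required")
    return shared, x.loc[shared].to_numpy(float), y.loc[shared].to_numpy(float)


def estimate_independence_slope(control: ScreenFitnessTable,
                                query: ScreenFitnessTable,
                                method: str = "robust") -> float:
    """Slope m of the genetic-independence line through the origin.

    ``lsq_origin`` is the through-origin least-squares slope Σxy/Σx² over
    per-gene mean fitnesses.  ``robust`` (default) iteratively reweights with
    Tukey's bisquare so that interacting genes — outliers from the line —
    do not bias m; most genes are assumed non-interacting.
    """
    _, x, y = _shared_means(control, query)
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise DegenerateScreenError("all control mean fitnesses are zero")
    m = float(np.dot(x, y) / sxx)
    if method == "lsq_origin":
        return m
    if method != "robust":
        raise InvalidParameterError(f"unknown slope method {method!r}")

    for _ in range(20):
        resid = y - m * x
        s = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
        if s <= 0:
            break
        u = resid / (TUKEY_C * s)
        w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        denom = float(np.sum(w * x * x))
        if denom == 0.0:
            break
        m_new = float(np.sum(w * x * y) / denom)
        if abs(m_new - m) <= 1e-8:
            m = m_new
            break
        m = m_new
    return m


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, order-preserving.

    NaN entries are passed through as NaN and excluded from the adjustment.
    """
    p = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch p-value; 1.0 when both samples are constant and equal."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def compute_interactions(control: ScreenFitnessTable,
                         query: ScreenFitnessTable,
                         m: float | None = None,
                         q_threshold: float = 0.05,
                         method: str = "robust") -> pd.DataFrame:
    """Score every shared ORF for genetic interaction with the query mutation.

    Returns one row per shared ORF with columns ``orf, gene, F_control,
    F_query, m, F_pred, gis, p, q, call, n_control, n_query, flagged``.
    The p-value is a two-sided Welch test of the query replicate fitnesses
    against the m-scaled control replicates, so the null is centred on the
    independence prediction; q is Benjamini–Hochberg over all shared ORFs.
    Genes with fewer than 2 replicates on either side get missing p and q,
    call ``none`` and ``flagged=True``.  Calls: q ≤ q_threshold and gis > 0 →
    suppressor; q ≤ q_threshold and gis < 0 → enhancer; otherwise none.
    """
    if not (0 < q_threshold < 1):
        raise InvalidParameterError(f"q_threshold must be in (0, 1), got {q_threshold}")
    shared, xmeans, ymeans = _shared_means(control, query)
    if m is None:
        m = estimate_independence_slope(control, query, method=method)

    creps = control.replicates_by_orf
    qreps = query.replicates_by_orf
    gene_names = control.data.set_index("orf")["gene"]

    rows = []
    pvals = []
    for orf, xm, ym in zip(shared, xmeans, ymeans):
        a = np.asarray(qreps.loc[orf], dtype=float)
        b = m * np.asarray(creps.loc[orf], dtype=float)
        flagged = len(a) < 2 or len(b) < 2
        p = np.nan if flagged else _welch_p(a, b)
        pvals.append(p)
        rows.append({
            "orf": orf, "gene": gene_names.loc[orf],
            "F_control": xm, "F_query": ym,
            "m": m, "F_pred": m * xm, "gis": ym - m * xm,
            "n_control": len(b), "n_query": len(a), "flagged": flagged,
        })

    q = bh_fdr(pvals)
    out = pd.DataFrame(rows)
    out["p"] = pvals
    out["q"] = q
    significant = pd.Series(q <= q_threshold).fillna(False).to_numpy()
    call = np.where(significant & (out["gis"] > 0), "suppressor",
                    np.where(significant & (out["gis"] < 0), "enhancer", "none"))
    out["call"] = call
    out = out[["orf", "gene", "F_control", "F_query", "m", "F_pred", "gis",
               "p", "q", "call", "n_control", "n_query", "flagged"]]
    out = out.sort_values("orf", ignore_index=True)
    out.attrs["m"] = m
    out.attrs["q_threshold"] = q_threshold
    out.attrs["screen_id"] = query.screen_id
    out.attrs["treatment"] = query.treatment
    return out


def coverage_report(control: ScreenFitnessTable,
                    query: ScreenFitnessTable) -> dict:
    """ORFs present in only one screen; these are dropped from slope and GIS."""
    cset = set(control.data["orf"])
    qset = set(query.data["orf"])
    return {
        "n_shared": len(cset & qset),
        "control_only": sorted(cset - qset),
        "query_only": sorted(qset - cset),
    }
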