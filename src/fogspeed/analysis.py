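"""Group-level analysis: the perceived-speed statistic, aggregation,
repeated-measures ANOVA with Huynh-Feldt correction and generalized eta
squared, and Holm-adjusted pairwise post hocs.

PSEs from the 2IFC task are converted to a perceived speed via

    speed_perceived = PSE_clear + PSE_clear * ln(PSE_clear / PSE_reduced),

a first-order (log-linearised) reading of the bias: a condition matched
at a PSE below the clear one (motion looks faster) maps to a perceived
speed above the clear PSE and vice versa, with the clear condition as a
fixed point.  The transform is applied per subject *before* group
averaging — the two orders differ (Jensen's inequality), and the
per-subject-first path is the one used throughout.

The within-subject ANOVA is the classical one-way decomposition
(condition, subject, residual sums of squares), with the sphericity
violation handled by Huynh-Feldt-corrected degrees of freedom and effect
size reported as generalized eta squared
``SS_cond / (SS_cond + SS_subject + SS_error)`` (the Olejnik-Algina form
for a fully within design with no measured between factor).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "perceived_speed_from_pse",
    "aggregate_subject_means",
    "perceived_speed_table",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "holm_adjust",
    "pairwise_posthoc",
]


@dataclass(frozen=True)
class AnovaResult:
    """One within-subject ANOVA effect, Huynh-Feldt corrected."""

    F: float
    df_num: float
    df_den: float
    p: float
    eta_g_squared: float
    hf_epsilon: float

    @property
    def df_num_corrected(self) -> float:
        return self.df_num * self.hf_epsilon

    @property
    def df_den_corrected(self) -> float:
        return self.df_den * self.hf_epsilon


def perceived_speed_from_pse(pse_clear: float, pse_reduced: float) -> float:
    """PSE pair -> perceived speed under the reduced-visibility condition.

    ``PSE_clear * (1 + ln(PSE_clear / PSE_reduced))``: equal PSEs give the
    clear PSE back; lower reduced-visibility PSEs (overestimation) give
    higher perceived speeds.
    """
    if pse_clear <= 0 or pse_reduced <= 0:
        raise ValueError("PSEs must be positive")
    return pse_clear + pse_clear * math.log(pse_clear / pse_reduced)


def aggregate_subject_means(
    results: pd.DataFrame,
    value_col: str,
    subject_col: str = "subject",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Average per-staircase estimates to a subject x condition table.

    Collapses across any further columns (e.g. target speed) by the
    arithmetic mean.  Incomplete crossings are rejected because the
    repeated-measures ANOVA requires a complete table.
    """
    table = results.pivot_table(
        index=subject_col, columns=condition_col, values=value_col, aggfunc="mean"
    )
    if table.isna().any().any():
        missing = [
            (subj, cond)
            for subj in table.index
            for cond in table.columns
            if pd.isna(table.at[subj, cond])
        ]
        raise ValueError(f"incomplete subject x condition crossing: {missing}")
    return table


def perceived_speed_table(
    pse_table: pd.DataFrame, clear_label: str = "clear"
) -> pd.DataFrame:
    """Apply the perceived-speed transform per subject (row-wise).

    Each subject's clear-condition PSE anchors their own transform; the
    clear column maps to itself (fixed point).  Group means of the result
    are therefore means of per-subject transforms, not transforms of
    means.
    """
    if clear_label not in pse_table.columns:
        raise ValueError(f"table lacks the {clear_label!r} column")
    out = pse_table.copy().astype(float)
    for cond in pse_table.columns:
        out[cond] = [
            perceived_speed_from_pse(row[clear_label], row[cond])
            for _, row in pse_table.iterrows()
        ]
    return out


def _hf_epsilon(table: np.ndarray) -> float:
    """Huynh-Feldt epsilon from the condition covariance matrix, capped at 1."""
    n, k = table.shape
    s = np.cov(table, rowvar=False, ddof=1)
    # Greenhouse-Geisser epsilon from the double-centered covariance
    sc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    denom = (k - 1) * float(np.sum(sc * sc))
    if denom <= 0:
        return 1.0
    gg = float(np.trace(sc)) ** 2 / denom
    hf_denom = (k - 1) * (n - 1 - (k - 1) * gg)
    if hf_denom <= 0:
        return 1.0
    hf = (n * (k - 1) * gg - 2.0) / hf_denom
    return float(min(1.0, max(hf, 1.0 / (k - 1))))


def rm_anova_oneway(table: pd.DataFrame) -> AnovaResult:
    """One-way within-subject ANOVA on a complete subject x condition table.

    Classical decomposition: ``SS_total = SS_cond + SS_subject + SS_error``
    with ``F = MS_cond / MS_error`` on (k-1, (k-1)(n-1)) degrees of
    freedom; the reported p uses Huynh-Feldt-corrected dfs.  All cells
    equal yields F = 0 by convention.
    """
    x = np.asarray(table, dtype=float)
    if np.isnan(x).any():
        raise ValueError("incomplete table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = x.mean()
    ss_cond = n * float(np.sum((x.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((x.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df_num = k - 1
    df_den = (k - 1) * (n - 1)
    ms_err = ss_err / df_den
    if ms_err <= 0:
        f_val = 0.0 if ss_cond <= 1e-300 else math.inf
    else:
        f_val = (ss_cond / df_num) / ms_err
    denom_eta = ss_cond + ss_subj + ss_err
    eta_g = ss_cond / denom_eta if denom_eta > 0 else 0.0
    eps = _hf_epsilon(x)
    if math.isinf(f_val):
        p = 0.0
    else:
        p = float(stats.f.sf(f_val, df_num * eps, df_den * eps))
    return AnovaResult(
        F=float(f_val),
        df_num=float(df_num),
        df_den=float(df_den),
        p=p,
        eta_g_squared=float(eta_g),
        hf_epsilon=eps,
    )


def rm_anova_twoway(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject",
) -> pd.DataFrame:
    """Two-factor within-subject ANOVA (uncorrected), via statsmodels AnovaRM.

    Convenience extension for condition x target-speed designs; the
    headline one-factor path (after averaging across speeds) is
    :func:`rm_anova_oneway`.
    """
    from statsmodels.stats.anova import AnovaRM

    res = AnovaRM(data=data, depvar=dv, subject=subject, within=within).fit()
    return res.anova_table


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm step-down adjusted p-values, order-preserving on input indices."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="holm")
    return [float(v) for v in adjusted]


def pairwise_posthoc(table: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests between all condition pairs with Holm-adjusted p."""
    conds = list(table.columns)
    rows = []
    for a, b in itertools.combinations(conds, 2):
        t, p = stats.ttest_rel(table[a], table[b])
        rows.append({"a": a, "b": b, "t": float(t), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(list(out["p_raw"])) if len(out) else []
    return out
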