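"""Group statistics for labelling metrics.

The comparison toolkit used throughout: 1.5*IQR outlier flagging
(type-7 linear-interpolation quartiles), one-way ANOVA with Tukey's HSD
for multi-group designs, pooled-variance Student's t (two- or one-sided)
for two-group designs, and Benjamini-Hochberg FDR adjustment across
metabolite panels.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

METHODS = ("anova_tukey", "t_two_sided", "t_one_sided")


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    method: str
    adjusted_p: float | None = None


def flag_outliers_iqr(values: Sequence[float]) -> np.ndarray:
    """Flag values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR].

    Quartiles use linear interpolation (numpy's default, the type-7
    convention).  Fewer than 4 values cannot support quartiles; nothing
    is flagged and a warning is issued.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        _warnings.warn(
            f"only {values.size} values; IQR outlier flagging skipped", stacklevel=2
        )
        return np.zeros(values.size, dtype=bool)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    method: str,
    metric: str = "",
    alternative: str = "two-sided",
) -> list[GroupComparison]:
    """Compare group means with the requested test.

    ``anova_tukey`` (>= 2 groups) returns every pairwise comparison with
    Tukey-HSD-adjusted p-values (the pair's mean difference as the
    statistic).  The t methods require exactly two groups and use pooled
    variance; for ``t_one_sided`` pass ``alternative`` as ``"less"`` or
    ``"greater"`` for the first group relative to the second.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    labels = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in labels]
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")

    if method == "anova_tukey":
        endog = np.concatenate(arrays)
        groups = np.concatenate([[g] * a.size for g, a in zip(labels, arrays)])
        tukey = pairwise_tukeyhsd(endog, groups)
        i_idx, j_idx = tukey._multicomp.pairindices
        by_label = {str(g): a for g, a in zip(labels, arrays)}
        # pooled-MSE across all groups, so the unadjusted pairwise p uses the
        # same error df as the Tukey adjustment (guaranteeing adjusted >= raw)
        df_err = endog.size - len(labels)
        mse = sum(a.size * a.var(ddof=0) for a in arrays) / df_err
        out = []
        for i, j, diff, p_adj in zip(i_idx, j_idx, tukey.meandiffs, tukey.pvalues):
            g1, g2 = str(tukey.groupsunique[i]), str(tukey.groupsunique[j])
            se = np.sqrt(mse * (1 / by_label[g1].size + 1 / by_label[g2].size))
            t_stat = diff / se
            pair_p = float(2 * stats.t.sf(abs(t_stat), df_err))
            out.append(
                GroupComparison(
                    metric=metric,
                    groups=(g1, g2),
                    statistic=float(diff),
                    p_value=pair_p,
                    adjusted_p=float(max(p_adj, pair_p)),
                    method=method,
                )
            )
        return out

    if len(labels) != 2:
        raise ValueError(f"{method} requires exactly 2 groups, got {len(labels)}")
    if method == "t_two_sided":
        alternative = "two-sided"
    elif alternative not in ("less", "greater"):
        raise ValueError("t_one_sided needs alternative='less' or 'greater'")
    res = stats.ttest_ind(arrays[0], arrays[1], equal_var=True, alternative=alternative)
    return [
        GroupComparison(
            metric=metric,
            groups=(labels[0], labels[1]),
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            method=method,
        )
    ]


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
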