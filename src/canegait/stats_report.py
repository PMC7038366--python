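"""Condition statistics: one-way repeated-measures ANOVA, Bonferroni
pairwise contrasts, and normalized-to-control summaries.

The experimental unit is the participant; each cell of the analysis matrix
is one participant's mean feature value over the valid strides of one
condition.  The ANOVA removes the participant effect
(``SS_total = SS_condition + SS_subject + SS_error``) and tests the
condition effect with ``F = MS_condition / MS_error`` on
``(k - 1, (k - 1)(n - 1))`` degrees of freedom.  Pairwise contrasts are
two-sided paired t tests with Bonferroni-adjusted p values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, ParameterError

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "rm_anova_oneway",
    "bonferroni_pairwise",
    "normalize_to_control",
    "make_report",
]


@dataclass
class AnovaResult:
    feature: str
    F: float
    p: float
    df_condition: int
    df_error: int
    ss_condition: float
    ss_subject: float
    ss_error: float


@dataclass
class PairwiseComparison:
    feature: str
    condition_a: str
    condition_b: str
    mean_difference: float
    p_raw: float
    p_adjusted: float
    significant: bool
    degenerate: bool = False


def _as_matrix(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise DataError("expected a subjects x conditions matrix")
    if np.isnan(m).any():
        raise DataError("missing cells in the subject x condition matrix "
                        "(no imputation is performed)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise DataError("need at least 2 subjects and 2 conditions")
    return m


def rm_anova_oneway(matrix, feature: str = "") -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix."""
    m = _as_matrix(matrix)
    n, k = m.shape
    grand = m.mean()
    cond_means = m.mean(axis=0)
    subj_means = m.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    ss_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_total = float(np.sum((m - grand) ** 2))
    ss_err = max(ss_total - ss_cond - ss_subj, 0.0)
    df_c = k - 1
    df_e = (k - 1) * (n - 1)
    ms_e = ss_err / df_e
    if ms_e <= 0:
        f_val = 0.0 if ss_cond == 0 else float("inf")
    else:
        f_val = (ss_cond / df_c) / ms_e
    p = float(stats.f.sf(f_val, df_c, df_e)) if np.isfinite(f_val) else 0.0
    return AnovaResult(feature, f_val, p, df_c, df_e, ss_cond, ss_subj, ss_err)


def bonferroni_pairwise(matrix, alpha: float = 0.05,
                        conditions: Optional[Sequence[str]] = None,
                        feature: str = "") -> List[PairwiseComparison]:
    """Paired t tests for every condition pair, Bonferroni-adjusted.

    A zero-variance difference vector is flagged degenerate and reported
    not significant rather than producing an infinite t statistic.
    """
    m = _as_matrix(matrix)
    n, k = m.shape
    if conditions is None:
        conditions = [f"c{i}" for i in range(k)]
    if len(conditions) != k:
        raise ParameterError("conditions must name every column")
    n_pairs = k * (k - 1) // 2
    out = []
    for i, j in itertools.combinations(range(k), 2):
        d = m[:, i] - m[:, j]
        if np.allclose(d.std(ddof=1), 0.0):
            out.append(PairwiseComparison(feature, conditions[i], conditions[j],
                                          float(d.mean()), float("nan"),
                                          float("nan"), False, degenerate=True))
            continue
        t_res = stats.ttest_rel(m[:, i], m[:, j])
        p_adj = min(1.0, float(t_res.pvalue) * n_pairs)
        out.append(PairwiseComparison(feature, conditions[i], conditions[j],
                                      float(d.mean()), float(t_res.pvalue),
                                      p_adj, p_adj < alpha))
    return out


def subject_matrix(subject_means: pd.DataFrame, feature: str,
                   conditions: Sequence[str], source: str = "MSMF"):
    """Pivot the tidy subject-mean table into a subjects x conditions matrix."""
    sub = subject_means[(subject_means.feature == feature)
                        & (subject_means.source == source)]
    pivot = sub.pivot(index="participant", columns="condition", values="value")
    missing = [c for c in conditions if c not in pivot.columns]
    if missing:
        raise DataError(f"conditions missing from the table: {missing}")
    return pivot[list(conditions)].to_numpy()


def normalize_to_control(summary: pd.DataFrame,
                         control: str = "control") -> pd.DataFrame:
    """Condition/control ratio of feature means, per source stream."""
    if control not in set(summary.condition):
        raise DataError(f"summary lacks the {control!r} condition")
    ctrl = (summary[summary.condition == control]
            .set_index(["feature", "source"])["mean"])
    out = summary.copy()
    denom = out.set_index(["feature", "source"]).index.map(ctrl)
    denom = np.asarray(denom, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom != 0.0, out["mean"].to_numpy() / denom, np.nan)
    out["ratio_to_control"] = ratio
    out["undefined_ratio"] = denom == 0.0
    return out


def _fmt(mean: float, sd: float) -> str:
    return f"({mean:.1f} ± {sd:.1f})"


def make_report(summary: pd.DataFrame,
                anova_results: Dict[str, AnovaResult],
                pairwise_results: Dict[str, List[PairwiseComparison]],
                control: str = "control",
                source: str = "MSMF") -> pd.DataFrame:
    """Per-feature report table in the published layout.

    One row per feature: the (F, p) pair and a "(mean +- sd)" cell per
    condition; a significant contrast against the control adds ``*`` and a
    significant contrast between the two non-control conditions adds ``**``.
    """
    sub = summary[summary.source == source]
    conditions = list(dict.fromkeys(sub.condition))
    rows = []
    for feature in dict.fromkeys(sub.feature):
        row = {"feature": feature}
        res = anova_results.get(feature)
        if res is not None:
            p_txt = "<0.001" if res.p < 0.001 else f"{res.p:.3f}"
            row["anova"] = f"({res.F:.1f}, {p_txt})"
        stars = {c: set() for c in conditions}
        for cmp_ in pairwise_results.get(feature, []):
            if not cmp_.significant:
                continue
            pair = {cmp_.condition_a, cmp_.condition_b}
            if control in pair:
                other = (pair - {control}).pop()
                if other in stars:
                    stars[other].add("*")
            else:
                for c in pair:
                    if c in stars:
                        stars[c].add("**")
        for cond in conditions:
            cell = sub[(sub.feature == feature) & (sub.condition == cond)]
            if len(cell):
                txt = _fmt(float(cell["mean"].iloc[0]), float(cell["sd"].iloc[0]))
                if cond != control and stars[cond]:
                    txt += " " + ", ".join(sorted(stars[cond]))
                row[cond] = txt
        rows.append(row)
    return pd.DataFrame(rows)
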