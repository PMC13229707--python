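"""Group-level inference on fractal-dimension values.

Two designs are supported, matching the emulated studies:

* acute: every subject measured under all conditions (drug-free,
  induced parkinsonian, rescued) -> one-way repeated-measures ANOVA
  with error df ``(c-1)(n-1)``;
* chronic: a between factor (lesioned vs sham group) crossed with a
  within factor (baseline vs stimulation) -> two-way mixed ANOVA with
  the conventional error terms (subjects-within-group for the between
  effect, subject x treatment residual for the within effects).

Post-hoc pairwise comparisons use Fisher's LSD: a plain t test on the
ANOVA's error mean square, with no multiplicity adjustment -- that is
the definition of the procedure and is intentional.  Normality and
homogeneity of variance are screened with Shapiro-Wilk and Levene
tests; failures warn rather than abort, mirroring their use as an
acceptance check before choosing the parametric analysis.

No sphericity correction is applied: the chronic within factor has two
levels (sphericity holds trivially) and none is applied for the acute
three-level design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSignalError, ParameterError

__all__ = [
    "AnovaResult",
    "LSDResult",
    "AssumptionReport",
    "rm_anova_oneway",
    "mixed_anova_twoway",
    "fisher_lsd",
    "assumption_checks",
]

ALPHA = 0.05  # significance convention throughout


@dataclass
class AnovaResult:
    effect_name: str
    F: float
    df_num: int
    df_den: int
    p: float
    ms_error: float  # error mean square of this effect's test (for LSD)
    #: number of observations per cell mean entering pairwise SEs
    n_per_level: dict[str, int] = field(default_factory=dict)


@dataclass
class LSDResult:
    pair: tuple[str, str]
    mean_diff: float
    se: float
    t: float
    df: int
    p: float


@dataclass
class AssumptionReport:
    shapiro_p: dict[str, float]  # per-cell normality p-values
    shapiro_residuals_p: float
    levene_p: float
    warnings: list[str]

    @property
    def all_met(self) -> bool:
        return not self.warnings


def _pivot(table: pd.DataFrame, subject: str, condition: str, value: str) -> pd.DataFrame:
    for col in (subject, condition, value):
        if col not in table.columns:
            raise ParameterError(f"table lacks required column {col!r}")
    dup = table.duplicated([subject, condition])
    if dup.any():
        raise ParameterError("duplicate (subject, condition) rows in table")
    wide = table.pivot(index=subject, columns=condition, values=value)
    if wide.isna().any().any():
        missing = [
            (s, c) for (s, c) in zip(*np.nonzero(wide.isna().to_numpy()))
        ]
        raise ParameterError(
            f"incomplete design: {len(missing)} missing (subject, condition) "
            "cells; no imputation is performed"
        )
    return wide


def rm_anova_oneway(
    table: pd.DataFrame,
    subject: str = "subject",
    condition: str = "condition",
    value: str = "value",
) -> AnovaResult:
    """One-way repeated-measures ANOVA on a tidy (subject, condition,
    value) table.  Requires a complete balanced design."""
    wide = _pivot(table, subject, condition, value)
    y = wide.to_numpy(dtype=float)
    n, c = y.shape
    if n < 2 or c < 2:
        raise ParameterError("need >= 2 subjects and >= 2 conditions")
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_cond = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = c * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_num = c - 1
    df_den = (c - 1) * (n - 1)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    if ms_err <= 0:
        if ms_cond == 0:
            return AnovaResult(
                "condition", 0.0, df_num, df_den, 1.0, 0.0,
                {str(l): n for l in wide.columns},
            )
        raise DegenerateSignalError("zero error variance; F undefined")
    F = ms_cond / ms_err
    p = float(stats.f.sf(F, df_num, df_den))
    return AnovaResult(
        "condition", float(F), df_num, df_den, p, float(ms_err),
        {str(l): n for l in wide.columns},
    )


def mixed_anova_twoway(
    table: pd.DataFrame,
    subject: str = "subject",
    group: str = "group",
    condition: str = "condition",
    value: str = "value",
) -> list[AnovaResult]:
    """Two-way mixed ANOVA: between factor ``group``, within factor
    ``condition``.  Returns [group, treatment, interaction] results.

    For g groups totalling n subjects measured under t within levels,
    the between effect is tested against subjects-within-groups
    (df ``n - g``) and the within effects against the subject x
    treatment residual (df ``(n - g)(t - 1)``).
    """
    for col in (subject, group, condition, value):
        if col not in table.columns:
            raise ParameterError(f"table lacks required column {col!r}")
    gmap = table.drop_duplicates(subject).set_index(subject)[group]
    if table.groupby(subject)[group].nunique().max() > 1:
        raise ParameterError("each subject must belong to exactly one group")
    wide = _pivot(table, subject, condition, value)
    y = wide.to_numpy(dtype=float)
    subj_groups = gmap.loc[wide.index].to_numpy()
    groups = pd.unique(subj_groups)
    g, t = len(groups), y.shape[1]
    n = y.shape[0]
    if g < 2 or t < 2:
        raise ParameterError("need >= 2 groups and >= 2 within levels")
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()

    subj_means = y.mean(axis=1)
    group_means = {gr: subj_means[subj_groups == gr].mean() for gr in groups}
    counts = {str(gr): int((subj_groups == gr).sum()) for gr in groups}
    ss_group = t * sum(
        (subj_groups == gr).sum() * (group_means[gr] - grand) ** 2 for gr in groups
    )
    ss_subj_within = t * sum(
        ((subj_means[subj_groups == gr] - group_means[gr]) ** 2).sum()
        for gr in groups
    )
    cond_means = y.mean(axis=0)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    # cell means: group x condition
    ss_cells = 0.0
    for gr in groups:
        sel = subj_groups == gr
        cell = y[sel].mean(axis=0)
        ss_cells += sel.sum() * ((cell - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_cond
    ss_err_within = ss_total - ss_group - ss_subj_within - ss_cond - ss_inter

    df_group, df_between_err = g - 1, n - g
    df_cond = t - 1
    df_inter = (g - 1) * (t - 1)
    df_within_err = (n - g) * (t - 1)
    ms_between_err = ss_subj_within / df_between_err
    ms_within_err = ss_err_within / df_within_err
    if ms_between_err <= 0 or ms_within_err <= 0:
        raise DegenerateSignalError("zero error variance; mixed ANOVA undefined")

    def res(name, ss, dfn, ms_err, dfd):
        F = (ss / dfn) / ms_err
        return AnovaResult(
            name, float(F), dfn, dfd, float(stats.f.sf(F, dfn, dfd)),
            float(ms_err), counts,
        )

    return [
        res("group", ss_group, df_group, ms_between_err, df_between_err),
        res("treatment", ss_cond, df_cond, ms_within_err, df_within_err),
        res("interaction", ss_inter, df_inter, ms_within_err, df_within_err),
    ]


def fisher_lsd(
    table: pd.DataFrame,
    anova: AnovaResult,
    pair: tuple[str, str],
    subject: str = "subject",
    group: str = "group",
    condition: str = "condition",
    value: str = "value",
    within_group: str | None = None,
) -> LSDResult:
    """Fisher's LSD comparison of two levels, using the ANOVA error MS.

    * ``anova.effect_name == 'condition'`` (one-way RM): ``pair`` names
      two within levels; SE = sqrt(2 MSe / n).
    * ``'group'`` (mixed): ``pair`` names two groups; subject means over
      the t within levels are compared against subjects-within-groups.
    * ``'treatment'``/``'interaction'`` (mixed): ``pair`` names two
      within levels, optionally restricted to one group via
      ``within_group`` (simple effect with the pooled within error).

    No multiplicity correction is applied (that is what distinguishes
    LSD from Bonferroni-style procedures).
    """
    a, b = pair
    if anova.effect_name == "group":
        sub = table.drop_duplicates([subject, condition])
        t_levels = sub[condition].nunique()
        means = table.groupby(group)[value].mean()
        for lvl in pair:
            if lvl not in means.index:
                raise ParameterError(f"group level {lvl!r} not present")
        n1 = anova.n_per_level.get(str(a))
        n2 = anova.n_per_level.get(str(b))
        if not n1 or not n2:
            raise ParameterError("anova result lacks per-group counts")
        diff = float(means[a] - means[b])
        se = float(np.sqrt(anova.ms_error / t_levels * (1.0 / n1 + 1.0 / n2)))
    else:
        data = table
        if within_group is not None:
            if group not in table.columns:
                raise ParameterError("within_group given but no group column")
            data = table[table[group] == within_group]
            if data.empty:
                raise ParameterError(f"group {within_group!r} not present")
        means = data.groupby(condition)[value].mean()
        ns = data.groupby(condition)[value].count()
        for lvl in pair:
            if lvl not in means.index:
                raise ParameterError(f"condition level {lvl!r} not present")
        if ns[a] != ns[b]:
            raise ParameterError("unbalanced pair; LSD assumes equal cell sizes")
        diff = float(means[a] - means[b])
        se = float(np.sqrt(2.0 * anova.ms_error / ns[a]))
    if se == 0:
        raise DegenerateSignalError("zero standard error in LSD comparison")
    tstat = diff / se
    p = float(2.0 * stats.t.sf(abs(tstat), anova.df_den))
    return LSDResult(
        pair=(str(a), str(b)), mean_diff=diff, se=se, t=float(tstat),
        df=anova.df_den, p=p,
    )


def assumption_checks(
    table: pd.DataFrame,
    condition: str = "condition",
    value: str = "value",
    group: str | None = None,
    alpha: float = ALPHA,
) -> AssumptionReport:
    """Shapiro-Wilk normality (per cell and on residuals) and Levene
    homogeneity screening.  p <= alpha produces warnings, not errors."""
    if condition not in table.columns or value not in table.columns:
        raise ParameterError("table lacks condition/value columns")
    keys = [group, condition] if group and group in table.columns else [condition]
    cells = {
        " / ".join(map(str, k if isinstance(k, tuple) else (k,))): v[value].to_numpy()
        for k, v in table.groupby(keys)
    }
    warnings: list[str] = []
    shapiro_p: dict[str, float] = {}
    residuals = []
    for name, obs in cells.items():
        if obs.size < 3:
            raise ParameterError(f"cell {name!r} has fewer than 3 observations")
        if np.ptp(obs) == 0:
            raise DegenerateSignalError(f"cell {name!r} is constant")
        p = float(stats.shapiro(obs).pvalue)
        shapiro_p[name] = p
        if p <= alpha:
            warnings.append(f"normality questionable in cell {name!r} (p={p:.3g})")
        residuals.append(obs - obs.mean())
    resid = np.concatenate(residuals)
    sh_res = float(stats.shapiro(resid).pvalue)
    if sh_res <= alpha:
        warnings.append(f"residual normality questionable (p={sh_res:.3g})")
    lev = float(stats.levene(*cells.values()).pvalue)
    if lev <= alpha:
        warnings.append(f"variance homogeneity questionable (p={lev:.3g})")
    return AssumptionReport(
        shapiro_p=shapiro_p, shapiro_residuals_p=sh_res, levene_p=lev,
        warnings=warnings,
    )
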