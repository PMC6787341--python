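"""Factorial group statistics.

The behavioral, imaging and protein measures are analyzed with a
between-subjects two-way ANOVA (injury x recovery time) using Type III
sums of squares with sum-to-zero contrasts, which remains well-defined
for the unbalanced cohorts typical of these studies (e.g. sham = 8 vs
injured = 10).  Protected pairwise group comparisons at each time point
use the pooled ANOVA error term with a Bonferroni correction.  Acute
injury measures recorded once per injury (first, second) are analyzed
with a 2x2 mixed-design ANOVA (between: group; within: injury number).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols


class DesignError(ValueError):
    pass


@dataclass
class PosthocComparison:
    level: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t: float
    p_raw: float
    p_adjusted: float
    family_size: int


def _check_cells(obs: pd.DataFrame, a: str, b: str) -> None:
    counts = obs.groupby([a, b], observed=True).size().unstack(fill_value=0)
    empty = [(ia, ib) for ia in counts.index for ib in counts.columns
             if counts.loc[ia, ib] == 0]
    if empty:
        raise DesignError(f"empty design cell(s) {empty}: interaction not estimable")


def two_way_anova(obs: pd.DataFrame, dv: str = "value",
                  between: tuple[str, str] = ("injury", "recovery_day"),
                  ) -> pd.DataFrame:
    """Between-subjects two-way ANOVA, Type III SS, sum-to-zero contrasts.

    Returns a table with one row per effect (both main effects, the
    interaction, and the residual): ``effect, ss, df, F, p``.
    """
    a, b = between
    for col in (a, b, dv):
        if col not in obs.columns:
            raise DesignError(f"missing column {col!r}")
    if obs[a].nunique() < 2 or obs[b].nunique() < 2:
        raise DesignError("each factor needs >= 2 levels")
    _check_cells(obs, a, b)
    model = ols(f"Q('{dv}') ~ C(Q('{a}'), Sum) * C(Q('{b}'), Sum)", data=obs).fit()
    if model.df_resid <= 0:
        raise DesignError("no residual degrees of freedom")
    tab = sm.stats.anova_lm(model, typ=3)
    rename = {f"C(Q('{a}'), Sum)": a,
              f"C(Q('{b}'), Sum)": b,
              f"C(Q('{a}'), Sum):C(Q('{b}'), Sum)": f"{a}:{b}",
              "Residual": "residual"}
    out = (tab.rename(index=rename)
              .loc[[a, b, f"{a}:{b}", "residual"]]
              .reset_index(names="effect")
              .rename(columns={"sum_sq": "ss", "F": "F", "PR(>F)": "p"}))
    return out[["effect", "ss", "df", "F", "p"]]


def bonferroni_pairwise(obs: pd.DataFrame, dv: str = "value",
                        group: str = "injury", family: str = "recovery_day",
                        ) -> list[PosthocComparison]:
    """Per-time-level two-group comparisons using the pooled error term.

    The raw p-value at each level of ``family`` is a two-sided t test of
    the group means against the ANOVA residual mean square (protected
    comparisons); the Bonferroni adjustment multiplies by the family
    size m (the number of levels compared), capped at 1.
    """
    levels = list(pd.unique(obs[family]))
    usable = []
    for lev in levels:
        sub = obs[obs[family] == lev]
        if sub[group].nunique() < 2:
            warnings.warn(f"{family}={lev!r}: only one group, skipped",
                          stacklevel=2)
            continue
        usable.append(lev)
    m = len(usable)
    if m < 2:
        raise DesignError("need >= 2 usable levels for the pooled error term")
    obs = obs[obs[family].isin(usable)]
    anova = two_way_anova(obs, dv=dv, between=(group, family))
    resid = anova.set_index("effect").loc["residual"]
    mse = float(resid["ss"] / resid["df"])
    df_err = float(resid["df"])
    out = []
    for lev in usable:
        sub = obs[obs[family] == lev]
        gvals = [g[dv].to_numpy(float) for _, g in sub.groupby(group, sort=True)]
        va, vb = gvals[0], gvals[1]
        se = np.sqrt(mse * (1.0 / len(va) + 1.0 / len(vb)))
        t = (va.mean() - vb.mean()) / se
        p = 2.0 * sps.t.sf(abs(t), df_err)
        out.append(PosthocComparison(
            level=str(lev), mean_a=float(va.mean()), mean_b=float(vb.mean()),
            n_a=len(va), n_b=len(vb), t=float(t), p_raw=float(p),
            p_adjusted=float(min(1.0, m * p)), family_size=m))
    return out


def mixed_anova_2x2(obs: pd.DataFrame, dv: str = "value",
                    subject: str = "subject_id", between: str = "injury",
                    within: str = "injury_number") -> pd.DataFrame:
    """2x2 mixed-design (split-plot) ANOVA.

    One between-subjects factor (two or more groups) and one
    within-subjects factor with exactly two levels (e.g. first vs second
    injury).  The between effect is tested against subjects-within-
    groups variation (via per-subject means); the within effect and the
    interaction are tested against the subject x within residual (via
    per-subject differences).  Subjects missing a measurement are
    dropped with a warning.  Type III semantics throughout.
    """
    wlevels = sorted(obs[within].unique())
    if len(wlevels) != 2:
        raise DesignError(f"within factor needs exactly 2 levels, got {wlevels}")
    wide = obs.pivot_table(index=[subject, between], columns=within,
                           values=dv, aggfunc="first").reset_index()
    incomplete = wide[wide[wlevels].isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(f"dropping {len(incomplete)} subject(s) with missing "
                      f"measurements: {list(incomplete[subject])}", stacklevel=2)
        wide = wide.dropna(subset=wlevels)
    if len(wide) < 3:
        raise DesignError("too few complete subjects")

    wide = wide.copy()
    wide["_mean"] = wide[wlevels].mean(axis=1)
    wide["_diff"] = wide[wlevels[1]] - wide[wlevels[0]]

    bterm = f"C(Q('{between}'), Sum)"
    # between stratum: subject means (x2 restores original-unit SS)
    mb = ols(f"_mean ~ {bterm}", data=wide).fit()
    tb = sm.stats.anova_lm(mb, typ=3)
    ss_between = 2.0 * float(tb.loc[bterm, "sum_sq"])
    df_between = float(tb.loc[bterm, "df"])
    ss_subj = 2.0 * float(tb.loc["Residual", "sum_sq"])
    df_subj = float(tb.loc["Residual", "df"])
    f_between = (ss_between / df_between) / (ss_subj / df_subj)
    p_between = float(sps.f.sf(f_between, df_between, df_subj))

    # within stratum: subject differences (x1/2 restores original-unit SS);
    # the Type III intercept tests the within main effect, the group term
    # the interaction
    diffs = wide["_diff"].to_numpy(float)
    n_groups = wide[between].nunique()
    df_inter = float(n_groups - 1)
    df_resid = float(len(wide) - n_groups)
    scale_tol = 1e-12 * (np.abs(diffs).max() ** 2 + 1.0)
    if np.ptp(diffs) ** 2 < scale_tol:
        # every subject changed by the same constant: no residual, no
        # interaction; the within effect is exactly zero or overwhelming
        ss_inter, ss_resid = 0.0, 0.0
        ss_within = 0.5 * float((diffs ** 2).sum())
        f_inter = 0.0
        f_within = 0.0 if ss_within < scale_tol else np.inf
    else:
        md = ols(f"_diff ~ {bterm}", data=wide).fit()
        td = sm.stats.anova_lm(md, typ=3)
        ss_within = 0.5 * float(td.loc["Intercept", "sum_sq"])
        ss_inter = 0.5 * float(td.loc[bterm, "sum_sq"])
        ss_resid = 0.5 * float(td.loc["Residual", "sum_sq"])
        ms_resid = ss_resid / df_resid
        f_within = ss_within / ms_resid
        f_inter = (ss_inter / df_inter) / ms_resid
    rows = [
        {"effect": between, "ss": ss_between, "df": df_between,
         "F": f_between, "p": p_between},
        {"effect": "subjects(group)", "ss": ss_subj, "df": df_subj,
         "F": np.nan, "p": np.nan},
        {"effect": within, "ss": ss_within, "df": 1.0, "F": f_within,
         "p": float(sps.f.sf(f_within, 1.0, df_resid))},
        {"effect": f"{between}:{within}", "ss": ss_inter, "df": df_inter,
         "F": f_inter, "p": float(sps.f.sf(f_inter, df_inter, df_resid))},
        {"effect": "residual", "ss": ss_resid, "df": df_resid,
         "F": np.nan, "p": np.nan},
    ]
    return pd.DataFrame(rows)


def summarize_mean_sem(obs: pd.DataFrame, dv: str = "value",
                       by: tuple[str, ...] = ("injury", "recovery_day"),
                       ) -> pd.DataFrame:
    """Per-cell n, mean and SEM (sample sd / sqrt(n); 0 when n = 1)."""
    def _sem(v):
        return 0.0 if len(v) < 2 else float(np.std(v, ddof=1) / np.sqrt(len(v)))
    out = (obs.groupby(list(by), observed=True)[dv]
              .agg(n="count", mean="mean", sem=_sem)
              .reset_index())
    return out
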