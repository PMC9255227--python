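"""Treatment-group comparison: one-way ANOVA, protected LSD letters,
percent change versus control.

Every derived parameter (fluorescence indices, dI/I_o, pigments, gas
exchange) flows through the same tidy table of
``{sample_id, group, replicate, parameter, value}`` rows and the same
classical machinery: equal-variance one-way ANOVA, Fisher's least
significant difference

    LSD = t_{1-alpha/2, df_err} * sqrt(2 * MSE / n)

and compact letters assigned greedily in descending-mean order. The LSD
step is *protected*: when the ANOVA is not significant at alpha all groups
share one letter, which keeps the familywise null error rate near alpha
(unprotected LSD on four groups would roughly quadruple it). No correction
is applied across parameters; each parameter is compared on its own.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import StatisticsError

logger = logging.getLogger("ojipkit")

TIDY_COLUMNS = ("sample_id", "group", "replicate", "parameter", "value")


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way decomposition: F = MS_between / MS_error."""

    f: float
    p: float
    ms_between: float
    mse: float
    df_between: int
    df_err: int
    flags: tuple[str, ...] = ()


def _as_groups(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(out) < 2:
        raise StatisticsError("ANOVA needs at least two groups")
    for g, v in out.items():
        if v.size < 2:
            raise StatisticsError(f"group {g!r} has fewer than 2 replicates")
        if not np.all(np.isfinite(v)):
            raise StatisticsError(f"group {g!r} contains non-finite values")
    return out


def one_way_anova(values_by_group: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Equal-variance one-way ANOVA via an OLS fit on group indicators.

    Degenerate inputs are resolved before fitting: zero variance both
    within and between groups gives F=0, p=1 (flagged); zero within-group
    variance with separated means gives F=inf, p=0 (flagged).
    """
    groups = _as_groups(values_by_group)
    k = len(groups)
    n_total = sum(v.size for v in groups.values())
    df_b, df_e = k - 1, n_total - k

    ssw = sum(float(((v - v.mean()) ** 2).sum()) for v in groups.values())
    grand = sum(float(v.sum()) for v in groups.values()) / n_total
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    scale = max(grand * grand, 1.0)
    if ssw / df_e < 1e-300 * scale:
        if ssb / df_b < 1e-300 * scale:
            return AnovaResult(0.0, 1.0, 0.0, 0.0, df_b, df_e,
                               flags=("degenerate: no variance at all",))
        return AnovaResult(math.inf, 0.0, ssb / df_b, 0.0, df_b, df_e,
                           flags=("degenerate: zero within-group variance",))

    frame = pd.DataFrame(
        {"value": np.concatenate(list(groups.values())),
         "group": np.repeat(list(groups), [v.size for v in groups.values()])}
    )
    fit = smf.ols("value ~ C(group)", data=frame).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    ms_b = float(table.loc["C(group)", "sum_sq"] / table.loc["C(group)", "df"])
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    return AnovaResult(
        f=float(table.loc["C(group)", "F"]),
        p=float(table.loc["C(group)", "PR(>F)"]),
        ms_between=ms_b, mse=mse, df_between=df_b, df_err=df_e,
    )


def lsd_posthoc(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float,
    mse: float,
    df_err: int,
    anova_p: float | None = None,
) -> dict[str, str]:
    """Compact letters from Fisher's (protected) LSD.

    Groups whose means differ by less than the LSD share a letter; letters
    are assigned greedily in descending-mean order. With unequal group
    sizes the harmonic-mean n is used (logged). When ``anova_p`` is given
    and exceeds ``alpha`` the test is protected: every group gets ``"a"``.
    """
    if df_err < 1:
        raise StatisticsError("df_err < 1: LSD undefined")
    if not 0.0 < alpha < 1.0:
        raise StatisticsError("alpha must lie in (0, 1)")
    groups = _as_groups(values_by_group)
    names = sorted(groups, key=lambda g: -float(np.mean(groups[g])))
    if anova_p is not None and anova_p > alpha:
        return {g: "a" for g in names}

    sizes = [groups[g].size for g in names]
    if len(set(sizes)) > 1:
        n_eff = len(sizes) / sum(1.0 / n for n in sizes)
        logger.info("unequal group sizes %s: harmonic-mean n=%.3f for LSD", sizes, n_eff)
    else:
        n_eff = float(sizes[0])
    lsd = scipy.stats.t.ppf(1.0 - alpha / 2.0, df_err) * math.sqrt(2.0 * mse / n_eff)
    means = {g: float(np.mean(groups[g])) for g in names}

    def differ(a: str, b: str) -> bool:
        return abs(means[a] - means[b]) >= lsd and lsd > 0 or (lsd == 0 and means[a] != means[b])

    classes: list[list[str]] = []  # each class = one letter
    for g in names:
        placed = False
        for cls in classes:
            if all(not differ(g, member) for member in cls):
                cls.append(g)
                placed = True
        if not placed:
            classes.append([g])
    letters = {g: "" for g in names}
    for i, cls in enumerate(classes):
        letter = chr(ord("a") + i) if i < 26 else f"({i})"
        for g in cls:
            letters[g] += letter
    return letters


def percent_change(
    table: pd.DataFrame, control: str = "CK"
) -> pd.DataFrame:
    """Group-mean percent change vs the control for every parameter.

    100 * (mean_group - mean_control) / mean_control; decreases are
    negative. A zero control mean leaves the value ``nan`` with a flag.
    """
    _require_tidy(table)
    if control not in set(table["group"]):
        raise StatisticsError(f"control group {control!r} absent from table")
    means = table.groupby(["parameter", "group"])["value"].mean().unstack("group")
    rows = []
    for parameter, row in means.iterrows():
        ref = row[control]
        for group, mean in row.items():
            if pd.isna(mean):
                continue
            if ref == 0 or pd.isna(ref):
                pct, flag = math.nan, "control mean is zero"
            else:
                pct, flag = 100.0 * (mean - ref) / ref, ""
            rows.append({"parameter": parameter, "group": group,
                         "percent_change": pct, "flag": flag})
    return pd.DataFrame(rows)


def summarize_groups(
    table: pd.DataFrame, control: str = "CK", alpha: float = 0.05
) -> pd.DataFrame:
    """Full comparison report: one row per group x parameter.

    Columns: n, mean, sd, ANOVA F and p, MSE, df_err, LSD letter(s), and
    percent change vs control. Parameters with fewer than two groups of
    n>=2 are skipped with a log entry.
    """
    _require_tidy(table)
    if control not in set(table["group"]):
        raise StatisticsError(f"control group {control!r} absent from table")
    pct = percent_change(table, control).set_index(["parameter", "group"])
    out = []
    for parameter, sub in table.groupby("parameter", sort=True):
        values = {g: v["value"].to_numpy(dtype=float).tolist()
                  for g, v in sub.groupby("group")}
        values = {g: v for g, v in values.items() if len(v) >= 2}
        if len(values) < 2 or control not in values:
            logger.warning("parameter %s: not enough replicated groups, skipped", parameter)
            continue
        anova = one_way_anova(values)
        if math.isfinite(anova.f):
            letters = lsd_posthoc(values, alpha, anova.mse, anova.df_err, anova_p=anova.p)
        else:  # complete separation: every distinct mean is its own letter
            letters = lsd_posthoc(values, alpha, 0.0, anova.df_err, anova_p=0.0)
        for group, vals in values.items():
            arr = np.asarray(vals)
            out.append({
                "parameter": parameter, "group": group,
                "n": arr.size, "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)),
                "anova_F": anova.f, "anova_p": anova.p,
                "mse": anova.mse, "df_err": anova.df_err,
                "letters": letters[group],
                "percent_change_vs_control":
                    float(pct.loc[(parameter, group), "percent_change"]),
                "flags": ";".join(anova.flags),
            })
    return pd.DataFrame(out)


def _require_tidy(table: pd.DataFrame) -> None:
    missing = {"group", "parameter", "value"} - set(table.columns)
    if missing:
        raise StatisticsError(f"tidy table missing columns: {sorted(missing)}")
    if table.empty:
        raise StatisticsError("tidy table is empty")
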