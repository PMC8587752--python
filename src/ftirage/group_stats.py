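"""Two-way ANOVA (tissue x age) with Sidak-adjusted pairwise contrasts.

Balanced designs use the classical sums-of-squares partition computed
directly from cell means (fast enough for calibration simulations);
unbalanced designs — the normal case after Q-residual outlier removal —
fall back to Type II sums of squares from an effect-coded linear model
(statsmodels OLS + anova_lm).  The two paths agree exactly on balanced
data.

Pairwise comparisons follow the figure convention of the field: within
each age, cardiac vs skeletal cell means, using the pooled residual mean
square, with Sidak multiplicity adjustment over the family of ages and
star codes at 0.05 / 0.01 / 0.001 / 0.0001.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, GroupError, ValidationError

EFFECTS = ["tissue", "age", "tissue:age", "residual"]

_STAR_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def _star(p: float) -> str:
    for cut, code in _STAR_LEVELS:
        if p < cut:
            return code
    return "ns"


def _check_inputs(values, tissue, age):
    values = np.asarray(values, dtype=float)
    tissue = np.asarray(tissue, dtype=object)
    age = np.asarray(age, dtype=object)
    if not (len(values) == len(tissue) == len(age)):
        raise ValidationError("values, tissue and age must be equal length")
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite values")
    if len(set(tissue)) < 2 or len(set(age)) < 2:
        raise GroupError("both factors need at least 2 levels")
    return values, tissue, age


def _balanced_anova(values, tissue, age) -> pd.DataFrame:
    """Classical partition from cell sums; valid only for balanced data."""
    df = pd.DataFrame({"v": values, "t": tissue, "a": age})
    cells = df.groupby(["t", "a"], sort=True)["v"]
    n_cell = cells.size().iloc[0]
    grand = df["v"].mean()
    N = len(df)
    a_lv = sorted(set(tissue))
    b_lv = sorted(set(age))
    ss_total = float(((df["v"] - grand) ** 2).sum())
    t_means = df.groupby("t")["v"].mean()
    a_means = df.groupby("a")["v"].mean()
    cell_means = cells.mean()
    ss_tissue = float((N / len(a_lv)) * ((t_means - grand) ** 2).sum())
    ss_age = float((N / len(b_lv)) * ((a_means - grand) ** 2).sum())
    ss_cells = float(n_cell * ((cell_means - grand) ** 2).sum())
    ss_inter = ss_cells - ss_tissue - ss_age
    ss_resid = ss_total - ss_cells
    df_t = len(a_lv) - 1
    df_a = len(b_lv) - 1
    df_i = df_t * df_a
    df_r = N - len(a_lv) * len(b_lv)
    return _assemble(ss_tissue, df_t, ss_age, df_a, ss_inter, df_i, ss_resid, df_r)


def _assemble(ss_t, df_t, ss_a, df_a, ss_i, df_i, ss_r, df_r) -> pd.DataFrame:
    if df_r <= 0:
        raise DegenerateDataError("zero residual degrees of freedom")
    ms_r = ss_r / df_r
    if ms_r <= 0:
        raise DegenerateDataError("no residual variance; F undefined")
    rows = []
    for name, ss, dfree in [
        ("tissue", ss_t, df_t),
        ("age", ss_a, df_a),
        ("tissue:age", ss_i, df_i),
    ]:
        ms = ss / dfree
        F = ms / ms_r
        rows.append(
            {
                "effect": name,
                "ss": ss,
                "df": dfree,
                "ms": ms,
                "F": F,
                "p": float(stats.f.sf(F, dfree, df_r)),
            }
        )
    rows.append(
        {"effect": "residual", "ss": ss_r, "df": df_r, "ms": ms_r,
         "F": float("nan"), "p": float("nan")}
    )
    return pd.DataFrame(rows).set_index("effect")


def _type2_anova(values, tissue, age) -> pd.DataFrame:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = pd.DataFrame(
        {"v": values, "t": pd.Categorical(tissue), "a": pd.Categorical(age)}
    )
    model = smf.ols("v ~ C(t, Sum) * C(a, Sum)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = []
    mapping = {
        "C(t, Sum)": "tissue",
        "C(a, Sum)": "age",
        "C(t, Sum):C(a, Sum)": "tissue:age",
        "Residual": "residual",
    }
    resid_ms = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
    if resid_ms <= 0:
        raise DegenerateDataError("no residual variance; F undefined")
    for key, name in mapping.items():
        ss = float(table.loc[key, "sum_sq"])
        dfree = float(table.loc[key, "df"])
        ms = ss / dfree
        out.append(
            {
                "effect": name,
                "ss": ss,
                "df": int(dfree),
                "ms": ms,
                "F": float(table.loc[key, "F"]) if name != "residual" else float("nan"),
                "p": float(table.loc[key, "PR(>F)"]) if name != "residual" else float("nan"),
            }
        )
    return pd.DataFrame(out).set_index("effect")


def two_way_anova(values, tissue, age) -> pd.DataFrame:
    """Ordinary (not repeated-measures) two-way ANOVA table.

    Returns a DataFrame indexed by effect (tissue, age, tissue:age,
    residual) with columns ss, df, ms, F, p.
    """
    values, tissue, age = _check_inputs(values, tissue, age)
    if np.ptp(values) == 0:
        raise DegenerateDataError("all observations identical; no variance")
    counts = pd.crosstab(pd.Series(tissue), pd.Series(age))
    if (counts.values == 0).any():
        empty = np.argwhere(counts.values == 0)[0]
        raise GroupError(
            f"empty cell ({counts.index[empty[0]]}, {counts.columns[empty[1]]})"
        )
    if counts.values.std() == 0:
        return _balanced_anova(values, tissue, age)
    return _type2_anova(values, tissue, age)


def sidak_adjust(raw_p, m: int | None = None) -> np.ndarray:
    """Sidak multiplicity adjustment: 1 - (1 - p)^m, clipped to [0, 1]."""
    p = np.atleast_1d(np.asarray(raw_p, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < 1:
        raise ValidationError("m must be >= 1")
    return np.clip(1.0 - np.power(1.0 - p, m), 0.0, 1.0)


def pairwise_cells(values, tissue, age, alpha: float = 0.05) -> pd.DataFrame:
    """Cardiac-vs-skeletal contrasts at each age, Sidak-adjusted.

    t = (mean_a - mean_b) / sqrt(MS_resid * (1/n_a + 1/n_b)) on the
    residual df of the two-way ANOVA; two-sided p; the adjustment family
    is the set of ages.
    """
    values, tissue, age = _check_inputs(values, tissue, age)
    table = two_way_anova(values, tissue, age)
    ms_resid = float(table.loc["residual", "ms"])
    df_resid = int(table.loc["residual", "df"])
    tissues = sorted(set(tissue))
    if len(tissues) != 2:
        raise GroupError("pairwise_cells expects exactly 2 tissues")
    ta, tb = tissues
    ages = sorted(set(age))
    rows = []
    for a in ages:
        va = values[(tissue == ta) & (age == a)]
        vb = values[(tissue == tb) & (age == a)]
        if len(va) == 0 or len(vb) == 0:
            raise GroupError(f"empty cell at age {a}")
        diff = float(va.mean() - vb.mean())
        se = np.sqrt(ms_resid * (1.0 / len(va) + 1.0 / len(vb)))
        tstat = diff / se
        p = float(2.0 * stats.t.sf(abs(tstat), df_resid))
        rows.append(
            {
                "age_months": a,
                "group_a": ta,
                "group_b": tb,
                "mean_difference": diff,
                "t": tstat,
                "raw_p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["sidak_p"] = sidak_adjust(out["raw_p"].to_numpy(), m=len(out))
    out["significant"] = out["sidak_p"] < alpha
    out["stars"] = [_star(p) for p in out["sidak_p"]]
    return out
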