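"""The statistical workflow: ROUT outlier removal, ANOVA with Tukey-Kramer
multiple comparisons, unpaired t-tests and residual normality checks.

ROUT (robust regression and outlier removal, Motulsky & Brown 2006) is
implemented for the constant model — a robust location fit followed by
FDR-controlled flagging of extreme residuals — which is how it applies to
column data.  The ANOVA decompositions delegate to statsmodels OLS
(Type-II sums of squares by default, suited to the unbalanced group sizes
that larva dropout produces); the Tukey-Kramer procedure is evaluated on the
studentized-range distribution with the Kramer small-sample adjustment for
unequal n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import normal_ad

__all__ = [
    "RoutResult",
    "AnovaResult",
    "NormalityResult",
    "rout_outliers",
    "two_way_anova_tukey",
    "one_way_anova_tukey",
    "ttest_unpaired",
    "normality_tests",
]


# --------------------------------------------------------------------------
# ROUT
# --------------------------------------------------------------------------

@dataclass
class RoutResult:
    robust_center: float
    rsdr: float
    outlier_flag: np.ndarray  # bool, aligned with the input
    q: float

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_flag.sum())


def _robust_center(x: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> float:
    """Location minimizing the Lorentzian merit sum(log(1 + (r/s)^2)).

    Iteratively reweighted mean with weights 1 / (1 + (r/s)^2); the scale s
    is re-estimated each sweep from the 68.27th percentile of |residuals|.
    """
    m = float(np.median(x))
    spread = float(np.percentile(np.abs(x - m), 68.27))
    if spread == 0:
        return m
    for _ in range(max_iter):
        r = x - m
        s = float(np.percentile(np.abs(r), 68.27))
        if s == 0:
            break
        w = 1.0 / (1.0 + (r / s) ** 2)
        m_new = float(np.sum(w * x) / np.sum(w))
        if abs(m_new - m) <= tol * max(1.0, abs(m)):
            m = m_new
            break
        m = m_new
    return m


def rout_outliers(values, q: float = 0.01) -> RoutResult:
    """Flag outliers in a single sample via the ROUT procedure at FDR level q.

    Steps: robust location fit; RSDR from the 68.27th percentile of absolute
    residuals scaled by n/(n - 1) (one fitted parameter); two-tailed t
    probability of each scaled residual with n - 1 df; Benjamini-Hochberg
    step-up over those p-values at level q, flagging from the most extreme
    residual inward.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    n = x.size
    if n < 3:
        raise ValueError("ROUT needs at least 3 values")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    center = _robust_center(x)
    resid = x - center
    rsdr = float(np.percentile(np.abs(resid), 68.27)) * n / (n - 1)
    flags = np.zeros(n, dtype=bool)
    if rsdr == 0:
        # Degenerate (e.g. all values identical): no outliers by definition.
        return RoutResult(center, 0.0, flags, q)
    t = np.abs(resid) / rsdr
    p = 2.0 * sps.t.sf(t, df=n - 1)
    order = np.argsort(p)  # most extreme first
    ranked = p[order]
    thresholds = q * (np.arange(1, n + 1) / n)
    passing = np.nonzero(ranked <= thresholds)[0]
    if passing.size:
        k = passing.max()
        flags[order[: k + 1]] = True
    return RoutResult(center, rsdr, flags, q)


# --------------------------------------------------------------------------
# ANOVA + Tukey-Kramer
# --------------------------------------------------------------------------

@dataclass
class AnovaResult:
    table: pd.DataFrame         # effects: sum_sq, df, F, PR(>F)
    comparisons: pd.DataFrame   # pairwise Tukey-Kramer results
    residuals: np.ndarray
    mse: float
    df_resid: float


def _tukey_kramer(
    means: pd.Series,
    counts: pd.Series,
    mse: float,
    df_resid: float,
    extra: dict | None = None,
) -> list[dict]:
    """All pairwise comparisons among the given cell means.

    q = |mi - mj| / sqrt((mse / 2) * (1/ni + 1/nj)); the adjusted p comes
    from the studentized-range distribution with k = number of means.
    """
    levels = list(means.index)
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = means[a] - means[b]
            se = math.sqrt((mse / 2.0) * (1.0 / counts[a] + 1.0 / counts[b]))
            qstat = abs(diff) / se if se > 0 else np.inf
            p_adj = float(sps.studentized_range.sf(qstat, k, df_resid)) if np.isfinite(qstat) else 0.0
            rows.append(
                {
                    **(extra or {}),
                    "group1": a,
                    "group2": b,
                    "mean_diff": diff,
                    "se": se,
                    "q": qstat,
                    "p_adj": min(max(p_adj, 0.0), 1.0),
                }
            )
    return rows


def _prepare(table: pd.DataFrame, value: str, factors: list[str]) -> pd.DataFrame:
    df = table[[value] + factors].dropna().copy()
    df.columns = ["y"] + [f"f{i}" for i in range(len(factors))]
    return df


def two_way_anova_tukey(
    table: pd.DataFrame,
    value: str = "normalized_area",
    factor_a: str = "group",
    factor_b: str = "timepoint",
    ss_type: int = 2,
) -> AnovaResult:
    """Two-factor ANOVA with interaction plus Tukey-Kramer comparisons of
    ``factor_a`` levels within each level of ``factor_b``.

    Sums of squares are Type II by default (Type III via ``ss_type=3``).
    Every factor combination must be observed at least once.
    """
    df = _prepare(table, value, [factor_a, factor_b])
    counts = df.groupby(["f0", "f1"], observed=True).size().unstack()
    if counts.isna().any().any() or (counts == 0).any().any():
        empty = [tuple(ix) for ix in np.argwhere(counts.fillna(0).to_numpy() == 0)]
        cells = [(counts.index[i], counts.columns[j]) for i, j in empty]
        raise ValueError(f"empty design cells: {cells}")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("each factor needs at least two levels")
    model = ols("y ~ C(f0) * C(f1)", data=df).fit()
    aov = anova_lm(model, typ=ss_type)
    aov.index = [
        i.replace("C(f0)", factor_a).replace("C(f1)", factor_b) for i in aov.index
    ]
    mse = float(aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"])
    df_resid = float(aov.loc["Residual", "df"])
    rows: list[dict] = []
    for level_b, sub in df.groupby("f1", observed=True):
        means = sub.groupby("f0", observed=True)["y"].mean()
        ns = sub.groupby("f0", observed=True)["y"].size()
        rows.extend(_tukey_kramer(means, ns, mse, df_resid, extra={factor_b: level_b}))
    return AnovaResult(aov, pd.DataFrame(rows), np.asarray(model.resid), mse, df_resid)


def one_way_anova_tukey(values, groups) -> AnovaResult:
    """One-factor ANOVA plus Tukey-Kramer comparisons of all group pairs."""
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "f0": np.asarray(groups)})
    ns = df.groupby("f0")["y"].size()
    if len(ns) < 2:
        raise ValueError("need at least two groups")
    if (ns < 2).any():
        raise ValueError(f"groups with fewer than 2 observations: {list(ns[ns < 2].index)}")
    model = ols("y ~ C(f0)", data=df).fit()
    aov = anova_lm(model, typ=1)
    aov.index = ["group", "Residual"]
    mse = float(aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"])
    df_resid = float(aov.loc["Residual", "df"])
    means = df.groupby("f0")["y"].mean()
    comps = pd.DataFrame(_tukey_kramer(means, ns, mse, df_resid))
    return AnovaResult(aov, comps, np.asarray(model.resid), mse, df_resid)


# --------------------------------------------------------------------------
# t-test and normality
# --------------------------------------------------------------------------

def ttest_unpaired(a, b, welch: bool = False) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; pooled variance by default (the Prism
    convention), Welch via ``welch=True``.  Returns (t, df, p).

    Degenerate zero-variance input: equal means give (0, df, 1); unequal
    means give the p -> 0 limit.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    df = a.size + b.size - 2 if not welch else None
    pooled_var = (np.var(a, ddof=1) * (a.size - 1) + np.var(b, ddof=1) * (b.size - 1)) / (a.size + b.size - 2)
    if pooled_var == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.copysign(math.inf, np.mean(a) - np.mean(b)), float(a.size + b.size - 2), 0.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    dof = float(res.df) if hasattr(res, "df") else float(df)
    return float(res.statistic), dof, float(res.pvalue)


@dataclass
class NormalityResult:
    anderson_darling_a2: float
    anderson_darling_p: float
    shapiro_w: float
    shapiro_p: float

    @property
    def available(self) -> bool:
        return not math.isnan(self.anderson_darling_a2)


def normality_tests(residuals, min_n: int = 8) -> NormalityResult:
    """Anderson-Darling (normal, estimated parameters) and Shapiro-Wilk.

    Advisory only — never gates the pipeline.  Below ``min_n`` observations,
    or for constant input, all fields are NaN (reported missing).
    """
    x = np.asarray(residuals, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_n or np.ptp(x) == 0:
        return NormalityResult(math.nan, math.nan, math.nan, math.nan)
    a2, ad_p = normal_ad(x)
    w, sw_p = sps.shapiro(x)
    return NormalityResult(float(a2), float(ad_p), float(w), float(sw_p))
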