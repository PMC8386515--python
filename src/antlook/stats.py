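"""The statistical battery, with its conventions made explicit.

Every test used in the main and supplementary analyses lives here:

* two-tailed **exact binomial** test of a proportion against chance;
* two-tailed **Fisher's exact** test on a 2x2 condition x correctness table;
* **one-sample t** on DLS scores against the chance level 0.5;
* **Welch two-sample t** (Satterthwaite fractional df) comparing DLS
  between conditions;
* 2x2 between-subjects **ANOVA** (condition x inclusion) on DLS,
  **Type-III** sums of squares with sum-to-zero contrasts — the convention
  of the SPSS-style reporting tradition for unbalanced designs;
* 2 (condition, between) x 2 (correct/incorrect window, within) **mixed
  ANOVA** on looking durations, implemented through the exact algebraic
  equivalence with between-subject ANOVAs on per-participant difference
  and mean scores (valid because the within factor has two levels).

Both exact tests use the *point-probability* two-sided convention: the
two-sided p is the total probability of outcomes no more likely than the
observed one.  "Two-tailed exact" is ambiguous across software packages;
this is the convention implemented by scipy (and R's ``binom.test`` /
``fisher.test``), and it is stated explicitly because such conventions
have driven replication disputes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    """Raised for domain errors (empty samples, zero variance, empty cells)."""


@dataclass(frozen=True)
class TestResult:
    """One test's report: statistic, df, p, point estimate, 95% CI."""

    method: str
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    estimate: float
    ci95: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")

    def to_dict(self) -> dict:
        df = self.df
        if isinstance(df, tuple):
            df = list(df)
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": df,
            "p": self.p,
            "estimate": self.estimate,
            "ci95": None if self.ci95 is None else list(self.ci95),
        }


def exact_binomial_two_tailed(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Two-tailed exact binomial test of ``k`` successes in ``n`` trials.

    p = sum of Binomial(n, p0) point probabilities over all outcomes whose
    probability does not exceed that of the observed ``k``.
    """
    if n <= 0:
        raise StatsError("binomial test requires n >= 1")
    if not 0 <= k <= n:
        raise StatsError(f"k={k} outside [0, {n}]")
    if not 0.0 < p0 < 1.0:
        raise StatsError("null probability must be in (0, 1)")
    res = sps.binomtest(k, n, p0)
    ci = res.proportion_ci(0.95, method="exact")
    return TestResult(
        method="exact binomial, two-tailed (point-probability)",
        statistic=float(k),
        df=None,
        p=float(res.pvalue),
        estimate=k / n,
        ci95=(float(ci.low), float(ci.high)),
    )


def fisher_exact_two_tailed(table) -> TestResult:
    """Two-tailed Fisher's exact test on a 2x2 table.

    p = sum of hypergeometric probabilities (margins fixed) of all tables
    no more probable than the observed one.  A degenerate table with a zero
    row or column margin yields p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise StatsError("Fisher test requires a 2x2 table of non-negative counts")
    if t.sum() == 0:
        raise StatsError("Fisher test requires at least one positive margin")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); p = 1 by convention")
        odds = math.nan
        p = 1.0
    else:
        odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(
        method="Fisher exact, two-tailed (point-probability)",
        statistic=float(odds),
        df=None,
        p=float(p),
        estimate=float(odds),
    )


def one_sample_t(values, mu0: float = 0.5) -> TestResult:
    """Classic one-sample t-test (df = n - 1) with 95% CI of the mean."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise StatsError("one-sample t requires >= 2 finite values")
    if np.var(x, ddof=1) == 0:
        raise StatsError("one-sample t requires nonzero variance")
    res = sps.ttest_1samp(x, mu0)
    ci = res.confidence_interval(0.95)
    return TestResult(
        method="one-sample t",
        statistic=float(res.statistic),
        df=float(x.size - 1),
        p=float(res.pvalue),
        estimate=float(x.mean()),
        ci95=(float(ci.low), float(ci.high)),
    )


def welch_t(a, b) -> TestResult:
    """Welch two-sample t with Satterthwaite (fractional) df.

    The estimate and CI are for the mean difference ``a - b``.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
    if xa.size < 2 or xb.size < 2:
        raise StatsError("Welch t requires >= 2 finite values per group")
    if np.var(xa, ddof=1) == 0 and np.var(xb, ddof=1) == 0:
        raise StatsError("Welch t requires nonzero variance")
    res = sps.ttest_ind(xa, xb, equal_var=False)
    ci = res.confidence_interval(0.95)
    return TestResult(
        method="Welch two-sample t",
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        estimate=float(xa.mean() - xb.mean()),
        ci95=(float(ci.low), float(ci.high)),
    )


def _check_cells(data: pd.DataFrame, f1: str, f2: str) -> None:
    counts = data.groupby([f1, f2], observed=True).size()
    for a in data[f1].unique():
        for b in data[f2].unique():
            if (a, b) not in counts.index or counts[(a, b)] == 0:
                raise StatsError(f"empty cell {f1}={a!r}, {f2}={b!r}")


def anova_2x2_between(y, f1, f2, names: tuple[str, str] = ("condition", "inclusion")) -> pd.DataFrame:
    """2x2 between-subjects ANOVA, Type-III SS with sum-to-zero contrasts.

    ``y`` may contain NaN (undefined DLS); those rows are dropped first.
    Returns an effect table with rows for both main effects, the
    interaction and the residual; columns ``sum_sq, df, F, p``.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    data = pd.DataFrame({"y": np.asarray(y, dtype=float),
                         "f1": list(f1), "f2": list(f2)})
    data = data.dropna(subset=["y"])
    if data["f1"].nunique() != 2 or data["f2"].nunique() != 2:
        raise StatsError("both factors must have exactly 2 observed levels")
    _check_cells(data, "f1", "f2")
    model = smf.ols("y ~ C(f1, Sum) * C(f2, Sum)", data=data).fit()
    table = anova_lm(model, typ=3)
    out = table.rename(
        index={
            "C(f1, Sum)": names[0],
            "C(f2, Sum)": names[1],
            "C(f1, Sum):C(f2, Sum)": f"{names[0]}:{names[1]}",
            "Residual": "residual",
        }
    ).drop(index="Intercept")
    out = out.rename(columns={"F": "F", "PR(>F)": "p"})
    return out[["sum_sq", "df", "F", "p"]]


def mixed_anova_duration(correct_ms, incorrect_ms, condition) -> pd.DataFrame:
    """2 (condition, between) x 2 (window: correct/incorrect, within) mixed
    ANOVA on looking durations.

    With a two-level within factor the mixed ANOVA decomposes exactly into
    two between-subject analyses on per-participant summaries:

    * the **between** (condition) effect is the condition effect on the
      participant mean ``(correct + incorrect) / 2``;
    * the **within** (window) effect is the test of the grand (unweighted)
      mean of the difference ``correct - incorrect`` against zero;
    * the **interaction** is the condition effect on that difference;

    the latter two sharing the subject x window error term, which is the
    residual of the difference-score model.  F statistics are identical to
    the classical mixed-model decomposition, including for unbalanced
    designs (Type III, sum-to-zero contrasts).
    """
    c = np.asarray(correct_ms, dtype=float)
    i = np.asarray(incorrect_ms, dtype=float)
    cond = np.asarray(list(condition))
    if not (len(c) == len(i) == len(cond)):
        raise StatsError("correct, incorrect and condition must be equal length")
    ok = np.isfinite(c) & np.isfinite(i)
    c, i, cond = c[ok], i[ok], cond[ok]
    levels = sorted(pd.unique(cond).tolist())
    if len(levels) != 2:
        raise StatsError("condition must have exactly 2 observed levels")
    n_by = {lv: int((cond == lv).sum()) for lv in levels}
    if min(n_by.values()) < 2:
        raise StatsError("each condition needs >= 2 participants")

    half = (c + i) / 2.0  # between-subject component
    diff = (c - i) / 2.0  # within-subject component (sign carries window)

    def _type3_two_group(y: np.ndarray, g: np.ndarray) -> tuple[float, float, float, float]:
        """Intercept and group F tests from y ~ 1 + group (sum coding)."""
        x = np.where(g == levels[0], 1.0, -1.0)
        X = np.column_stack([np.ones_like(y), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dfe = len(y) - 2
        mse = float(resid @ resid) / dfe
        xtx_inv = np.linalg.inv(X.T @ X)
        f_int = beta[0] ** 2 / (mse * xtx_inv[0, 0])
        f_grp = beta[1] ** 2 / (mse * xtx_inv[1, 1])
        return float(f_int), float(f_grp), float(mse), float(dfe)

    # Within-level multiplicity: each participant contributes 2 observations,
    # so sums of squares on the per-participant summaries are scaled by 2 to
    # match the classical decomposition; F ratios are unaffected.
    f_between_int, f_between, mse_b, dfe = _type3_two_group(half, cond)
    f_within, f_interaction, mse_w, _ = _type3_two_group(diff, cond)

    def _p(fval: float) -> float:
        return float(sps.f.sf(fval, 1, dfe))

    rows = [
        ("condition", 1.0, dfe, f_between, _p(f_between)),
        ("window", 1.0, dfe, f_within, _p(f_within)),
        ("condition:window", 1.0, dfe, f_interaction, _p(f_interaction)),
    ]
    return pd.DataFrame(
        rows, columns=["effect", "df1", "df2", "F", "p"]
    ).set_index("effect")
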