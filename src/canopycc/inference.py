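"""Statistical surface: OLS correlation, balanced fixed-factor ANOVA with
partial eta-squared, and Tukey HSD post hoc comparisons.

The ANOVA models the color index as additive fixed effects of species,
season (growth stage) and treatment, with replicate as an additive blocking
factor; the design must be balanced, so sums of squares are unambiguous.
Partial eta-squared is SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


@dataclass(frozen=True)
class CorrelationResult:
    """OLS fit of y on x with the Pearson correlation test for the slope."""

    r2: float
    r: float
    p_value: float
    n: int
    slope: float
    intercept: float


@dataclass(frozen=True)
class TukeyComparison:
    level_a: str
    level_b: str
    mean_diff: float
    q_statistic: float
    p_adjusted: float


class ANOVATable:
    """Fixed-effect rows (df, MS, F, p, partial eta^2) plus the error row."""

    def __init__(self, frame: pd.DataFrame, error_df: int, error_ms: float):
        self.frame = frame
        self.error_df = error_df
        self.error_ms = error_ms

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ANOVATable(\n{self.summary()}\n)"

    def summary(self) -> str:
        rows = self.frame.copy()
        rows["p"] = [
            "<0.001" if p < 0.001 else f"{p:.3f}" for p in rows["p"]
        ]
        rows["MS"] = rows["MS"].map(lambda v: f"{v:.4g}")
        rows["F"] = rows["F"].map(lambda v: f"{v:.3f}")
        rows["partial_eta2"] = rows["partial_eta2"].map(lambda v: f"{v:.3f}")
        body = rows.to_string()
        return f"{body}\nError: df={self.error_df}, MS={self.error_ms:.4g}"


def linear_r2(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Least-squares line of y on x; r^2 and two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    if np.ptp(y) == 0:
        raise ValueError("y is constant: correlation undefined")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r2=float(fit.rvalue**2),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def _check_balance(frame: pd.DataFrame, factors: Sequence[str]) -> None:
    counts = frame.groupby(list(factors), observed=True).size()
    if counts.nunique() != 1:
        offenders = counts[counts != counts.mode().iloc[0]]
        raise ValueError(
            f"unbalanced design: unequal cell counts for factor cells:\n{offenders}"
        )
    expected_cells = int(np.prod([frame[f].nunique() for f in factors]))
    if len(counts) != expected_cells:
        raise ValueError(
            f"unbalanced design: {expected_cells - len(counts)} empty factor cells"
        )


def anova_table(
    long_table: pd.DataFrame,
    response: str = "value",
    factors: Sequence[str] = ("species", "season", "treatment"),
    block: str | None = "replicate",
) -> ANOVATable:
    """Main-effects ANOVA of ``response`` for the given fixed factors.

    ``block`` adds an additive blocking factor (not reported as an effect
    row).  Requires a balanced design with at least two observations per
    fixed-factor cell combination overall.
    """
    frame = long_table.copy()
    missing = [c for c in (*factors, response) if c not in frame.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    for f in factors:
        if frame[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than two levels")
    _check_balance(frame, factors)

    terms = [f"C({f})" for f in factors]
    if block is not None and block in frame.columns:
        terms.append(f"C({block})")
    formula = f"{response} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=frame).fit()
    table = anova_lm(fit, typ=1)

    ss_error = float(table.loc["Residual", "sum_sq"])
    df_error = int(table.loc["Residual", "df"])
    if df_error < 1:
        raise ValueError("no error degrees of freedom: add replicates")
    ms_error = ss_error / df_error
    scale = float(np.mean(np.square(frame[response]))) or 1.0
    if np.ptp(frame[response].to_numpy()) == 0 or ms_error <= 1e-14 * scale:
        raise ValueError("degenerate data: error mean square is zero")

    rows = []
    for f in factors:
        term = f"C({f})"
        ss = float(table.loc[term, "sum_sq"])
        df = int(table.loc[term, "df"])
        ms = ss / df
        fstat = ms / ms_error
        p = float(stats.f.sf(fstat, df, df_error))
        rows.append(
            {
                "source": f,
                "df": df,
                "MS": ms,
                "F": fstat,
                "p": p,
                "partial_eta2": ss / (ss + ss_error),
            }
        )
    out = pd.DataFrame(rows).set_index("source")
    return ANOVATable(out, error_df=df_error, error_ms=ms_error)


def tukey_hsd(
    groups: Mapping[str, Sequence[float]],
    *,
    df_error: int | None = None,
    ms_error: float | None = None,
) -> list[TukeyComparison]:
    """Studentized-range pairwise comparisons between group means.

    By default the error variance is pooled within groups (one-way ANOVA
    error); pass ``df_error``/``ms_error`` to reuse the error term of an
    accompanying factorial ANOVA.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    k = len(names)
    if ms_error is None or df_error is None:
        n_total = sum(a.size for a in arrays.values())
        ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
        df_error = n_total - k
        ms_error = ss_within / df_error
    if ms_error <= 0:
        raise ValueError("degenerate data: zero within-group variance")

    out = []
    for a, b in combinations(names, 2):
        xa, xb = arrays[a], arrays[b]
        diff = float(xa.mean() - xb.mean())
        se = np.sqrt(ms_error / 2.0 * (1.0 / xa.size + 1.0 / xb.size))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_error))
        out.append(
            TukeyComparison(
                level_a=a, level_b=b, mean_diff=diff, q_statistic=q,
                p_adjusted=min(1.0, p),
            )
        )
    return out
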