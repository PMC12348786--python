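"""Soil-water-content thresholds for maintaining a color-index criterion.

Fits a monotone dose-response of a color index to SWC — a four-parameter
logistic (lower asymptote, upper asymptote, midpoint, rate > 0) with an
isotonic-regression fallback — and inverts it at a stated criterion to find
the smallest SWC at which the fitted index reaches the criterion.
Uncertainty comes from a plot-level percentile bootstrap.

``SWCResponseModel`` / ``SWCResponseResults`` wrap the functional API in a
fit/results pair with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit


def logistic4(swc, lower, upper, mid, rate):
    """Non-decreasing logistic response of an index to SWC."""
    return lower + (upper - lower) * expit(rate * (np.asarray(swc, dtype=float) - mid))


@dataclass
class MonotoneFit:
    """A fitted non-decreasing index-vs-SWC curve."""

    family: str  # "logistic" or "isotonic"
    swc: np.ndarray
    index: np.ndarray
    params: dict[str, float] | None = None
    _iso_x: np.ndarray | None = field(default=None, repr=False)
    _iso_y: np.ndarray | None = field(default=None, repr=False)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.swc.min()), float(self.swc.max())

    def predict(self, swc) -> np.ndarray:
        swc = np.asarray(swc, dtype=float)
        if self.family == "logistic":
            p = self.params
            return logistic4(swc, p["lower"], p["upper"], p["mid"], p["rate"])
        return np.interp(swc, self._iso_x, self._iso_y)

    @property
    def upper_limit(self) -> float:
        if self.family == "logistic":
            return self.params["upper"]
        return float(self._iso_y[-1])


@dataclass(frozen=True)
class ThresholdEstimate:
    """SWC at which the fitted index first reaches the criterion, with CI."""

    criterion: float
    swc_star: float
    ci_low: float
    ci_high: float
    n_boot: int
    achievable: bool
    n_unachievable: int = 0
    reliable: bool = True
    fit_family: str = "logistic"


def _validate_pairs(swc, index) -> tuple[np.ndarray, np.ndarray]:
    swc = np.asarray(swc, dtype=float)
    index = np.asarray(index, dtype=float)
    if swc.shape != index.shape or swc.ndim != 1:
        raise ValueError("swc and index must be aligned 1-D arrays")
    if np.unique(swc).size < 5:
        raise ValueError("need at least 5 distinct SWC values")
    if np.ptp(index) < 1e-12:
        raise ValueError("index shows no spread across SWC: inversion is meaningless")
    return swc, index


def _fit_isotonic(swc: np.ndarray, index: np.ndarray) -> MonotoneFit:
    order = np.argsort(swc, kind="stable")
    x, y = swc[order], index[order]
    iso = optimize.isotonic_regression(y, increasing=True)
    # collapse tied x to their fitted value so interpolation is well defined
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.array([iso.x[inv == i].mean() for i in range(ux.size)])
    return MonotoneFit(
        family="isotonic", swc=swc, index=index, _iso_x=ux, _iso_y=np.maximum.accumulate(uy)
    )


def fit_index_response(
    swc: Sequence[float], index: Sequence[float], *, family: str = "logistic"
) -> MonotoneFit:
    """Least-squares monotone fit of index on SWC.

    ``family="logistic"`` fits the four-parameter logistic (monotone by the
    rate > 0 bound) and falls back to isotonic regression when the optimizer
    fails; ``family="isotonic"`` requests the fallback directly.
    """
    swc, index = _validate_pairs(swc, index)
    if family == "isotonic":
        return _fit_isotonic(swc, index)
    if family != "logistic":
        raise ValueError(f"unknown family {family!r}")

    lo, hi = float(index.min()), float(index.max())
    span0 = max(hi - lo, 1e-6)
    p0 = (lo, span0, float(np.median(swc)), 4.0 / max(np.ptp(swc), 1.0))
    # parameters: (lower, span>=0, mid, rate>0); upper = lower + span
    bounds = (
        [-0.5, 0.0, swc.min() - 100.0, 1e-4],
        [1.5, 2.0, swc.max() + 100.0, 10.0],
    )
    try:
        popt, _ = optimize.curve_fit(
            lambda x, lower, span, mid, rate: logistic4(x, lower, lower + span, mid, rate),
            swc,
            index,
            p0=p0,
            bounds=bounds,
            maxfev=20000,
            xtol=1e-12,
            ftol=1e-12,
        )
    except (RuntimeError, optimize.OptimizeWarning):
        return _fit_isotonic(swc, index)
    lower, span, mid, rate = (float(v) for v in popt)
    return MonotoneFit(
        family="logistic",
        swc=swc,
        index=index,
        params={"lower": lower, "upper": lower + span, "mid": mid, "rate": rate},
    )


def invert_criterion(fit: MonotoneFit, criterion: float) -> tuple[float, bool]:
    """Smallest SWC (within the fitted domain) where the curve reaches the criterion.

    Returns ``(swc_star, achievable)``.  A criterion at or above the curve's
    upper limit is unachievable (``swc_star`` is NaN); a criterion at or
    below the fitted value at the domain minimum returns the domain minimum.
    """
    dom_lo, dom_hi = fit.domain
    if fit.family == "logistic":
        p = fit.params
        if criterion >= p["upper"] or criterion > float(fit.predict(dom_hi)):
            return float("nan"), False
        if criterion <= p["lower"] or criterion <= float(fit.predict(dom_lo)):
            return dom_lo, True
        frac = (criterion - p["lower"]) / (p["upper"] - p["lower"])
        swc_star = p["mid"] + np.log(frac / (1.0 - frac)) / p["rate"]
        return float(np.clip(swc_star, dom_lo, dom_hi)), True
    # isotonic: bisect on the piecewise-linear interpolant
    if criterion > fit.upper_limit:
        return float("nan"), False
    if criterion <= float(fit.predict(dom_lo)):
        return dom_lo, True
    f = lambda x: float(fit.predict(x)) - criterion
    return float(optimize.bisect(f, dom_lo, dom_hi, xtol=1e-10)), True


def bootstrap_threshold_ci(
    swc: Sequence[float],
    index: Sequence[float],
    criterion: float,
    n_boot: int = 500,
    seed: int = 0,
    *,
    family: str = "logistic",
) -> ThresholdEstimate:
    """Plot-level percentile bootstrap of the criterion-crossing SWC."""
    swc, index = _validate_pairs(swc, index)
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    if swc.size < 8:
        raise ValueError("need at least 8 plots for a plot-level bootstrap")

    fit = fit_index_response(swc, index, family=family)
    swc_star, achievable = invert_criterion(fit, criterion)

    rng = np.random.default_rng(seed)
    stars = []
    n_unachievable = 0
    n = swc.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bs, bi = swc[idx], index[idx]
        try:
            bfit = fit_index_response(bs, bi, family=family)
        except ValueError:
            n_unachievable += 1
            continue
        star, ok = invert_criterion(bfit, criterion)
        if ok:
            stars.append(star)
        else:
            n_unachievable += 1
    reliable = n_unachievable <= n_boot // 2 and achievable
    if stars:
        ci_low, ci_high = np.percentile(stars, [2.5, 97.5])
    else:
        ci_low = ci_high = float("nan")
    return ThresholdEstimate(
        criterion=float(criterion),
        swc_star=float(swc_star),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        achievable=achievable,
        n_unachievable=n_unachievable,
        reliable=reliable,
        fit_family=fit.family,
    )


class SWCResponseModel:
    """Dose-response model of one color index against soil water content.

    Parameters
    ----------
    swc, index : 1-D arrays of per-plot (typically plot-stage mean) values.
    """

    def __init__(self, swc: Sequence[float], index: Sequence[float]):
        self.swc, self.index = _validate_pairs(swc, index)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, swc_col: str = "swc_percent", index_col: str = "g_cc"
    ) -> "SWCResponseModel":
        sub = frame[[swc_col, index_col]].dropna()
        return cls(sub[swc_col].to_numpy(), sub[index_col].to_numpy())

    def fit(self, family: str = "logistic") -> "SWCResponseResults":
        return SWCResponseResults(self, fit_index_response(self.swc, self.index, family=family))


class SWCResponseResults:
    """Fitted monotone response; thresholds and plots hang off this object."""

    def __init__(self, model: SWCResponseModel, fit: MonotoneFit):
        self.model = model
        self.fit_ = fit

    @property
    def family(self) -> str:
        return self.fit_.family

    @property
    def params(self) -> dict[str, float] | None:
        return self.fit_.params

    def predict(self, swc) -> np.ndarray:
        return self.fit_.predict(swc)

    def threshold(
        self, criterion: float, n_boot: int = 500, seed: int = 0
    ) -> ThresholdEstimate:
        return bootstrap_threshold_ci(
            self.model.swc, self.model.index, criterion, n_boot=n_boot, seed=seed,
            family="logistic" if self.family == "logistic" else "isotonic",
        )

    def summary(self, criterion: float | None = None) -> str:
        lines = [
            "SWC dose-response fit",
            f"  family:   {self.family}",
            f"  n plots:  {self.model.swc.size}",
            f"  SWC span: {self.fit_.domain[0]:.1f} - {self.fit_.domain[1]:.1f} %",
        ]
        if self.params:
            p = self.params
            lines += [
                f"  lower asymptote: {p['lower']:.4f}",
                f"  upper asymptote: {p['upper']:.4f}",
                f"  midpoint SWC:    {p['mid']:.2f} %",
                f"  rate:            {p['rate']:.4f} per % SWC",
            ]
        if criterion is not None:
            est = self.threshold(criterion)
            if est.achievable:
                lines.append(
                    f"  criterion {criterion:.3f} reached at SWC >= {est.swc_star:.1f} % "
                    f"(95% CI {est.ci_low:.1f} - {est.ci_high:.1f})"
                )
            else:
                lines.append(f"  criterion {criterion:.3f} not achievable under the fit")
        return "\n".join(lines)

    def plot(self, ax=None, criterion: float | None = None):
        """Scatter of the data with the fitted curve (and criterion line)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.swc, self.model.index, s=18, alpha=0.7, label="plots")
        grid = np.linspace(*self.fit_.domain, 200)
        ax.plot(grid, self.predict(grid), color="C1", label=f"{self.family} fit")
        if criterion is not None:
            ax.axhline(criterion, ls="--", color="C3", lw=1, label="criterion")
        ax.set_xlabel("soil water content (%)")
        ax.set_ylabel("color index")
        ax.legend()
        return ax
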