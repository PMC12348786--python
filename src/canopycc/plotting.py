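"""Quick-look plots for seasonal index series and response ratios."""

from __future__ import annotations

from typing import Sequence

from .indices import ColorTimeSeries
from .response import ResponseRatioSeries


def plot_seasonal_series(series: Sequence[ColorTimeSeries], ax=None):
    """Seasonal index trajectories, one line per series key."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for s in series:
        ax.plot(s.doy, s.values, marker="o", ms=3, label=" / ".join(map(str, s.key)))
    ax.set_xlabel("day of year")
    ax.set_ylabel(series[0].index_name if series else "index")
    ax.legend(fontsize=7)
    return ax


def plot_response_ratios(series: Sequence[ResponseRatioSeries], ax=None):
    """RR-vs-DOY curves with the zero line marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for s in series:
        ax.plot(s.doy, s.rr, marker="o", ms=3, label=" / ".join(map(str, s.key)))
    ax.axhline(0.0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("day of year")
    ax.set_ylabel("response ratio ln(treatment / control)")
    ax.legend(fontsize=7)
    return ax
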