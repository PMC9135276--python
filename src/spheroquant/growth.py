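"""Logistic growth fitting of confluency time courses.

Confluency (% of field area covered) from live-cell imaging is fitted with
the logistic function K / (1 + exp(−r (t − t0))); the doubling time is the
exponential-phase value ln(2)/r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

__all__ = ["LogisticGrowthModel", "GrowthResults", "fit_logistic_growth"]


def _logistic(t, K, r, t0):
    return K / (1.0 + np.exp(-r * (t - t0)))


class LogisticGrowthModel:
    """Logistic model for a confluency time course.

    Parameters
    ----------
    times : array-like, hours
    confluency : array-like, percent (0–100)

    Needs at least 6 time points spanning the inflection for a stable fit.
    """

    def __init__(self, times, confluency):
        t = np.asarray(times, dtype=float)
        y = np.asarray(confluency, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times and confluency must have the same length")
        if len(t) < 6:
            raise ValueError("need >= 6 time points for a logistic fit")
        order = np.argsort(t)
        self.times = t[order]
        self.confluency = y[order]

    def fit(self, xtol: float = 1e-8, maxfev: int = 10000) -> "GrowthResults":
        t, y = self.times, self.confluency
        if np.ptp(y) < 1e-6:
            return GrowthResults(self, np.nan, np.nan, np.nan, {}, False,
                                 "constant confluency: nothing to fit")
        rho = spearmanr(t, y).statistic
        if rho <= 0:
            return GrowthResults(self, np.nan, np.nan, np.nan, {}, False,
                                 "non-increasing confluency series")
        K0 = float(min(max(y.max(), 1e-3), 100.0))
        t0_0 = float(t[np.argmin(np.abs(y - K0 / 2.0))])
        # crude rate guess from the central rise
        span = t.max() - t.min()
        r0 = 4.0 / span if span > 0 else 0.1
        try:
            popt, pcov = curve_fit(
                _logistic, t, y, p0=[K0, r0, t0_0],
                bounds=([1e-6, 1e-9, -np.inf], [100.0, np.inf, np.inf]),
                xtol=xtol, maxfev=maxfev,
            )
        except RuntimeError as err:
            return GrowthResults(self, np.nan, np.nan, np.nan, {}, False,
                                 f"fit did not converge: {err}")
        K, r, t0 = (float(v) for v in popt)
        perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
        return GrowthResults(
            self, K, r, t0,
            {"K": perr[0], "r": perr[1], "t0": perr[2]},
            True, "converged",
        )


@dataclass
class GrowthResults:
    model: LogisticGrowthModel
    K: float  # carrying capacity, % confluency
    r: float  # rate, per hour
    t0: float  # inflection time, hours
    bse: dict
    converged: bool
    message: str = ""

    @property
    def doubling_time(self) -> float:
        """Exponential-phase doubling time ln(2)/r in hours."""
        if not self.converged or self.r <= 0:
            return float("nan")
        return math.log(2.0) / self.r

    @property
    def fittedvalues(self) -> np.ndarray:
        if not self.converged:
            return np.full_like(self.model.confluency, np.nan)
        return _logistic(self.model.times, self.K, self.r, self.t0)

    @property
    def resid(self) -> np.ndarray:
        return self.model.confluency - self.fittedvalues

    def plot(self, ax=None):
        """Confluency data and fitted logistic curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.times, self.model.confluency, "o", ms=3, label="data")
        if self.converged:
            grid = np.linspace(self.model.times.min(), self.model.times.max(), 200)
            ax.plot(grid, _logistic(grid, self.K, self.r, self.t0), "-", label="fit")
        ax.set_xlabel("time [h]")
        ax.set_ylabel("confluency [%]")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "Logistic growth fit",
            "=" * 40,
            f"converged:      {self.converged} ({self.message})",
            f"n time points:  {len(self.model.times)}",
        ]
        if self.converged:
            lines += [
                f"K [% confl.]:   {self.K:.2f}",
                f"r [per hour]:   {self.r:.5f}",
                f"t0 [hours]:     {self.t0:.2f}",
                f"doubling time:  {self.doubling_time:.2f} h",
            ]
        return "\n".join(lines)


def fit_logistic_growth(times, confluency) -> GrowthResults:
    """Convenience wrapper: build the model and fit in one call."""
    return LogisticGrowthModel(times, confluency).fit()
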