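"""Plate-level viability normalization and three-parameter dose-response
fitting.

The MTT readout is a pair of absorbances per well (560 nm signal, 690 nm
reference); net absorbance is A560 − A690 minus the mean blank net, and
viability is the net normalized to the untreated wells of the same
experimental replicate.  Dose-response curves use the conventional
three-parameter inhibition model with the Hill slope fixed at 1,

    V(c) = bottom + (top − bottom) / (1 + c / IC50),

fitted by least squares in log-dose space with IC50 parameterized as
log(IC50) for conditioning.  One curve is fitted per experimental
replicate; replicate IC50s are summarized as mean ± SEM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseDataset",
    "DoseResponseModel",
    "DoseResponseResults",
    "ReplicateDoseResponse",
    "normalize_mtt",
    "normalize_cytotox",
    "fit_dose_response",
    "fold_resistance",
]

# response range below which a dataset is treated as flat (no dose effect)
_FLAT_TOL = 1e-6


@dataclass
class DoseResponseDataset:
    """Normalized viabilities on a dose grid, one row per (dose, replicate).

    ``data`` columns: dose_M (strictly positive), replicate (experimental
    replicate id), viability (untreated ≈ 1).  Technical replicates are
    expected to be averaged already (see :func:`normalize_mtt`).
    """

    condition: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"dose_M", "replicate", "viability"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        if (self.data["dose_M"] <= 0).any():
            raise ValueError("doses must be strictly positive")
        if not np.isfinite(self.data["viability"]).all():
            raise ValueError("viabilities must be finite")
        if self.data["dose_M"].nunique() < 4:
            raise ValueError("need >= 4 distinct doses to fit a dose-response curve")

    @property
    def doses(self) -> np.ndarray:
        return np.sort(self.data["dose_M"].unique())

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique())


def normalize_mtt(
    raw: pd.DataFrame,
    untreated_label: str = "untreated",
    blank_label: str = "blank",
) -> dict[str, DoseResponseDataset]:
    """Normalize raw MTT absorbances into per-condition viability datasets.

    ``raw`` columns: well, condition, dose_M, replicate, a560, a690.  Wells
    whose condition equals ``blank_label`` are media-only blanks; wells whose
    condition equals ``untreated_label`` are the untreated controls of their
    experimental replicate.  For every well net = a560 − a690 − mean blank
    net; viability = net / (mean untreated net of the same replicate);
    technical replicates (same condition, dose and replicate) are then
    averaged.

    Returns one :class:`DoseResponseDataset` per treated condition.

    Raises
    ------
    ValueError
        If untreated wells are absent or their mean net absorbance is <= 0.
    """
    required = {"well", "condition", "dose_M", "replicate", "a560", "a690"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw MTT table missing columns: {sorted(missing)}")
    df = raw.copy()
    df["net"] = df["a560"] - df["a690"]

    blanks = df[df["condition"] == blank_label]
    blank_net = blanks["net"].mean() if len(blanks) else 0.0
    df["net"] = df["net"] - blank_net

    untreated = df[df["condition"] == untreated_label]
    if untreated.empty:
        raise ValueError(f"no untreated wells (condition == {untreated_label!r})")
    untreated_mean = untreated.groupby("replicate")["net"].mean()
    if (untreated_mean <= 0).any():
        bad = list(untreated_mean.index[untreated_mean <= 0])
        raise ValueError(f"mean untreated net absorbance <= 0 in replicates {bad}")

    treated = df[~df["condition"].isin([untreated_label, blank_label])].copy()
    treated["viability"] = treated["net"] / treated["replicate"].map(untreated_mean)
    if treated["viability"].isna().any():
        bad = sorted(treated.loc[treated["viability"].isna(), "replicate"].unique())
        raise ValueError(f"replicates {bad} have no untreated wells")

    out: dict[str, DoseResponseDataset] = {}
    for cond, grp in treated.groupby("condition"):
        tech_avg = (
            grp.groupby(["dose_M", "replicate"], as_index=False)["viability"].mean()
        )
        out[str(cond)] = DoseResponseDataset(condition=str(cond), data=tech_avg)
    return out


def normalize_cytotox(
    table: pd.DataFrame,
    untreated_label: str = "untreated",
) -> pd.DataFrame:
    """Relative death per dose from red-object area and matched viability.

    ``table`` columns: well, condition, dose_M, area, viability — area being
    the cytotoxicity-dye-positive area of the well and viability the matched
    metabolic readout of the same condition.  Death per well is
    area / viability, then normalized to the mean of the same quantity over
    the untreated wells.  Wells with viability <= 0 are excluded with a
    warning.
    """
    required = {"well", "condition", "dose_M", "area", "viability"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cytotoxicity table missing columns: {sorted(missing)}")
    df = table.copy()
    bad = df["viability"] <= 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} wells with viability <= 0: "
            f"{sorted(df.loc[bad, 'well'])}",
            stacklevel=2,
        )
        df = df[~bad]
    df["death"] = df["area"] / df["viability"]
    controls = df[df["condition"] == untreated_label]
    if controls.empty:
        raise ValueError(f"no untreated wells (condition == {untreated_label!r})")
    ctrl = controls["death"].mean()
    if ctrl <= 0:
        raise ValueError("untreated control death signal is <= 0")
    df["relative_death"] = df["death"] / ctrl
    return df[["well", "condition", "dose_M", "relative_death"]].reset_index(drop=True)


def _model(log_dose: np.ndarray, top: float, bottom: float, log_ic50: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + np.exp(log_dose - log_ic50))


class DoseResponseModel:
    """Three-parameter inhibition model for one viability curve.

    Parameters
    ----------
    dose : array-like
        Strictly positive molar doses.
    viability : array-like
        Normalized responses (untreated ≈ 1), same length as ``dose``.

    ``fit()`` returns a :class:`DoseResponseResults`.
    """

    def __init__(self, dose, viability):
        dose = np.asarray(dose, dtype=float)
        viability = np.asarray(viability, dtype=float)
        if dose.shape != viability.shape:
            raise ValueError("dose and viability must have the same length")
        if (dose <= 0).any():
            raise ValueError("doses must be strictly positive")
        if not np.isfinite(viability).all():
            raise ValueError("viabilities must be finite")
        order = np.argsort(dose)
        self.dose = dose[order]
        self.viability = viability[order]

    @classmethod
    def from_dataset(cls, ds: DoseResponseDataset, replicate) -> "DoseResponseModel":
        sub = ds.data[ds.data["replicate"] == replicate]
        return cls(sub["dose_M"].to_numpy(), sub["viability"].to_numpy())

    def fit(self, xtol: float = 1e-8, maxfev: int = 10000) -> "DoseResponseResults":
        y = self.viability
        x = np.log(self.dose)
        if np.ptp(y) < _FLAT_TOL:
            return DoseResponseResults(
                model=self, top=float(y.mean()), bottom=float(y.mean()),
                ic50=None, bse={}, converged=False,
                message="flat response: no dose effect to fit",
            )
        # init: top/bottom from response extremes, IC50 at the dose nearest
        # the half-range crossing
        top0, bot0 = float(y.max()), float(y.min())
        half = (top0 + bot0) / 2.0
        p0 = [top0, bot0, float(x[np.argmin(np.abs(y - half))])]
        try:
            popt, pcov = curve_fit(
                _model, x, y, p0=p0, xtol=xtol, maxfev=maxfev,
            )
        except RuntimeError as err:
            return DoseResponseResults(
                model=self, top=np.nan, bottom=np.nan, ic50=None, bse={},
                converged=False, message=f"fit did not converge: {err}",
            )
        top, bottom, log_ic50 = popt
        if bottom > top:  # enforce the inhibition orientation
            top, bottom = bottom, top
        perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
        ic50 = float(np.exp(log_ic50))
        return DoseResponseResults(
            model=self, top=float(top), bottom=float(bottom), ic50=ic50,
            bse={"top": perr[0], "bottom": perr[1], "log_ic50": perr[2]},
            converged=True, message="converged",
        )


@dataclass
class DoseResponseResults:
    """Fitted three-parameter curve: top, bottom and IC50 with diagnostics."""

    model: DoseResponseModel
    top: float
    bottom: float
    ic50: float | None
    bse: dict[str, float]
    converged: bool
    message: str = ""

    @property
    def extrapolated(self) -> bool:
        """True when the fitted IC50 lies outside the tested dose range."""
        if self.ic50 is None:
            return False
        return not (self.model.dose.min() <= self.ic50 <= self.model.dose.max())

    @property
    def fittedvalues(self) -> np.ndarray:
        if self.ic50 is None:
            return np.full_like(self.model.viability, np.nan)
        return _model(np.log(self.model.dose), self.top, self.bottom, math.log(self.ic50))

    @property
    def resid(self) -> np.ndarray:
        return self.model.viability - self.fittedvalues

    @property
    def rss(self) -> float:
        return float(np.nansum(self.resid**2))

    def predict(self, dose) -> np.ndarray:
        if self.ic50 is None:
            raise ValueError("cannot predict from a non-converged fit")
        return _model(np.log(np.asarray(dose, dtype=float)), self.top, self.bottom,
                      math.log(self.ic50))

    def plot(self, ax=None):
        """Data and fitted curve on a log-dose axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(self.model.dose, self.model.viability, "o", label="data")
        if self.ic50 is not None:
            grid = np.geomspace(self.model.dose.min(), self.model.dose.max(), 200)
            ax.semilogx(grid, self.predict(grid), "-", label="fit")
            ax.axvline(self.ic50, ls="--", color="gray", lw=0.8)
        ax.set_xlabel("dose [M]")
        ax.set_ylabel("viability")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "Three-parameter dose-response fit",
            "=" * 40,
            f"converged:     {self.converged} ({self.message})",
            f"n doses:       {len(self.model.dose)}",
            f"top:           {self.top:.4f}",
            f"bottom:        {self.bottom:.4f}",
        ]
        if self.ic50 is not None:
            flag = "  [extrapolated]" if self.extrapolated else ""
            lines.append(f"IC50 [M]:      {self.ic50:.4g}{flag}")
            lines.append(f"RSS:           {self.rss:.4g}")
        return "\n".join(lines)


@dataclass
class ReplicateDoseResponse:
    """Per-experimental-replicate fits and their IC50 summary."""

    condition: str
    fits: dict = field(default_factory=dict)  # replicate id -> DoseResponseResults

    @property
    def ic50s(self) -> np.ndarray:
        return np.array(
            [f.ic50 for f in self.fits.values() if f.converged and f.ic50 is not None]
        )

    @property
    def ic50_mean(self) -> float:
        vals = self.ic50s
        return float(vals.mean()) if len(vals) else float("nan")

    @property
    def ic50_sem(self) -> float:
        vals = self.ic50s
        if len(vals) < 2:
            return float("nan")
        return float(vals.std(ddof=1) / math.sqrt(len(vals)))

    def summary(self) -> str:
        lines = [
            f"Dose-response summary — {self.condition}",
            "=" * 40,
            f"replicates fitted: {len(self.fits)} "
            f"(converged: {len(self.ic50s)})",
            f"IC50 mean [M]:     {self.ic50_mean:.4g}",
            f"IC50 SEM  [M]:     {self.ic50_sem:.4g}",
        ]
        return "\n".join(lines)


def fit_dose_response(ds: DoseResponseDataset) -> ReplicateDoseResponse:
    """Fit the three-parameter curve to each experimental replicate.

    Replicates that fail to converge (flat response, optimizer failure) are
    kept with their flag but contribute no IC50 to the summary.
    """
    out = ReplicateDoseResponse(condition=ds.condition)
    for rep in ds.replicates:
        out.fits[rep] = DoseResponseModel.from_dataset(ds, rep).fit()
    return out


def fold_resistance(ic50_query: float, ic50_reference: float) -> float:
    """IC50 ratio of a query condition over a reference (fold change).

    E.g. a resistant subclone at 3000 nM against a parental line at 10 nM
    gives 300.
    """
    if ic50_query <= 0 or ic50_reference <= 0:
        raise ValueError("IC50 values must be positive")
    return ic50_query / ic50_reference
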