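"""Chemoprotection quantification for mixed cultures.

A resistant subpopulation can shield a drug-sensitive one when the two are
co-cultured (most strikingly when the resistant cells sort to the spheroid
shell).  Protection is quantified by comparing the observed co-culture
viability to the expectation under independence: the ratio-weighted linear
combination of the mono-culture viabilities,

    E[V] = Σ wᵢ Vᵢ / Σ wᵢ      (e.g. 3:1 ->  (3 V_a + V_b) / 4)

and the chemoprotection coefficient C_O/E = observed / expected.  C_O/E = 1
means the populations respond as they do alone; C_O/E > 1 indicates
population-level protection of the sensitive component.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MixtureRatio",
    "ProtectionProfile",
    "expected_viability",
    "protection_coefficient",
    "protection_profile",
]

# below this expected viability the O/E ratio is noise-dominated
_UNSTABLE_EXPECTED = 0.02


@dataclass
class MixtureRatio:
    """Seeding ratio of the co-cultured components, e.g. 3:1."""

    labels: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.weights):
            raise ValueError("labels and weights must have the same length")
        if any(w <= 0 for w in self.weights):
            raise ValueError("mixture weights must be positive")

    @property
    def normalized(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()


def expected_viability(component_viabilities, ratio: MixtureRatio) -> float:
    """Ratio-weighted mean of mono-culture viabilities at one dose."""
    v = np.asarray(component_viabilities, dtype=float)
    if v.shape != (len(ratio.weights),):
        raise ValueError(
            f"{len(v)} viabilities for {len(ratio.weights)} mixture components"
        )
    return float(np.dot(ratio.normalized, v))


def protection_coefficient(observed: float, expected: float) -> float:
    """Observed / expected viability; NaN with a warning if expected <= 0."""
    if expected <= 0:
        warnings.warn(
            f"expected viability {expected} <= 0: protection coefficient undefined",
            stacklevel=2,
        )
        return float("nan")
    return observed / expected


@dataclass
class ProtectionProfile:
    """Per-dose observed, expected and C_O/E values for one mixed culture.

    ``table`` columns: dose_M, observed, observed_sem, expected,
    expected_sem, c_oe, c_oe_sem, unstable (True where expected falls below
    2% of the untreated signal and the ratio is noise-dominated).
    """

    table: pd.DataFrame
    ratio: MixtureRatio
    context: str = "2D"  # "2D" | "spheroid"

    @property
    def c_oe(self) -> np.ndarray:
        return self.table["c_oe"].to_numpy()

    @property
    def doses(self) -> np.ndarray:
        return self.table["dose_M"].to_numpy()

    def summary(self) -> str:
        lines = [
            f"Chemoprotection profile ({self.context}, "
            f"ratio {':'.join(str(w) for w in self.ratio.weights)})",
            "=" * 56,
            f"{'dose [M]':>12} {'observed':>9} {'expected':>9} {'C_O/E':>7}",
        ]
        for _, row in self.table.iterrows():
            flag = " *" if row["unstable"] else ""
            lines.append(
                f"{row['dose_M']:>12.3g} {row['observed']:>9.3f} "
                f"{row['expected']:>9.3f} {row['c_oe']:>7.3f}{flag}"
            )
        if self.table["unstable"].any():
            lines.append("* expected viability < 2% of control: ratio unstable")
        return "\n".join(lines)


def _dose_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM of value per dose over replicates."""
    g = table.groupby("dose_M")["value"]
    out = g.agg(mean="mean", n="count", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.reset_index()


def protection_profile(
    mono_tables: dict[str, pd.DataFrame],
    co_table: pd.DataFrame,
    ratio: MixtureRatio,
    context: str = "2D",
) -> ProtectionProfile:
    """Build the per-dose protection profile from viability tables.

    ``mono_tables`` maps each component label in ``ratio.labels`` to its
    mono-culture long-format table (columns dose_M, replicate, value);
    ``co_table`` is the co-culture table on the same dose grid.  Expected
    viability per dose is computed from the mono-culture means; the
    observed/expected ratio is summarized with a first-order delta-method
    SEM from the observed and expected SEMs.

    Raises
    ------
    ValueError
        If a component table is missing or the dose grids disagree (the
        message lists the mismatching doses).
    """
    missing = [lab for lab in ratio.labels if lab not in mono_tables]
    if missing:
        raise ValueError(f"mono-culture tables missing for components {missing}")

    co_stats = _dose_stats(co_table)
    co_doses = set(np.round(np.log10(co_stats["dose_M"]), 9))
    mono_stats = {}
    for lab in ratio.labels:
        st = _dose_stats(mono_tables[lab])
        doses = set(np.round(np.log10(st["dose_M"]), 9))
        if doses != co_doses:
            only_mono = sorted(10.0**d for d in doses - co_doses)
            only_co = sorted(10.0**d for d in co_doses - doses)
            raise ValueError(
                f"dose grids disagree for component {lab!r}: "
                f"only in mono-culture {only_mono}, only in co-culture {only_co}"
            )
        mono_stats[lab] = st.set_index("dose_M")

    w = ratio.normalized
    rows = []
    for _, co_row in co_stats.sort_values("dose_M").iterrows():
        dose = co_row["dose_M"]
        comp_means = np.array([mono_stats[lab].loc[dose, "mean"] for lab in ratio.labels])
        comp_sems = np.array([mono_stats[lab].loc[dose, "sem"] for lab in ratio.labels])
        expected = float(np.dot(w, comp_means))
        expected_sem = float(math.sqrt(np.sum((w * comp_sems) ** 2)))
        observed = float(co_row["mean"])
        observed_sem = float(co_row["sem"])
        c_oe = protection_coefficient(observed, expected)
        if np.isfinite(c_oe) and expected > 0:
            # delta method: var(O/E) ≈ var(O)/E² + O² var(E)/E⁴
            c_sem = math.sqrt(
                (observed_sem / expected) ** 2
                + (observed * expected_sem / expected**2) ** 2
            )
        else:
            c_sem = float("nan")
        rows.append(
            {
                "dose_M": dose,
                "observed": observed,
                "observed_sem": observed_sem,
                "expected": expected,
                "expected_sem": expected_sem,
                "c_oe": c_oe,
                "c_oe_sem": c_sem,
                "unstable": expected < _UNSTABLE_EXPECTED,
            }
        )
    return ProtectionProfile(table=pd.DataFrame(rows), ratio=ratio, context=context)
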