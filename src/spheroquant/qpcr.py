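"""Ct-based copy-number and relative-expression arithmetic, plus
loading-normalized densitometry.

The copy-number chain assumes exact two-fold amplification per cycle:
ΔCt = Ct_target − Ct_reference_gene, n_rel = 2^−ΔCt, and the absolute copy
number is anchored to a diploid control sample,
n_abs = (n_rel / n_rel_diploid) × 2, so the control itself is assigned
exactly 2 copies.  Relative expression uses the standard ΔΔCt method
against a housekeeping gene and a calibrator sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "CopyNumberResult",
    "cnv_from_ct",
    "ddct_expression",
    "densitometry_abundance",
]


@dataclass
class CtTable:
    """Replicate qPCR cycle-threshold values.

    ``data`` holds long-format rows (sample, gene, replicate, ct);
    ``target_gene`` and ``reference_gene`` designate the assayed locus and
    the internal-reference locus.
    """

    data: pd.DataFrame
    target_gene: str
    reference_gene: str

    def __post_init__(self) -> None:
        required = {"sample", "gene", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns: {sorted(missing)}")
        ct = self.data["ct"]
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValueError("Ct values must be finite and > 0")

    def mean_ct(self) -> pd.DataFrame:
        """Average technical replicates to one Ct per (sample, gene)."""
        return (
            self.data.groupby(["sample", "gene"], as_index=False)["ct"]
            .mean()
            .rename(columns={"ct": "ct_mean"})
        )


@dataclass
class CopyNumberResult:
    """Per-sample ΔCt, relative and absolute copy numbers."""

    table: pd.DataFrame  # sample, delta_ct, n_rel, n_abs
    diploid_reference_sample: str

    def n_abs(self, sample: str) -> float:
        row = self.table.loc[self.table["sample"] == sample]
        if row.empty:
            raise KeyError(f"sample {sample!r} not in result")
        return float(row["n_abs"].iloc[0])


def cnv_from_ct(table: CtTable, diploid_reference_sample: str) -> CopyNumberResult:
    """Copy numbers from a Ct table via the ΔCt / 2^−ΔCt chain.

    Technical replicates are combined by arithmetic mean of Ct.  For each
    sample, ΔCt = mean Ct(target) − mean Ct(reference gene),
    n_rel = 2^−ΔCt, and n_abs = n_rel / n_rel(diploid reference) × 2.

    Raises
    ------
    ValueError
        If the target or reference gene is missing for any sample, or the
        diploid reference sample is absent.
    """
    means = table.mean_ct().pivot(index="sample", columns="gene", values="ct_mean")
    for gene in (table.target_gene, table.reference_gene):
        if gene not in means.columns or means[gene].isna().any():
            bad = (
                list(means.index[means[gene].isna()])
                if gene in means.columns
                else list(means.index)
            )
            raise ValueError(f"gene {gene!r} missing for samples {bad}")
    if diploid_reference_sample not in means.index:
        raise ValueError(
            f"diploid reference sample {diploid_reference_sample!r} not in table"
        )

    delta_ct = means[table.target_gene] - means[table.reference_gene]
    n_rel = np.power(2.0, -delta_ct)
    n_abs = n_rel / n_rel.loc[diploid_reference_sample] * 2.0
    out = pd.DataFrame(
        {
            "sample": means.index,
            "delta_ct": delta_ct.values,
            "n_rel": n_rel.values,
            "n_abs": n_abs.values,
        }
    ).reset_index(drop=True)
    return CopyNumberResult(table=out, diploid_reference_sample=diploid_reference_sample)


def ddct_expression(
    table: CtTable, housekeeping_gene: str, calibrator_sample: str
) -> pd.DataFrame:
    """Relative expression per sample by the ΔΔCt method.

    fold = 2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_housekeeping)_sample −
    (Ct_target − Ct_housekeeping)_calibrator.  The calibrator's fold change
    is identically 1.
    """
    means = table.mean_ct().pivot(index="sample", columns="gene", values="ct_mean")
    for gene in (table.target_gene, housekeeping_gene):
        if gene not in means.columns or means[gene].isna().any():
            raise ValueError(f"gene {gene!r} missing for some samples")
    if calibrator_sample not in means.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")
    dct = means[table.target_gene] - means[housekeeping_gene]
    ddct = dct - dct.loc[calibrator_sample]
    return pd.DataFrame(
        {"sample": means.index, "ddct": ddct.values, "fold": np.power(2.0, -ddct.values)}
    ).reset_index(drop=True)


def densitometry_abundance(
    band_intensities: dict[str, float],
    protein_loaded_ug: dict[str, float],
    control_sample: str,
) -> pd.DataFrame:
    """Loading-normalized band abundance relative to a control lane.

    abundance = (intensity / load) / (intensity_control / load_control).
    Lanes may carry different protein loads (down to sub-μg amounts for
    strongly overexpressing samples); dividing by load before normalizing
    to the control makes the values comparable.
    """
    if control_sample not in band_intensities:
        raise ValueError(f"control sample {control_sample!r} has no band intensity")
    for s, load in protein_loaded_ug.items():
        if load <= 0:
            raise ValueError(f"protein load for {s!r} must be positive, got {load}")
    missing = set(band_intensities) - set(protein_loaded_ug)
    if missing:
        raise ValueError(f"no protein load given for samples {sorted(missing)}")
    per_load = {s: band_intensities[s] / protein_loaded_ug[s] for s in band_intensities}
    ctrl = per_load[control_sample]
    if ctrl <= 0:
        warnings.warn("control lane has zero normalized intensity", stacklevel=2)
    rows = [
        {"sample": s, "relative_abundance": v / ctrl} for s, v in per_load.items()
    ]
    return pd.DataFrame(rows)
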