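"""Collective-invasion quantification for spheroids embedded in collagen.

The readout is the distance from the spheroid center to the ends of the
three longest continuous labeled invasive cell sheets, normalized to the
starting spheroid diameter.  A sheet is an above-threshold connected
component of the label channel, outside the initial (t=0) spheroid
footprint and in contact with its boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .image import MultiChannelImage
from .spheroid import SpheroidMask

__all__ = ["MigrationMeasurement", "identify_invasive_sheets", "migration_distance",
           "migration_analysis"]

MIN_SHEET_AREA = 50  # px², smaller components are debris
TOP_K = 3


@dataclass
class MigrationMeasurement:
    """Top-k mean normalized invasion distance for one spheroid."""

    center: tuple[float, float]
    starting_diameter_px: float
    sheet_distances_px: tuple[float, ...]  # sorted descending, all sheets
    mean_normalized_distance: float
    n_sheets: int
    flags: tuple[str, ...] = ()


def identify_invasive_sheets(
    label_channel: np.ndarray,
    initial_mask: np.ndarray,
    min_area: int = MIN_SHEET_AREA,
    boundary_dilation_px: int = 3,
    threshold: float | None = None,
) -> np.ndarray:
    """Label the continuous invasive sheets emanating from the spheroid.

    The label channel is thresholded (Otsu unless ``threshold`` is given);
    signal inside the initial spheroid footprint is removed, and connected
    components that touch the dilated footprint boundary and exceed
    ``min_area`` are kept.  Returns a labeled raster (0 = background); an
    image without labeled signal yields an all-zero raster, not an error.
    """
    if threshold is None:
        if np.ptp(label_channel) == 0:
            return np.zeros_like(label_channel, dtype=np.int32)
        threshold = threshold_otsu(label_channel)
    fg = label_channel > threshold
    fg = fg & ~initial_mask
    if not fg.any():
        return np.zeros_like(label_channel, dtype=np.int32)
    ring = (
        ndimage.distance_transform_edt(~initial_mask) <= boundary_dilation_px
    ) & ~initial_mask
    comps = cc_label(fg)
    touching = set(np.unique(comps[ring])) - {0}
    out = np.zeros_like(comps, dtype=np.int32)
    next_id = 1
    for lab in sorted(touching):
        m = comps == lab
        if m.sum() < min_area:
            continue
        out[m] = next_id
        next_id += 1
    return out


def migration_distance(
    sheets: np.ndarray,
    center: tuple[float, float],
    starting_diameter: float,
    top_k: int = TOP_K,
) -> MigrationMeasurement:
    """Mean of the top-k sheet end distances, normalized to the diameter.

    Per sheet the end distance is the maximum Euclidean distance from the
    spheroid center over the sheet's pixels.  Ties between sheets are broken
    by component area (larger first) then by label order.  With fewer than
    ``top_k`` sheets the available ones are averaged and the measurement is
    flagged; with none, the statistic falls back to the center-to-boundary
    floor of 0.5 and is flagged ``no invasion``.
    """
    if starting_diameter <= 0:
        raise ValueError("starting diameter must be positive")
    cx, cy = center
    per_sheet: list[tuple[float, int, int]] = []  # (distance, area, label)
    for prop in regionprops(sheets):
        ys, xs = prop.coords[:, 0], prop.coords[:, 1]
        d = float(np.max(np.hypot(xs - cx, ys - cy)))
        per_sheet.append((d, int(prop.area), int(prop.label)))
    per_sheet.sort(key=lambda t: (-t[0], -t[1], t[2]))
    distances = tuple(d for d, _, _ in per_sheet)

    flags: list[str] = []
    if not distances:
        return MigrationMeasurement(
            center=center,
            starting_diameter_px=starting_diameter,
            sheet_distances_px=(),
            mean_normalized_distance=0.5,
            n_sheets=0,
            flags=("no invasion",),
        )
    top = distances[:top_k]
    if len(top) < top_k:
        flags.append(f"k<{top_k}")
    return MigrationMeasurement(
        center=center,
        starting_diameter_px=starting_diameter,
        sheet_distances_px=distances,
        mean_normalized_distance=float(np.mean(top) / starting_diameter),
        n_sheets=len(distances),
        flags=tuple(flags),
    )


def migration_analysis(
    img: MultiChannelImage,
    initial_mask: SpheroidMask | np.ndarray,
    label_channel: str = "CTG",
    top_k: int = TOP_K,
    min_area: int = MIN_SHEET_AREA,
) -> MigrationMeasurement:
    """Sheet identification plus distance measurement for one spheroid.

    The starting diameter is twice the equivalent radius of the t=0 mask
    and the center is its centroid.
    """
    if isinstance(initial_mask, SpheroidMask):
        mask = initial_mask.mask
        center = initial_mask.centroid
        diameter = 2.0 * initial_mask.equivalent_radius_px
    else:
        mask = np.asarray(initial_mask, dtype=bool)
        ys, xs = np.nonzero(mask)
        center = (float(xs.mean()), float(ys.mean()))
        diameter = 2.0 * float(np.sqrt(mask.sum() / np.pi))
    sheets = identify_invasive_sheets(
        img[label_channel], mask, min_area=min_area
    )
    return migration_distance(sheets, center, diameter, top_k=top_k)
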