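"""Spheroid detection, radial intensity profiling and the cell-sorting
statistic.

The sorting readout works on co-culture spheroids in which one population
carries a cytoplasmic tracker dye.  For each spheroid the mean tracker
intensity is computed in concentric 1-px annuli around the spheroid center;
the spheroid radius is defined as the distance enclosing 95% of the total
tracker intensity; profiles are rescaled to normalized distance (0 =
center, 1 = that radius), averaged across spheroids of the same type,
normalized so the center intensity is 1, and the shell enrichment is read
off at normalized distance 0.77.  A ratio of 1 means the labeled population
is well mixed; ratios above 1 indicate enrichment of the labeled cells in
the spheroid shell.

Spheroid death under drug is scored as the integrated dead-cell-stain (PI)
intensity over the spheroid area, normalized to untreated control wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label

from .image import MultiChannelImage

__all__ = [
    "SpheroidMask",
    "RadialProfile",
    "SortingStatistic",
    "detect_spheroid_mask",
    "radial_profile",
    "radius_enclosing_fraction",
    "subtract_background",
    "normalize_profile",
    "sorting_statistic",
    "sorting_analysis",
    "integrated_intensity",
    "pi_death_score",
]

#: fraction of total intensity defining the spheroid radius
ENCLOSURE_FRACTION = 0.95
#: normalized distance at which shell (edge) intensity is read
EDGE_POSITION = 0.77
#: inner fraction of the spheroid radius averaged for the center estimate
CENTER_FRACTION = 0.05
#: common grid for normalized profiles: 100 bins on [0, 1.2]
NORMALIZED_GRID = np.linspace(0.0, 1.2, 100)


@dataclass
class SpheroidMask:
    """Binary spheroid footprint with centroid and size."""

    mask: np.ndarray  # bool raster
    centroid: tuple[float, float]  # (x, y), intensity-weighted
    area_px: int
    equivalent_radius_px: float


@dataclass
class RadialProfile:
    """Mean intensity per concentric annulus.

    ``edges`` are annulus boundaries (half-open [r, r+Δ)); ``mean`` is the
    mean intensity and ``count`` the pixel count per annulus.  The
    ``normalization`` state is ``raw`` (edges in px), ``distance`` (edges in
    units of the spheroid radius) or ``center`` (additionally scaled so the
    center value is 1).
    """

    edges: np.ndarray
    mean: np.ndarray
    count: np.ndarray
    center: tuple[float, float]
    normalization: str = "raw"
    spheroid_radius_px: float | None = None

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.mean) + 1:
            raise ValueError("edges must have one more element than mean")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("annulus edges must be strictly increasing")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total_intensity(self) -> float:
        return float(np.sum(self.mean * self.count))

    def value_at(self, distance: float) -> float:
        """Linear interpolation of the profile at one distance."""
        return float(np.interp(distance, self.midpoints, self.mean))


def detect_spheroid_mask(
    img: MultiChannelImage,
    channel: str | None = None,
    smooth_sigma: float = 2.0,
) -> SpheroidMask:
    """Segment the spheroid: smooth, Otsu, largest component, fill holes.

    ``channel=None`` thresholds the sum of all channels; otherwise the named
    channel (e.g. ``brightfield``).  The centroid is the intensity-weighted
    center of the detected region.

    Raises
    ------
    ValueError
        If no foreground survives thresholding ("no spheroid detected").
    """
    if channel is None:
        data = sum(img.channels[c] for c in img.channel_names)
    else:
        data = img[channel]
    smoothed = gaussian(data, sigma=smooth_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        raise ValueError("no spheroid detected: image is constant")
    thr = threshold_otsu(smoothed)
    fg = smoothed > thr
    if not fg.any():
        raise ValueError("no spheroid detected: empty foreground after thresholding")
    labels = cc_label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    weights = smoothed * mask
    cy, cx = ndimage.center_of_mass(weights)
    area = int(mask.sum())
    return SpheroidMask(
        mask=mask,
        centroid=(float(cx), float(cy)),
        area_px=area,
        equivalent_radius_px=float(np.sqrt(area / np.pi)),
    )


def radial_profile(channel: np.ndarray, center: tuple[float, float]) -> RadialProfile:
    """Mean intensity in concentric 1-px annuli out to the nearest border.

    Annuli are half-open [r, r+1) around ``center`` (x, y).  The sum of
    annulus mean × annulus pixel count equals the image sum over the covered
    pixels exactly.
    """
    h, w = channel.shape
    cx, cy = center
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError(f"center {center} lies outside the image ({w}x{h})")
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(xx - cx, yy - cy)
    r_max = min(cx, w - 1 - cx, cy, h - 1 - cy)
    n_annuli = max(int(np.floor(r_max)), 1)
    bins = np.floor(rr).astype(int)
    covered = bins < n_annuli
    sums = np.bincount(bins[covered], weights=channel[covered], minlength=n_annuli)
    counts = np.bincount(bins[covered], minlength=n_annuli)
    mean = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return RadialProfile(
        edges=np.arange(n_annuli + 1, dtype=float),
        mean=mean,
        count=counts.astype(float),
        center=(float(cx), float(cy)),
    )


def radius_enclosing_fraction(
    profile: RadialProfile, fraction: float = ENCLOSURE_FRACTION
) -> float:
    """Distance from the center enclosing ``fraction`` of total intensity.

    Cumulative intensity (annulus mean × annulus area) is summed outward;
    the crossing radius is found by linear interpolation between annulus
    edges.  ``fraction=1`` returns the outer edge of the last annulus with
    nonzero intensity.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    contrib = profile.mean * profile.count
    total = contrib.sum()
    if total <= 0:
        raise ValueError("zero total intensity: enclosure radius undefined")
    cum = np.cumsum(contrib)
    if fraction >= 1.0:
        nz = np.nonzero(contrib)[0]
        return float(profile.edges[nz[-1] + 1])
    target = fraction * total
    # cum can dip non-monotonically in background-subtracted noise; take the
    # first annulus at which the running total reaches the target
    reached = np.nonzero(cum >= target)[0]
    i = int(reached[0])
    lo_cum = cum[i - 1] if i > 0 else 0.0
    frac_in = (target - lo_cum) / (cum[i] - lo_cum)
    return float(profile.edges[i] + frac_in * (profile.edges[i + 1] - profile.edges[i]))


def subtract_background(
    channel: np.ndarray, mask: np.ndarray, dilation_factor: float = 1.5
) -> np.ndarray:
    """Subtract the median intensity outside a dilated spheroid footprint.

    The background region is everything outside the mask dilated to
    ``dilation_factor`` times its equivalent radius.  The result is NOT
    clipped at zero: leaving the noise residuals symmetric around zero keeps
    annulus means and cumulative-intensity sums unbiased outside the
    spheroid.
    """
    radius = np.sqrt(mask.sum() / np.pi)
    grow = max(int(round((dilation_factor - 1.0) * radius)), 1)
    # isotropic dilation via EDT threshold (fast for large radii)
    dilated = ndimage.distance_transform_edt(~mask) <= grow
    outside = ~dilated
    bg = np.median(channel[outside]) if outside.any() else 0.0
    return channel - bg


def _resample(profile: RadialProfile, grid: np.ndarray) -> RadialProfile:
    """Linear resampling of a distance-normalized profile onto a common grid."""
    mids = profile.midpoints
    vals = np.interp(grid, mids, profile.mean)
    step = grid[1] - grid[0]
    edges = np.concatenate([grid - step / 2.0, [grid[-1] + step / 2.0]])
    return replace(profile, edges=edges, mean=vals, count=np.ones_like(vals))


def normalize_profile(
    profile: RadialProfile,
    spheroid_radius: float,
    center_fraction: float = CENTER_FRACTION,
    grid: np.ndarray | None = None,
) -> RadialProfile:
    """Rescale distances to the spheroid radius and the center value to 1.

    The center intensity is estimated as the count-weighted mean of the
    annuli within the innermost ``center_fraction`` of the spheroid radius
    (single-pixel centers are noise-dominated).  The normalized profile is
    resampled onto ``grid`` (default: 100 uniform bins on [0, 1.2]).

    Raises
    ------
    ValueError
        If the center intensity estimate is <= 0 (normalization undefined).
    """
    if spheroid_radius <= 0:
        raise ValueError("spheroid radius must be positive")
    inner = profile.midpoints <= center_fraction * spheroid_radius
    if not inner.any():
        inner = np.zeros_like(profile.mean, dtype=bool)
        inner[0] = True
    wts = profile.count[inner]
    center_val = float(np.average(profile.mean[inner], weights=wts))
    if center_val <= 0:
        raise ValueError("normalization undefined: center intensity <= 0")
    scaled = replace(
        profile,
        edges=profile.edges / spheroid_radius,
        mean=profile.mean / center_val,
        normalization="center",
        spheroid_radius_px=spheroid_radius,
    )
    return _resample(scaled, NORMALIZED_GRID if grid is None else grid)


def distance_normalize(
    profile: RadialProfile, spheroid_radius: float, grid: np.ndarray | None = None
) -> RadialProfile:
    """Rescale only the distance axis (no center normalization)."""
    if spheroid_radius <= 0:
        raise ValueError("spheroid radius must be positive")
    scaled = replace(
        profile,
        edges=profile.edges / spheroid_radius,
        normalization="distance",
        spheroid_radius_px=spheroid_radius,
    )
    return _resample(scaled, NORMALIZED_GRID if grid is None else grid)


@dataclass
class SortingStatistic:
    """Shell-enrichment readout at normalized distance 0.77.

    ``edge_center_ratio`` is the center-normalized intensity at the edge
    position of the across-spheroid average profile (center ≡ 1);
    ``per_spheroid`` holds the per-spheroid edge values behind the SEM.
    """

    edge_center_ratio: float
    sem: float
    n_spheroids: int
    edge_position: float = EDGE_POSITION
    per_spheroid: np.ndarray | None = None
    mean_profile: RadialProfile | None = None


def sorting_statistic(
    normalized_profiles: list[RadialProfile],
    edge_position: float = EDGE_POSITION,
) -> SortingStatistic:
    """Edge/center statistic from center-normalized profiles.

    Each profile is read at ``edge_position`` by linear interpolation;
    profiles not spanning that distance are excluded with a warning.  The
    ratio is the mean edge value across spheroids (center ≡ 1); the SEM is
    across spheroids, NaN for a single profile.
    """
    if not normalized_profiles:
        raise ValueError("need at least one normalized profile")
    values = []
    for i, p in enumerate(normalized_profiles):
        if p.midpoints[-1] < edge_position:
            warnings.warn(
                f"profile {i} spans only to {p.midpoints[-1]:.2f} < "
                f"{edge_position}: excluded",
                stacklevel=2,
            )
            continue
        values.append(p.value_at(edge_position))
    if not values:
        raise ValueError(f"no profile spans the edge position {edge_position}")
    vals = np.asarray(values)
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    return SortingStatistic(
        edge_center_ratio=float(vals.mean()),
        sem=sem,
        n_spheroids=len(vals),
        edge_position=edge_position,
    )


#: interior plateau (in units of the spheroid radius) used as the center
#: intensity in the aggregate sorting pipeline; labeled cells are sparse, so
#: the innermost annuli alone are Poisson-noise-dominated while the whole
#: core interior shares the same expected intensity
CENTER_PLATEAU_FRACTION = 0.5


def sorting_analysis(
    images: list[MultiChannelImage],
    label_channel: str = "CTR",
    mask_channel: str | None = None,
    edge_position: float = EDGE_POSITION,
    per_spheroid_radius: bool = False,
    center_fraction: float = CENTER_PLATEAU_FRACTION,
) -> SortingStatistic:
    """Full sorting pipeline over the spheroids of one type.

    For each image: detect the spheroid, subtract background from the label
    channel, profile radially around the centroid, and measure the
    95%-enclosure radius.  Distances are normalized by the across-spheroid
    mean of that radius (set ``per_spheroid_radius`` to use each spheroid's
    own).  Profiles are averaged across spheroids on the normalized grid and
    then center-normalized; the ratio is read at ``edge_position``.  The SEM
    comes from per-spheroid center-normalized edge values.

    ``center_fraction`` sets how much of the spheroid interior is averaged
    as the center intensity.  The default pools the core plateau out to half
    the spheroid radius: a shell-sorted spheroid is radially uniform inside
    the shell band, so every interior annulus estimates the same center
    intensity and pooling them suppresses the sparse-cell Poisson noise that
    dominates the innermost annuli alone.
    """
    raw_profiles: list[RadialProfile] = []
    radii: list[float] = []
    for img in images:
        sm = detect_spheroid_mask(img, channel=mask_channel)
        chan = subtract_background(img[label_channel], sm.mask)
        prof = radial_profile(chan, sm.centroid)
        raw_profiles.append(prof)
        radii.append(radius_enclosing_fraction(prof, ENCLOSURE_FRACTION))
    type_radius = float(np.mean(radii))

    dist_profiles = []
    norm_profiles = []
    for i, (prof, own_r) in enumerate(zip(raw_profiles, radii)):
        r = own_r if per_spheroid_radius else type_radius
        dist_profiles.append(distance_normalize(prof, r))
        try:
            norm_profiles.append(
                normalize_profile(prof, r, center_fraction=center_fraction)
            )
        except ValueError:
            # sparse labeling can leave an individual spheroid with a
            # non-positive center estimate; it still contributes to the
            # averaged profile, just not to the per-spheroid SEM
            warnings.warn(
                f"spheroid {i}: center intensity <= 0, excluded from "
                "per-spheroid edge values",
                stacklevel=2,
            )

    # average across spheroids on the common grid, then center-normalize
    grid = NORMALIZED_GRID
    mean_vals = np.mean([p.mean for p in dist_profiles], axis=0)
    step = grid[1] - grid[0]
    mean_prof = RadialProfile(
        edges=np.concatenate([grid - step / 2.0, [grid[-1] + step / 2.0]]),
        mean=mean_vals,
        count=np.ones_like(mean_vals),
        center=(np.nan, np.nan),
        normalization="distance",
        spheroid_radius_px=type_radius,
    )
    inner = grid <= center_fraction
    center_val = float(mean_vals[inner].mean())
    if center_val <= 0:
        raise ValueError("normalization undefined: averaged center intensity <= 0")
    mean_prof = replace(mean_prof, mean=mean_vals / center_val, normalization="center")

    per = sorting_statistic(norm_profiles, edge_position)
    per_vals = np.array(
        [p.value_at(edge_position) for p in norm_profiles if p.midpoints[-1] >= edge_position]
    )
    return SortingStatistic(
        edge_center_ratio=mean_prof.value_at(edge_position),
        sem=per.sem,
        n_spheroids=per.n_spheroids,
        edge_position=edge_position,
        per_spheroid=per_vals,
        mean_profile=mean_prof,
    )


def integrated_intensity(
    img: MultiChannelImage, mask: SpheroidMask | np.ndarray, channel: str = "PI"
) -> float:
    """Sum of channel intensity over the spheroid footprint."""
    m = mask.mask if isinstance(mask, SpheroidMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty spheroid mask")
    return float(img[channel][m].sum())


def pi_death_score(
    img: MultiChannelImage,
    mask: SpheroidMask | np.ndarray,
    controls: list[tuple[MultiChannelImage, SpheroidMask | np.ndarray]],
    channel: str = "PI",
) -> float:
    """Integrated dead-cell-stain intensity relative to untreated controls.

    The treated well's integrated intensity over its spheroid area is
    divided by the mean of the same quantity over the control wells.
    """
    if not controls:
        raise ValueError("need at least one untreated control well")
    ctrl = float(np.mean([integrated_intensity(ci, cm, channel) for ci, cm in controls]))
    if ctrl <= 0:
        raise ValueError("control integrated intensity <= 0")
    return integrated_intensity(img, mask, channel) / ctrl
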