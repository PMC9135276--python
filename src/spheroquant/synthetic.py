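"""Synthetic microscopy and plate-assay data with known ground truth.

Every quantification stage in this package was designed against wet-lab
readouts (IncuCyte spheroid imaging, MTT/CellTiter-Glo plates, CellProfiler
immunofluorescence fields, qPCR Ct tables).  The generators here emulate the
statistical structure of those readouts — two-population spheroids with a
controllable radial sorting bias, dose-response viabilities with a
controllable shell-shielding protection effect, logistic confluency curves,
tessellated monolayers with a membrane marker of controllable edge
enrichment, collagen-invasion fields with labeled sheets of known extent,
and Ct tables encoding known copy-number ratios — so the full pipeline can
be exercised and validated against exact ground truth without any imaging
hardware.

All randomness flows from the explicit ``seed`` of each call (one
``numpy.random.default_rng`` per call, no global state); identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

from .image import MultiChannelImage
from .qpcr import CtTable

__all__ = [
    "SyntheticSpheroidSpec",
    "GroundTruth",
    "ProtectionGenSpec",
    "ProtectionTables",
    "MonolayerTruth",
    "MigrationTruth",
    "gen_spheroid_image",
    "gen_protection_tables",
    "gen_growth_curve",
    "gen_monolayer_image",
    "gen_migration_image",
    "gen_ct_table",
    "three_param_viability",
]

# integrated fluorescence contributed by one rendered cell (arbitrary units)
_CELL_AMPLITUDE = 100.0


# --------------------------------------------------------------------------
# spheroid images
# --------------------------------------------------------------------------

@dataclass
class SyntheticSpheroidSpec:
    """Recipe for a two-population co-culture spheroid image.

    The default condition mirrors a 2000-cell spheroid with 25% of cells
    carrying a cytoplasmic tracker dye.  ``sorting_strength`` controls how
    strongly the labeled population is pushed into the shell: labeled cell
    radii are rejection-sampled with weight
    ``exp(sorting_strength * 1[r/R in shell_band])``, so strength 0 is a
    well-mixed spheroid and the true edge/center intensity ratio of the
    labeled channel is ``exp(sorting_strength)`` when the read-out position
    falls inside the band.
    """

    image_size_px: tuple[int, int] = (384, 384)
    spheroid_radius_px: float = 120.0
    n_cells: int = 2000
    labeled_fraction: float = 0.25
    sorting_strength: float = 0.0
    cell_radius_px: float = 6.0
    shell_band: tuple[float, float] = (0.7, 1.0)
    noise_sd: float = 1.0
    background_level: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must lie in [0, 1]")
        lo, hi = self.shell_band
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("shell_band must be a sub-interval of [0, 1]")
        if self.sorting_strength < 0:
            raise ValueError("sorting_strength must be >= 0")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise_sd and background_level must be >= 0")
        if self.spheroid_radius_px <= 0 or self.n_cells <= 0:
            raise ValueError("spheroid_radius_px and n_cells must be positive")
        if self.cell_radius_px <= 0:
            raise ValueError("cell_radius_px must be positive")
        h, w = self.image_size_px
        if min(h, w) / 2.0 < 1.1 * self.spheroid_radius_px:
            raise ValueError(
                "spheroid does not fit: image half-size "
                f"{min(h, w) / 2.0:.0f} px is below 1.1 x radius "
                f"({1.1 * self.spheroid_radius_px:.0f} px)"
            )

    @property
    def true_edge_center_ratio(self) -> float:
        """Labeled-channel intensity ratio at edge (0.77) vs center (0)."""
        return self._weight(0.77) / self._weight(0.0)

    def _weight(self, r_norm: float) -> float:
        lo, hi = self.shell_band
        return math.exp(self.sorting_strength) if lo <= r_norm <= hi else 1.0

    @classmethod
    def strength_for_ratio(cls, ratio: float) -> float:
        """Sorting strength giving a true edge/center ratio of ``ratio``."""
        if ratio < 1:
            raise ValueError("edge/center ratio below 1 is not representable")
        return math.log(ratio)


@dataclass
class GroundTruth:
    """Exact placements behind a generated spheroid image."""

    cell_centers: np.ndarray  # (n, 2) float, (x, y)
    populations: np.ndarray  # (n,) str, "labeled" | "unlabeled"
    true_radial_density: pd.DataFrame  # per normalized-radius bin
    true_edge_center_ratio: float
    mask: np.ndarray  # bool raster of spheroid area
    center: tuple[float, float] = (0.0, 0.0)  # (x, y)
    radius_px: float = 0.0


def _sample_disk(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform points on the unit disk in polar form (r, theta)."""
    r = np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return r, theta


def _sample_shell_biased(
    rng: np.random.Generator, n: int, strength: float, band: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection sampling with weight exp(strength * 1[r in band]).

    The proposal is the uniform disk; acceptance probability is
    weight / exp(strength), so the accepted density per unit area is
    proportional to the weight.
    """
    rs: list[np.ndarray] = []
    ts: list[np.ndarray] = []
    got = 0
    wmax = math.exp(strength)
    lo, hi = band
    while got < n:
        m = max(2 * (n - got), 64)
        r, theta = _sample_disk(rng, m)
        w = np.where((r >= lo) & (r <= hi), wmax, 1.0)
        keep = rng.uniform(size=m) * wmax < w
        rs.append(r[keep])
        ts.append(theta[keep])
        got += int(keep.sum())
    r = np.concatenate(rs)[:n]
    theta = np.concatenate(ts)[:n]
    return r, theta


def _render_points(
    shape: tuple[int, int],
    xs: np.ndarray,
    ys: np.ndarray,
    sigma: float,
    amplitude: float,
) -> np.ndarray:
    """Splat unit masses onto the pixel grid and blur to Gaussian spots."""
    img = np.zeros(shape, dtype=float)
    ix = np.clip(np.round(ys).astype(int), 0, shape[0] - 1)
    iy = np.clip(np.round(xs).astype(int), 0, shape[1] - 1)
    np.add.at(img, (ix, iy), amplitude)
    return gaussian_filter(img, sigma=sigma)


def gen_spheroid_image(
    spec: SyntheticSpheroidSpec,
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render a two-channel co-culture spheroid with exact ground truth.

    Channels: ``CTR`` (labeled population) and ``CTG`` (unlabeled
    population).  Cells are drawn as isotropic Gaussian spots with
    ``sigma = cell_radius_px / 2`` over a constant background, plus additive
    Gaussian noise clipped at zero.  The unlabeled population is uniform on
    the spheroid disk; the labeled one carries the shell bias described on
    :class:`SyntheticSpheroidSpec`.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    R = spec.spheroid_radius_px

    n_labeled = int(rng.binomial(spec.n_cells, spec.labeled_fraction))
    n_unlabeled = spec.n_cells - n_labeled

    r_lab, t_lab = _sample_shell_biased(
        rng, n_labeled, spec.sorting_strength, spec.shell_band
    )
    r_unl, t_unl = _sample_disk(rng, n_unlabeled)

    x_lab = cx + R * r_lab * np.cos(t_lab)
    y_lab = cy + R * r_lab * np.sin(t_lab)
    x_unl = cx + R * r_unl * np.cos(t_unl)
    y_unl = cy + R * r_unl * np.sin(t_unl)

    sigma = spec.cell_radius_px / 2.0
    ctr = _render_points((h, w), x_lab, y_lab, sigma, _CELL_AMPLITUDE)
    ctg = _render_points((h, w), x_unl, y_unl, sigma, _CELL_AMPLITUDE)

    channels = {}
    for name, raw in (("CTR", ctr), ("CTG", ctg)):
        noisy = raw + spec.background_level
        if spec.noise_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.noise_sd, size=raw.shape)
        channels[name] = np.clip(noisy, 0.0, None)

    yy, xx = np.mgrid[0:h, 0:w]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= R**2

    # analytic labeled density per normalized-radius bin: proportional to the
    # rejection weight, normalized so the disk integral is 1
    edges = np.linspace(0.0, 1.0, 51)
    mids = 0.5 * (edges[:-1] + edges[1:])
    weight = np.array([spec._weight(m) for m in mids])
    norm = np.sum(weight * 2.0 * np.pi * mids * np.diff(edges))
    density = pd.DataFrame(
        {"r_norm": mids, "density": weight / norm}
    )

    centers = np.column_stack(
        [np.concatenate([x_lab, x_unl]), np.concatenate([y_lab, y_unl])]
    )
    pops = np.array(["labeled"] * n_labeled + ["unlabeled"] * n_unlabeled)

    truth = GroundTruth(
        cell_centers=centers,
        populations=pops,
        true_radial_density=density,
        true_edge_center_ratio=spec.true_edge_center_ratio,
        mask=mask,
        center=(cx, cy),
        radius_px=R,
    )
    img = MultiChannelImage(channels, provenance=f"gen_spheroid_image(seed={spec.seed})")
    return img, truth


# --------------------------------------------------------------------------
# chemoprotection viability tables
# --------------------------------------------------------------------------

def three_param_viability(
    dose: np.ndarray | float, ic50: float, top: float = 1.0, bottom: float = 0.0
) -> np.ndarray | float:
    """Three-parameter inhibition curve V(c) = bottom + (top-bottom)/(1 + c/ic50)."""
    return bottom + (top - bottom) / (1.0 + np.asarray(dose, dtype=float) / ic50)


@dataclass
class ProtectionGenSpec:
    """Recipe for mono- and co-culture viability tables.

    ``mode="independent_2d"`` makes each population respond to the nominal
    dose (a well-mixed monolayer); ``mode="shell_shielding_spheroid"``
    divides the dose reaching the sensitive population by
    ``attenuation_factor``, a deliberately simple stand-in for drug
    depletion and limited mass transport into the spheroid core.  It is a
    testing construct, not a transport model.
    """

    ic50_sensitive: float
    ic50_resistant: float
    concentrations: tuple[float, ...]
    mixture_weights: tuple[float, float] = (3.0, 1.0)  # (sensitive, resistant)
    mode: str = "independent_2d"
    attenuation_factor: float = 1.0
    replicate_noise_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("independent_2d", "shell_shielding_spheroid"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.attenuation_factor < 1.0:
            raise ValueError("attenuation_factor must be >= 1")
        doses = np.asarray(self.concentrations, dtype=float)
        if (doses <= 0).any():
            raise ValueError("concentrations must be strictly positive")
        if not np.all(np.diff(doses) > 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.ic50_sensitive <= 0 or self.ic50_resistant <= 0:
            raise ValueError("IC50s must be positive")
        if any(wt <= 0 for wt in self.mixture_weights):
            raise ValueError("mixture weights must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class ProtectionTables:
    """Long-format viability tables for two mono-cultures and their co-culture."""

    mono_sensitive: pd.DataFrame
    mono_resistant: pd.DataFrame
    co_culture: pd.DataFrame
    spec: ProtectionGenSpec

    def as_dict(self) -> dict[str, pd.DataFrame]:
        return {
            "mono_sensitive": self.mono_sensitive,
            "mono_resistant": self.mono_resistant,
            "co_culture": self.co_culture,
        }


def _viability_table(
    condition: str,
    doses: np.ndarray,
    means: np.ndarray,
    noise_sd: float,
    n_rep: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    well = 0
    for dose, mu in zip(doses, means):
        for rep in range(1, n_rep + 1):
            # noise is not floored at zero: normalized viabilities from
            # blank-subtracted plates can dip slightly negative, and
            # clipping would bias deep-kill doses upward
            v = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {
                    "well": f"w{well:03d}",
                    "condition": condition,
                    "dose_M": dose,
                    "replicate": rep,
                    "value": v,
                }
            )
            well += 1
    return pd.DataFrame(rows)


def gen_protection_tables(spec: ProtectionGenSpec) -> ProtectionTables:
    """Generate mono- and co-culture viability tables under a known model.

    Mono-cultures follow the three-parameter inhibition curve at each
    nominal dose.  The co-culture observed viability is the
    mixture-weight-averaged combination of the two components, with the
    sensitive component evaluated at ``dose / attenuation_factor`` in
    shielding mode — so with ``attenuation_factor == 1`` the two modes
    coincide and the chemoprotection coefficient is identically 1.
    """
    rng = np.random.default_rng(spec.seed)
    doses = np.asarray(spec.concentrations, dtype=float)
    v_sens = three_param_viability(doses, spec.ic50_sensitive)
    v_res = three_param_viability(doses, spec.ic50_resistant)

    if spec.mode == "shell_shielding_spheroid":
        v_sens_in_co = three_param_viability(
            doses / spec.attenuation_factor, spec.ic50_sensitive
        )
    else:
        v_sens_in_co = v_sens

    ws, wr = spec.mixture_weights
    v_co = (ws * v_sens_in_co + wr * v_res) / (ws + wr)

    sd, nr = spec.replicate_noise_sd, spec.n_replicates
    return ProtectionTables(
        mono_sensitive=_viability_table("sensitive", doses, v_sens, sd, nr, rng),
        mono_resistant=_viability_table("resistant", doses, v_res, sd, nr, rng),
        co_culture=_viability_table("co_culture", doses, v_co, sd, nr, rng),
        spec=spec,
    )


# --------------------------------------------------------------------------
# confluency growth curves
# --------------------------------------------------------------------------

def gen_growth_curve(
    K: float,
    r: float,
    t0: float,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Logistic confluency time course, emulating live-cell imaging exports.

    confluency(t) = K / (1 + exp(-r (t - t0))) + noise, clipped to [0, 100].
    ``K`` is % confluency at plateau, ``r`` per-hour, ``t0`` the inflection
    time in hours.  The implied exponential-phase doubling time is ln(2)/r.
    """
    if not 0.0 < K <= 100.0:
        raise ValueError("carrying capacity K must lie in (0, 100]")
    if r <= 0:
        raise ValueError("growth rate r must be positive")
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    conf = K / (1.0 + np.exp(-r * (times - t0)))
    if noise_sd > 0:
        conf = conf + rng.normal(0.0, noise_sd, size=times.shape)
    conf = np.clip(conf, 0.0, 100.0)
    return pd.DataFrame({"time_h": times, "confluency": conf})


# --------------------------------------------------------------------------
# monolayer immunofluorescence fields
# --------------------------------------------------------------------------

@dataclass
class MonolayerTruth:
    """Ground truth behind a generated monolayer field."""

    seeds: np.ndarray  # (n, 2) float, (x, y) nucleus centers
    cell_labels: np.ndarray  # int raster, 0 = background
    intended_ratio: float  # per-cell edge/cytoplasm construction ratio
    per_cell_ratio: pd.DataFrame  # cell id -> intended ratio


def gen_monolayer_image(
    n_cells: int,
    enrichment: float = 0.0,
    seed: int = 0,
    image_size_px: tuple[int, int] = (512, 512),
    nucleus_radius_px: float = 5.0,
    min_separation_px: float = 28.0,
    cell_extent_px: float = 45.0,
    band_width_px: float = 2.0,
    cytoplasm_level: float = 50.0,
    noise_sd: float = 1.0,
) -> tuple[MultiChannelImage, MonolayerTruth]:
    """Generate a nuclei + membrane-marker field with a tessellated monolayer.

    Nuclei are Gaussian blobs at randomly placed seed points (rejected if
    closer than ``min_separation_px``); the cell sheet is the set of pixels
    within ``cell_extent_px`` of a seed, partitioned into Voronoi cells by
    nearest seed.  The marker channel equals ``cytoplasm_level`` inside each
    cell plus ``enrichment * cytoplasm_level`` within ``band_width_px`` of a
    cell boundary, so the intended edge/cytoplasm intensity ratio is
    ``1 + enrichment`` and ``enrichment == 0`` gives a marker that is
    uniform within every cell.

    Raises
    ------
    ValueError
        If ``n_cells`` seeds cannot be placed at the required separation
        (cells too dense to tessellate).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if enrichment < 0:
        raise ValueError("enrichment must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = image_size_px
    margin = 8.0

    seeds: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 200 * n_cells
    while len(seeds) < n_cells:
        if attempts >= max_attempts:
            raise ValueError(
                f"cells too dense to tessellate: placed {len(seeds)}/{n_cells} "
                f"seeds at separation >= {min_separation_px} px"
            )
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - sx) ** 2 + (y - sy) ** 2 >= min_separation_px**2 for sx, sy in seeds):
            seeds.append((x, y))
        attempts += 1
    seed_arr = np.array(seeds)

    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    tree = cKDTree(seed_arr)
    dist, idx = tree.query(pix)
    dist = dist.reshape(h, w)
    labels = (idx.reshape(h, w) + 1).astype(np.int32)
    labels[dist > cell_extent_px] = 0  # background outside the sheet

    boundary = find_boundaries(labels, mode="thick")
    from scipy.ndimage import distance_transform_edt

    dist_to_boundary = distance_transform_edt(~boundary)
    band = (labels > 0) & (dist_to_boundary <= band_width_px)

    marker = np.zeros((h, w), dtype=float)
    marker[labels > 0] = cytoplasm_level
    marker[band] += enrichment * cytoplasm_level
    marker = gaussian_filter(marker, sigma=0.8)

    dapi = _render_points(
        (h, w), seed_arr[:, 0], seed_arr[:, 1], nucleus_radius_px / 2.0, _CELL_AMPLITUDE
    )

    channels = {}
    for name, raw in (("dapi", dapi), ("marker", marker)):
        noisy = raw + (rng.normal(0.0, noise_sd, size=raw.shape) if noise_sd > 0 else 0.0)
        channels[name] = np.clip(noisy, 0.0, None)

    per_cell = pd.DataFrame(
        {"cell": np.arange(1, n_cells + 1), "intended_ratio": 1.0 + enrichment}
    )
    truth = MonolayerTruth(
        seeds=seed_arr,
        cell_labels=labels,
        intended_ratio=1.0 + enrichment,
        per_cell_ratio=per_cell,
    )
    img = MultiChannelImage(channels, provenance=f"gen_monolayer_image(seed={seed})")
    return img, truth


# --------------------------------------------------------------------------
# collagen invasion fields
# --------------------------------------------------------------------------

@dataclass
class MigrationTruth:
    center: tuple[float, float]  # (x, y)
    spheroid_radius_px: float
    sheet_end_distances_px: tuple[float, ...]
    sheet_angles_rad: tuple[float, ...]
    initial_mask: np.ndarray
    mean_top3_normalized: float


def gen_migration_image(
    spheroid_diameter_px: float,
    sheet_end_distances_px: list[float],
    seed: int = 0,
    sheet_width_px: float = 16.0,
    image_margin_px: float = 30.0,
) -> tuple[MultiChannelImage, MigrationTruth]:
    """Render a labeled spheroid with radially oriented invasive sheets.

    The central disk has radius ``spheroid_diameter_px / 2``; each sheet is a
    radial band of width ``sheet_width_px`` connected to the disk and ending
    at its given center distance, at angles spread around the circle with a
    seeded jitter.  An empty distance list yields a bare spheroid.
    """
    radius = spheroid_diameter_px / 2.0
    if radius <= 0:
        raise ValueError("spheroid_diameter_px must be positive")
    for d in sheet_end_distances_px:
        if d <= radius:
            raise ValueError(
                f"sheet end distance {d} px does not exceed the spheroid "
                f"radius {radius} px"
            )
    rng = np.random.default_rng(seed)
    reach = max([radius, *sheet_end_distances_px])
    half = int(np.ceil(reach + image_margin_px))
    h = w = 2 * half + 1
    cx = cy = float(half)

    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    rr = np.hypot(dx, dy)
    signal = np.zeros((h, w), dtype=float)
    signal[rr <= radius] = 100.0
    initial_mask = rr <= radius

    n = len(sheet_end_distances_px)
    angles = []
    if n:
        base = rng.uniform(0.0, 2.0 * np.pi)
        jitter = rng.uniform(-0.1, 0.1, size=n)
        angles = [base + 2.0 * np.pi * k / n + jitter[k] for k in range(n)]
        theta = np.arctan2(dy, dx)
        for ang, dend in zip(angles, sheet_end_distances_px):
            # perpendicular distance from the sheet's central ray
            perp = np.abs(rr * np.sin(np.arctan2(np.sin(theta - ang), np.cos(theta - ang))))
            along = rr * np.cos(theta - ang)
            in_sheet = (perp <= sheet_width_px / 2.0) & (along >= 0) & (rr <= dend)
            signal[in_sheet] = 100.0

    if sheet_end_distances_px:
        top3 = sorted(sheet_end_distances_px, reverse=True)[:3]
        mean_norm = float(np.mean(top3) / spheroid_diameter_px)
    else:
        mean_norm = 0.5  # center-to-boundary floor

    truth = MigrationTruth(
        center=(cx, cy),
        spheroid_radius_px=radius,
        sheet_end_distances_px=tuple(sheet_end_distances_px),
        sheet_angles_rad=tuple(angles),
        initial_mask=initial_mask,
        mean_top3_normalized=mean_norm,
    )
    img = MultiChannelImage(
        {"CTG": signal}, provenance=f"gen_migration_image(seed={seed})"
    )
    return img, truth


# --------------------------------------------------------------------------
# qPCR Ct tables
# --------------------------------------------------------------------------

def gen_ct_table(
    true_copy_numbers: dict[str, float],
    reference_sample: str,
    ct_ref_gene: float = 26.0,
    replicate_sd: float = 0.0,
    n_tech: int = 3,
    seed: int = 0,
    target_gene: str = "RRM1",
    reference_gene: str = "RNaseP",
) -> CtTable:
    """Ct table whose ΔCt arithmetic recovers known copy numbers.

    For each sample the relative copy number is ``n_rel = copies / 2`` (the
    diploid reference carries 2 copies), and the target-gene Ct is
    ``ct_ref_gene - log2(n_rel)`` so that ``ΔCt = Ct_target - Ct_reference``
    followed by ``n_rel = 2^-ΔCt`` and normalization to the diploid control
    returns the true copy numbers exactly in the noiseless case.  Gaussian
    noise of SD ``replicate_sd`` cycles is added independently to every
    technical-replicate Ct.
    """
    if reference_sample not in true_copy_numbers:
        raise ValueError(
            f"reference sample {reference_sample!r} missing from true_copy_numbers"
        )
    for s, c in true_copy_numbers.items():
        if c <= 0:
            raise ValueError(f"copy number for {s!r} must be positive, got {c}")
    if n_tech < 1:
        raise ValueError("n_tech must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, copies in true_copy_numbers.items():
        n_rel = copies / 2.0
        ct_target = ct_ref_gene - math.log2(n_rel)
        for rep in range(1, n_tech + 1):
            for gene, ct in ((target_gene, ct_target), (reference_gene, ct_ref_gene)):
                noise = rng.normal(0.0, replicate_sd) if replicate_sd > 0 else 0.0
                rows.append(
                    {"sample": sample, "gene": gene, "replicate": rep, "ct": ct + noise}
                )
    return CtTable(
        data=pd.DataFrame(rows),
        target_gene=target_gene,
        reference_gene=reference_gene,
    )
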