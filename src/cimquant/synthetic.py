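"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline is validated by parameter recovery on
data from these generators: scratch fields whose nucleus->Golgi angles come
from a sector-uniform mixture with a known polarized weight, two-population
brain-section point patterns with exponential distance thinning, tumour
composition time courses with binomial section counts, and two-channel
images whose marker signal is split between nuclear / perinuclear /
cytoplasmic compartments in known proportions.

The angular model is a mixture: with probability ``rho`` a cell's direction
is uniform inside the +/-60 deg polarized sector, otherwise uniform over the
full circle, so the expected polarized fraction has the closed form
``rho + (1 - rho) * (2 * halfwidth / 360)`` — exactly 1/3 under the uniform
null (rho = 0).  A von Mises alternative is provided for shape realism, but
the mixture is the default because its polarized probability is exact.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compartments import CompartmentImage, perinuclear_band
from .infiltration import SectionPointPattern
from .polarity import ScratchField, wound_normal

__all__ = [
    "PolarityGenConfig",
    "SectionGenConfig",
    "CompartmentGenConfig",
    "gen_scratch_field",
    "gen_section",
    "gen_compartment_image",
    "gen_timecourse",
    "sample_polarity_angles",
    "sample_von_mises_angles",
    "expected_polarized_fraction",
    "write_scratch_csv",
    "write_section_csv",
    "write_timecourse_csv",
    "write_compartment_tiff",
]


# ---------------------------------------------------------------------------
# scratch fields

def _default_rim() -> np.ndarray:
    # vertical scratch rim, wound on the +x side
    return np.array([[0.0, -500.0], [0.0, 500.0]])


@dataclass
class PolarityGenConfig:
    """Scratch-field generator parameters.

    ``polarized_weight`` (rho) is the probability that a cell's direction is
    drawn from the polarized sector component; ``band_depth`` is how far
    from the rim (into the monolayer) nuclei are placed; ``golgi_offset``
    is the fixed nucleus->Golgi centroid distance (the assays this emulates
    never report it, and it affects only geometry, not angles).
    """

    n_cells: int
    polarized_weight: float
    sector_halfwidth: float = 60.0
    rim: np.ndarray = field(default_factory=_default_rim)
    wound_side_point: np.ndarray = field(default_factory=lambda: np.array([100.0, 0.0]))
    band_depth: float = 100.0
    golgi_offset: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if not 0.0 <= self.polarized_weight <= 1.0:
            raise ValueError("polarized_weight must be in [0, 1]")
        if not 0 < self.sector_halfwidth < 180:
            raise ValueError("sector_halfwidth must be in (0, 180)")
        self.rim = np.asarray(self.rim, dtype=float).reshape(-1, 2)
        self.wound_side_point = np.asarray(self.wound_side_point, dtype=float).reshape(2)


def expected_polarized_fraction(rho: float, sector_halfwidth: float = 60.0) -> float:
    """Closed-form expected polarized fraction of the angular mixture."""
    return rho + (1.0 - rho) * (2.0 * sector_halfwidth / 360.0)


def sample_polarity_angles(n: int, rho: float, sector_halfwidth: float = 60.0,
                           seed: int | None = 0, rng=None) -> np.ndarray:
    """Draw n angles from the sector mixture (degrees, in (-180, 180]).

    With probability ``rho`` an angle is uniform inside the polarized
    sector, otherwise uniform over the full circle, so the expected
    polarized fraction is ``rho + (1 - rho) * 2 * sector_halfwidth / 360``
    and ``rho=0`` is exactly the uniform direction null.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    halfwidth = sector_halfwidth
    in_sector = rng.random(n) < rho
    theta = np.empty(n)
    k = int(in_sector.sum())
    theta[in_sector] = rng.uniform(-halfwidth, halfwidth, k)
    background = rng.uniform(-180.0, 180.0, n - k)
    background[background == -180.0] = 180.0
    theta[~in_sector] = background
    return theta


def sample_von_mises_angles(n: int, kappa: float, seed: int | None = 0) -> np.ndarray:
    """Von Mises alternative to the sector mixture (mean direction 0 =
    toward the wound); no closed-form polarized fraction, shape realism
    only."""
    rng = np.random.default_rng(seed)
    return np.degrees(rng.vonmises(0.0, kappa, n))


def gen_scratch_field(config: PolarityGenConfig) -> tuple[ScratchField, np.ndarray]:
    """Generate a scratch field with known per-cell polarity angles.

    Nuclei occupy a jittered grid filling the band of depth ``band_depth``
    on the monolayer side of the rim, with a guaranteed minimum
    nucleus-nucleus spacing of ``2 * (golgi_offset + 1)`` um (cells exclude
    each other physically); this makes nearest-nucleus Golgi pairing
    unambiguous, so the recorded ground-truth angles are exactly what the
    analysis recovers.  Each Golgi centroid sits at ``golgi_offset`` from
    its nucleus along a direction whose signed angle to the wound-directed
    rim normal is drawn from the mixture.  Returns ``(field, true_angles)``.

    Raises ``ValueError`` when ``n_cells`` exceeds the band's capacity at
    that spacing (use a longer rim or fewer cells).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    seg = np.diff(cfg.rim, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    L = float(cum[-1])
    c = 2.0 * (cfg.golgi_offset + 1.0)  # grid cell side, um
    ncols = int(L // c)
    nrows = int(cfg.band_depth // c)
    if ncols * nrows < cfg.n_cells:
        raise ValueError(
            f"n_cells={cfg.n_cells} exceeds band capacity {ncols * nrows} at "
            f"min spacing {c:g} um; lengthen the rim or reduce n_cells")
    slots = rng.choice(ncols * nrows, size=cfg.n_cells, replace=False)
    col, row = slots % ncols, slots // ncols
    pitch_s, pitch_d = L / ncols, cfg.band_depth / nrows
    jit_s = max(0.0, pitch_s / 2.0 - c / 2.0)
    jit_d = max(0.0, pitch_d / 2.0 - c / 2.0)
    s = (col + 0.5) * pitch_s + rng.uniform(-jit_s, jit_s, cfg.n_cells)
    depth = (row + 0.5) * pitch_d + rng.uniform(-jit_d, jit_d, cfg.n_cells)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    frac = (s - cum[idx]) / np.where(seg_len[idx] == 0, 1.0, seg_len[idx])
    on_rim = cfg.rim[idx] + frac[:, None] * seg[idx]
    theta = sample_polarity_angles(cfg.n_cells, cfg.polarized_weight,
                                   cfg.sector_halfwidth, rng=rng)
    nuclei = np.empty((cfg.n_cells, 2))
    golgi = np.empty((cfg.n_cells, 2))
    rad = np.radians(theta)
    for i in range(cfg.n_cells):
        normal, _ = wound_normal(on_rim[i], cfg.rim, cfg.wound_side_point)
        nuclei[i] = on_rim[i] - depth[i] * normal
        # re-evaluate the normal at the nucleus so the recorded angle matches
        # the analysis geometry exactly (identical for a straight rim)
        n_at, _ = wound_normal(nuclei[i], cfg.rim, cfg.wound_side_point)
        c, sn = np.cos(rad[i]), np.sin(rad[i])
        direction = np.array([c * n_at[0] - sn * n_at[1],
                              sn * n_at[0] + c * n_at[1]])
        golgi[i] = nuclei[i] + cfg.golgi_offset * direction
    fld = ScratchField(nuclei=nuclei, golgi=golgi, rim=cfg.rim,
                       wound_side_point=cfg.wound_side_point,
                       field_id=f"sim-rho{cfg.polarized_weight:g}-seed{cfg.seed}")
    return fld, theta


# ---------------------------------------------------------------------------
# brain sections

def _default_rim_polygon(radius: float = 150.0, k: int = 64) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


@dataclass
class SectionGenConfig:
    """Brain-section point-pattern generator parameters.

    Radial cell placement outside the injection-site rim follows a
    truncated exponential with per-population rate (per um); rate 0 means
    uniform over [0, max_extent].  A larger silenced rate than control rate
    concentrates the silenced population near the rim, which is the
    depletion-with-distance structure the infiltration analysis detects.
    ``max_extent`` is the observation window around the rim; its default
    (300 um) spans several decay lengths of the default silenced rate while
    keeping counts in the far bins.
    """

    n_silenced: int
    n_control: int
    decay_silenced: float = 0.02  # per um
    decay_control: float = 0.005
    rim_polygon: np.ndarray = field(default_factory=_default_rim_polygon)
    max_extent: float = 300.0
    section_id: str = "sim"
    day: float | None = None
    tumor_id: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_silenced < 0 or self.n_control < 0:
            raise ValueError("population sizes must be non-negative")
        if self.decay_silenced < 0 or self.decay_control < 0:
            raise ValueError("decay rates must be >= 0")
        self.rim_polygon = np.asarray(self.rim_polygon, dtype=float).reshape(-1, 2)
        area = 0.5 * abs(np.dot(self.rim_polygon[:, 0], np.roll(self.rim_polygon[:, 1], -1))
                         - np.dot(self.rim_polygon[:, 1], np.roll(self.rim_polygon[:, 0], -1)))
        if area <= 0:
            raise ValueError("degenerate rim polygon (zero area)")


def _truncated_exponential(rng, rate, hi, size):
    if rate == 0:
        return rng.uniform(0.0, hi, size)
    u = rng.random(size)
    return -np.log1p(-u * (1.0 - np.exp(-rate * hi))) / rate


def _boundary_radius(polygon: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Distance from the polygon centroid to its boundary along direction
    phi, for a polygon star-shaped about its centroid (vectorised
    ray-segment intersection)."""
    c = polygon.mean(axis=0)
    d = np.column_stack([np.cos(phi), np.sin(phi)])  # (N, 2)
    a = polygon - c
    b = np.roll(polygon, -1, axis=0) - c
    e = b - a  # (K, 2)
    # solve c + t*d = a + s*e for each (ray, segment)
    det = d[:, None, 0] * (-e[None, :, 1]) - d[:, None, 1] * (-e[None, :, 0])
    det = np.where(np.abs(det) < 1e-12, np.nan, det)
    rhs = a[None, :, :]  # origin shifted to centroid
    t = (rhs[..., 0] * (-e[None, :, 1]) - rhs[..., 1] * (-e[None, :, 0])) / det
    s = (d[:, None, 0] * rhs[..., 1] - d[:, None, 1] * rhs[..., 0]) / det
    valid = (t > 0) & (s >= -1e-12) & (s <= 1 + 1e-12)
    t = np.where(valid, t, np.inf)
    return t.min(axis=1)


def gen_section(config: SectionGenConfig) -> tuple[SectionPointPattern, dict]:
    """Generate one two-population section around an injection-site rim.

    For each cell an angular position (uniform) and a radial offset from the
    rim boundary (truncated exponential with the population's rate) are
    drawn; all points lie outside the rim polygon and within ``max_extent``
    of it.  Returns ``(pattern, true_offsets)`` where ``true_offsets`` maps
    population -> the sampled radial offsets (the ground truth the distance
    measurement recovers, up to polygon-discretisation error).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    centroid = cfg.rim_polygon.mean(axis=0)
    xs, pops, truth = [], [], {}
    for pop, n, rate in (("silenced", cfg.n_silenced, cfg.decay_silenced),
                         ("control", cfg.n_control, cfg.decay_control)):
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        off = _truncated_exponential(rng, rate, cfg.max_extent, n)
        r0 = _boundary_radius(cfg.rim_polygon, phi)
        xy = centroid + np.column_stack([(r0 + off) * np.cos(phi),
                                         (r0 + off) * np.sin(phi)])
        xs.append(xy)
        pops.extend([pop] * n)
        truth[pop] = off
    xy = np.vstack(xs) if xs else np.empty((0, 2))
    pattern = SectionPointPattern(
        section_id=cfg.section_id, xy=xy,
        population=np.array(pops, dtype=object),
        rim_polygon=cfg.rim_polygon, day=cfg.day, tumor_id=cfg.tumor_id)
    return pattern, truth


# ---------------------------------------------------------------------------
# tumour composition time course

def gen_timecourse(fractions_by_day, cells_per_section: int = 500,
                   sections_per_tumor: int = 3, seed: int = 0) -> pd.DataFrame:
    """Per-section silenced/control counts for a composition schedule.

    ``fractions_by_day`` is a list of ``(day, expected_silenced_fraction)``
    with strictly increasing days, one tumour per schedule entry; each
    section's silenced count is binomial around the tumour's expected
    fraction.  Returns a section table consumable by
    :func:`cimquant.infiltration.composition_timecourse`.
    """
    sched = list(fractions_by_day)
    if not sched:
        raise ValueError("empty schedule")
    days = [d for d, _f in sched]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing")
    if any(not 0.0 <= f <= 1.0 for _d, f in sched):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for t, (day, frac) in enumerate(sched):
        for s in range(sections_per_tumor):
            k = int(rng.binomial(cells_per_section, frac))
            rows.append({"tumor_id": f"tumor-{t}", "day": float(day),
                         "section_id": f"tumor-{t}-sec-{s}",
                         "n_silenced": k, "n_control": cells_per_section - k})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# compartment images

@dataclass
class CompartmentGenConfig:
    """Two-channel compartment-image generator parameters.

    ``target_fractions`` are the ground-truth shares of total marker signal
    in the nuclear / perinuclear (3 um band) / cytoplasmic compartments
    (must sum to 1).  Cells are disjoint disks on a grid; channel 1 is the
    nuclear dye, channel 2 the marker.  ``noise_sd`` is Gaussian, in units
    of the brightest compartment's noise-free intensity (which is scaled
    to 1).
    """

    image_shape: tuple = (256, 256)
    pixel_size: float = 0.4  # um/pixel
    n_nuclei: int = 9
    nucleus_radius: float = 5.0  # um
    cell_radius: float = 12.0
    band_um: float = 3.0
    target_fractions: tuple = (0.2, 0.3, 0.5)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.target_fractions, dtype=float)
        if f.shape != (3,) or abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
            raise ValueError("target_fractions must be 3 non-negative values summing to 1")
        if self.nucleus_radius >= self.cell_radius:
            raise ValueError("nucleus_radius must be smaller than cell_radius")
        if self.cell_radius - self.nucleus_radius < self.band_um:
            warnings.warn("perinuclear band spans the whole cytoplasm "
                          "(cell_radius - nucleus_radius < band_um)")


def gen_compartment_image(config: CompartmentGenConfig):
    """Render a two-channel image with known compartment signal fractions.

    Returns ``(image, masks)`` where ``image`` is a
    :class:`cimquant.compartments.CompartmentImage` and ``masks`` holds the
    ground-truth boolean masks (``nuclear``, ``perinuclear``, ``cyto``,
    ``cell``).  Before noise, the marker signal integrated over each
    ground-truth compartment matches ``target_fractions`` exactly (up to
    float rounding); compartments are piecewise-constant in intensity.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    n_side = int(np.ceil(np.sqrt(cfg.n_nuclei)))
    pitch_y, pitch_x = h / n_side, w / n_side
    r_cell_px = cfg.cell_radius / cfg.pixel_size
    if min(pitch_x, pitch_y) / 2.0 <= r_cell_px:
        raise ValueError("cells would overlap: reduce n_nuclei or cell_radius")
    yy, xx = np.mgrid[0:h, 0:w]
    nuclear = np.zeros((h, w), dtype=bool)
    cell = np.zeros((h, w), dtype=bool)
    centers = []
    for i in range(cfg.n_nuclei):
        r, c = divmod(i, n_side)
        cy, cx = (r + 0.5) * pitch_y, (c + 0.5) * pitch_x
        centers.append((cy, cx))
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nuclear |= d2 <= (cfg.nucleus_radius / cfg.pixel_size) ** 2
        cell |= d2 <= r_cell_px ** 2
    band = perinuclear_band(nuclear, cfg.pixel_size, cfg.band_um)
    peri = band & cell
    cyto = cell & ~nuclear & ~band
    masks = {"nuclear": nuclear, "perinuclear": peri, "cyto": cyto, "cell": cell}

    marker = np.zeros((h, w))
    intensities = []
    for frac, mask in zip(cfg.target_fractions, (nuclear, peri, cyto)):
        npix = int(mask.sum())
        if frac > 0 and npix == 0:
            raise ValueError("a compartment with positive target fraction has no pixels")
        level = frac / npix if npix else 0.0
        intensities.append(level)
        marker[mask] = level
    peak = max(intensities) or 1.0
    marker /= peak  # brightest compartment at intensity 1
    nuclear_dye = nuclear.astype(float)
    if cfg.noise_sd > 0:
        marker = marker + rng.normal(0.0, cfg.noise_sd, marker.shape)
        nuclear_dye = nuclear_dye + rng.normal(0.0, cfg.noise_sd, marker.shape)
    image = CompartmentImage(nuclear_channel=nuclear_dye, marker_channel=marker,
                             pixel_size=cfg.pixel_size,
                             image_id=f"sim-seed{cfg.seed}")
    return image, masks


# ---------------------------------------------------------------------------
# CSV / TIFF export (the on-disk formats the CLI stages consume)

def write_scratch_csv(field: ScratchField, true_angles, cells_path, rim_path) -> None:
    rows = [{"field_id": field.field_id, "object_type": "nucleus",
             "x_um": x, "y_um": y, "true_angle_deg": a}
            for (x, y), a in zip(field.nuclei, true_angles)]
    rows += [{"field_id": field.field_id, "object_type": "golgi",
              "x_um": x, "y_um": y, "true_angle_deg": np.nan}
             for x, y in field.golgi]
    pd.DataFrame(rows).to_csv(cells_path, index=False)
    rim_rows = [{"field_id": field.field_id, "role": "rim", "vertex_order": i,
                 "x_um": x, "y_um": y}
                for i, (x, y) in enumerate(field.rim)]
    rim_rows.append({"field_id": field.field_id, "role": "wound_side",
                     "vertex_order": 0, "x_um": field.wound_side_point[0],
                     "y_um": field.wound_side_point[1]})
    pd.DataFrame(rim_rows).to_csv(rim_path, index=False)


def write_section_csv(patterns, cells_path, polygons_path) -> None:
    cell_rows, poly_rows = [], []
    for pat in patterns:
        for (x, y), pop in zip(pat.xy, pat.population):
            cell_rows.append({"section_id": pat.section_id,
                              "tumor_id": pat.tumor_id or "", "day": pat.day,
                              "x_um": x, "y_um": y, "population": pop})
        for i, (x, y) in enumerate(pat.rim_polygon):
            poly_rows.append({"section_id": pat.section_id, "role": "rim",
                              "vertex_order": i, "x_um": x, "y_um": y})
    pd.DataFrame(cell_rows).to_csv(cells_path, index=False)
    pd.DataFrame(poly_rows).to_csv(polygons_path, index=False)


def write_timecourse_csv(section_table: pd.DataFrame, path) -> None:
    section_table.to_csv(path, index=False)


def write_compartment_tiff(image, config: CompartmentGenConfig, tiff_path,
                           sidecar_path=None) -> None:
    """Two-page TIFF (nuclear, marker) with pixel-size metadata and a JSON
    sidecar recording the generator's ground-truth parameters."""
    import json

    import tifffile

    stack = np.stack([image.nuclear_channel, image.marker_channel]).astype("float32")
    ppu = 1.0 / image.pixel_size  # pixels per micrometre
    tifffile.imwrite(tiff_path, stack, resolution=(ppu, ppu),
                     resolutionunit="NONE",
                     metadata={"pixel_size_um": image.pixel_size})
    if sidecar_path is not None:
        truth = {"pixel_size_um": config.pixel_size,
                 "target_fractions": list(config.target_fractions),
                 "n_nuclei": config.n_nuclei,
                 "nucleus_radius_um": config.nucleus_radius,
                 "cell_radius_um": config.cell_radius,
                 "band_um": config.band_um,
                 "noise_sd": config.noise_sd, "seed": config.seed}
        Path(sidecar_path).write_text(json.dumps(truth, indent=2))
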