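"""In vivo infiltration quantification for two-population competition assays.

Silenced (GFP) and control (DsRed) tumour cells are co-injected and their
positions digitised per brain section together with the injection-site rim.
For each cell outside the needle track the distance to the rim is measured;
because the maximum distance walked varies strongly between sections, each
section's distances are normalised into 10 equal-width bins before pooling.
The silenced/control count ratio per bin, and the Pearson correlation of
that ratio against bin index, quantify whether the silenced population is
depleted far from the injection site.  A second stage follows tumour
composition (fraction of silenced cells) over time post injection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Polygon

__all__ = [
    "SectionPointPattern",
    "BinEnrichment",
    "CompositionTimepoint",
    "cell_distances",
    "bin_distances",
    "enrichment_profile",
    "composition_timecourse",
    "read_sections",
]

POPULATIONS = ("silenced", "control")


@dataclass
class SectionPointPattern:
    """Labelled two-population cell coordinates of one brain section."""

    section_id: str
    xy: np.ndarray  # (N, 2) in um
    population: np.ndarray  # (N,) strings from POPULATIONS
    rim_polygon: np.ndarray  # (K, 2) closed ring (first==last not required)
    exclusion_polygon: np.ndarray | None = None  # needle track; defaults to rim
    day: float | None = None
    tumor_id: str | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.population = np.asarray(self.population, dtype=object).reshape(-1)
        if self.xy.shape[0] != self.population.shape[0]:
            raise ValueError("xy and population lengths differ")
        bad = set(self.population) - set(POPULATIONS)
        if bad:
            raise ValueError(f"unknown population labels: {sorted(bad)}")
        self.rim_polygon = np.asarray(self.rim_polygon, dtype=float).reshape(-1, 2)
        poly = Polygon(self.rim_polygon)
        if not poly.is_valid or poly.area == 0:
            raise ValueError(f"section {self.section_id}: degenerate rim polygon")
        if self.exclusion_polygon is not None:
            self.exclusion_polygon = np.asarray(self.exclusion_polygon, dtype=float).reshape(-1, 2)


@dataclass
class BinEnrichment:
    """Pooled per-bin counts, silenced/control ratio and its trend test."""

    n_bins: int
    counts_silenced: np.ndarray
    counts_control: np.ndarray
    ratio: np.ndarray  # NaN where the control count is zero
    pearson_r: float  # signed; NaN when undefined
    p_value: float
    n_defined_bins: int
    sections_used: int
    cells_used: dict
    excluded: dict
    max_distance_per_section: dict

    @property
    def abs_r(self) -> float:
        """Magnitude of the correlation, reported alongside the signed value
        because published enrichment analyses differ in sign convention."""
        return abs(self.pearson_r)


@dataclass
class CompositionTimepoint:
    tumor_id: str
    day: float
    fraction_silenced_mean: float
    fraction_silenced_sem: float
    n_sections: int


# ---------------------------------------------------------------------------

def cell_distances(section: SectionPointPattern):
    """Distance of each cell to the injection-site rim.

    Distance is the minimum Euclidean distance to the rim polygon boundary;
    cells strictly inside the exclusion region (the needle track, by default
    the rim polygon itself) are excluded.  Returns ``(distances, included,
    n_excluded)`` where ``included`` is a boolean mask over the section's
    cells and ``distances`` aligns with ``section.xy[included]``.
    """
    rim = Polygon(section.rim_polygon)
    excl_ring = section.exclusion_polygon
    excl = rim if excl_ring is None else Polygon(excl_ring)
    pts = shapely.points(section.xy)
    inside = shapely.contains(excl, pts)  # strict interior: rim cells stay
    included = ~inside
    dist = shapely.distance(pts[included], rim.exterior)
    n_excluded = int(inside.sum())
    if included.sum() == 0:
        warnings.warn(f"section {section.section_id}: all cells inside the exclusion region")
    return np.asarray(dist, dtype=float), included, n_excluded


def bin_distances(distances, n_bins: int = 10, max_distance: float | None = None):
    """Normalise distances of one section into equal-width bins 1..n_bins.

    The bin width is the section's maximum cell distance (over both
    populations pooled) divided by ``n_bins``; ``bin(d) = ceil(n_bins*d/D)``
    with d=0 mapped to bin 1 and d=D to bin n_bins, so sections with very
    different spreads become comparable.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances to bin")
    if np.any(d < 0):
        raise ValueError("negative distance")
    D = float(d.max()) if max_distance is None else float(max_distance)
    if D == 0:
        warnings.warn("all cells on the rim: every cell assigned to bin 1")
        return np.ones(d.shape, dtype=int)
    b = np.ceil(n_bins * d / D).astype(int)
    b[b < 1] = 1
    b[b > n_bins] = n_bins
    return b


def enrichment_profile(sections, n_bins: int = 10, pseudocount: float = 0.0,
                       alpha: float = 0.01) -> BinEnrichment:
    """Pooled silenced/control enrichment by distance bin with trend test.

    Bins are computed per section (see :func:`bin_distances`) and counts
    pooled across sections.  ``ratio[b] = silenced[b] / control[b]``; bins
    with zero control count are flagged undefined (NaN) and excluded from
    the Pearson correlation of ratio against bin index (two-sided t test,
    df = defined bins - 2).  ``pseudocount`` optionally stabilises the
    ratio for robustness analyses; it is 0 by default so the statistic is
    the plain count ratio.
    """
    counts = {pop: np.zeros(n_bins) for pop in POPULATIONS}
    excluded = {pop: 0 for pop in POPULATIONS}
    used = {pop: 0 for pop in POPULATIONS}
    max_d = {}
    n_sections = 0
    for sec in sections:
        dist, included, _n_excl = cell_distances(sec)
        pops = sec.population[included]
        for pop in POPULATIONS:
            excluded[pop] += int((sec.population == pop).sum() - (pops == pop).sum())
        if dist.size == 0:
            continue
        bins = bin_distances(dist, n_bins=n_bins)
        max_d[sec.section_id] = float(dist.max())
        n_sections += 1
        for pop in POPULATIONS:
            sel = pops == pop
            counts[pop] += np.bincount(bins[sel] - 1, minlength=n_bins)
            used[pop] += int(sel.sum())
    cs = counts["silenced"] + pseudocount
    cc = counts["control"] + pseudocount
    defined = cc > 0
    ratio = np.full(n_bins, np.nan)
    ratio[defined] = cs[defined] / cc[defined]
    n_def = int(defined.sum())
    if n_def < 3:
        raise ValueError(f"only {n_def} bins have a defined ratio; need >= 3 "
                         "for the trend test")
    idx = np.arange(1, n_bins + 1)[defined]
    vals = ratio[defined]
    if np.ptp(vals) == 0:  # constant ratio: correlation undefined by convention
        r, p = np.nan, 1.0
    else:
        r, p = stats.pearsonr(idx, vals)
    return BinEnrichment(
        n_bins=n_bins, counts_silenced=counts["silenced"],
        counts_control=counts["control"], ratio=ratio, pearson_r=float(r),
        p_value=float(p), n_defined_bins=n_def, sections_used=n_sections,
        cells_used=used, excluded=excluded, max_distance_per_section=max_d)


# ---------------------------------------------------------------------------
# tumour composition over time

def composition_timecourse(section_counts: pd.DataFrame):
    """Tumour composition (fraction silenced) over days post injection.

    ``section_counts`` has one row per section with columns ``tumor_id``,
    ``day``, ``n_silenced``, ``n_control``.  Per-section fractions are
    averaged per tumour (mean +/- SEM across sections, the intra-tumoral
    variability), then the trend is a Pearson correlation of per-tumour mean
    fraction against day, two-sided p.

    Returns ``(timepoints, r, p)`` with one :class:`CompositionTimepoint`
    per tumour.
    """
    df = section_counts.copy()
    total = df["n_silenced"] + df["n_control"]
    if (total == 0).any():
        bad = df.loc[total == 0, "tumor_id"].tolist()
        raise ValueError(f"sections with zero cells in tumors: {bad}")
    df["fraction"] = df["n_silenced"] / total
    points = []
    for (tid, day), grp in df.groupby(["tumor_id", "day"], sort=True):
        frac = grp["fraction"].to_numpy()
        sem = float(stats.sem(frac)) if frac.size > 1 else 0.0
        points.append(CompositionTimepoint(
            tumor_id=str(tid), day=float(day),
            fraction_silenced_mean=float(frac.mean()),
            fraction_silenced_sem=sem, n_sections=int(frac.size)))
    days = np.array([p.day for p in points])
    means = np.array([p.fraction_silenced_mean for p in points])
    if len(points) < 3 or np.unique(days).size < 2:
        raise ValueError("need >= 3 tumors at >= 2 distinct days for the trend test")
    if np.ptp(means) == 0 or np.ptp(days) == 0:
        r, p = np.nan, 1.0
    else:
        r, p = stats.pearsonr(days, means)
    return points, float(r), float(p)


def section_counts(sections) -> pd.DataFrame:
    """Per-section population counts (outside the exclusion region) for
    :func:`composition_timecourse`."""
    rows = []
    for sec in sections:
        _d, included, _n = cell_distances(sec)
        pops = sec.population[included]
        rows.append({"tumor_id": sec.tumor_id, "day": sec.day,
                     "section_id": sec.section_id,
                     "n_silenced": int((pops == "silenced").sum()),
                     "n_control": int((pops == "control").sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV input

def read_sections(cells_csv, polygons_csv) -> list[SectionPointPattern]:
    """Load sections from coordinate CSVs.

    ``cells_csv`` columns: section_id, tumor_id, day, x_um, y_um,
    population.  ``polygons_csv`` columns: section_id, role in {rim,
    needle}, vertex_order, x_um, y_um.
    """
    cells = pd.read_csv(cells_csv)
    polys = pd.read_csv(polygons_csv)
    sections = []
    for sid, grp in cells.groupby("section_id", sort=True):
        pg = polys[polys["section_id"] == sid]
        rim = pg[pg["role"] == "rim"].sort_values("vertex_order")[["x_um", "y_um"]].to_numpy()
        needle = pg[pg["role"] == "needle"].sort_values("vertex_order")[["x_um", "y_um"]].to_numpy()
        sections.append(SectionPointPattern(
            section_id=str(sid), xy=grp[["x_um", "y_um"]].to_numpy(),
            population=grp["population"].to_numpy(),
            rim_polygon=rim,
            exclusion_polygon=needle if needle.shape[0] >= 3 else None,
            day=float(grp["day"].iloc[0]) if "day" in grp else None,
            tumor_id=str(grp["tumor_id"].iloc[0]) if "tumor_id" in grp else None))
    return sections
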