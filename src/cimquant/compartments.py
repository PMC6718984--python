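"""Nuclear / perinuclear / cytoplasmic partitioning of a fluorescence marker.

Field-level quantification of where a marker (e.g. beta-catenin) sits in the
cell: the nuclear area comes from thresholding the nuclear dye channel, the
perinuclear region is the 3 um band surrounding the nuclear areas (computed
by thresholding the Euclidean distance transform, so the band width is
physical and resolution-consistent rather than an integer number of dilation
rounds), and the cytoplasmic/membrane compartment is the remaining cell
area.  Fractions of total marker signal per compartment sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "CompartmentImage",
    "CompartmentFractions",
    "nuclear_mask",
    "perinuclear_band",
    "compartment_fractions",
    "compare_conditions",
]


@dataclass
class CompartmentImage:
    """Two-channel field with physical pixel size (um/pixel)."""

    nuclear_channel: np.ndarray
    marker_channel: np.ndarray
    pixel_size: float
    cell_mask: np.ndarray | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        self.nuclear_channel = np.asarray(self.nuclear_channel, dtype=float)
        self.marker_channel = np.asarray(self.marker_channel, dtype=float)
        if self.nuclear_channel.shape != self.marker_channel.shape:
            raise ValueError("channel shapes differ")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.cell_mask is not None:
            self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
            if self.cell_mask.shape != self.marker_channel.shape:
                raise ValueError("cell_mask shape differs from channels")


@dataclass
class CompartmentFractions:
    """Marker-signal fractions per compartment; they sum to 1."""

    f_nuclear: float
    f_perinuclear: float
    f_cytoplasmic: float
    band_um: float
    threshold_method: str
    background_level: float
    image_id: str = ""

    def as_dict(self) -> dict:
        return {"image_id": self.image_id, "f_nuclear": self.f_nuclear,
                "f_perinuclear": self.f_perinuclear,
                "f_cytoplasmic": self.f_cytoplasmic, "band_um": self.band_um,
                "threshold_method": self.threshold_method,
                "background_level": self.background_level}


def nuclear_mask(nuclear_channel, method: str = "otsu",
                 threshold: float | None = None, min_area: int = 20,
                 fill_holes: bool = True) -> np.ndarray:
    """Nuclear segmentation by global thresholding of the nuclear dye.

    ``method`` is 'otsu' (default), 'fixed' (requires ``threshold``) or
    'local' (Niblack-style local mean via a 51-pixel uniform filter).  Holes
    are filled and objects below ``min_area`` pixels removed.
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(nuclear_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        mask = img > threshold
    elif method == "otsu":
        if img.max() == img.min():
            raise ValueError("uniform image: no foreground to threshold")
        mask = img > threshold_otsu(img)
    elif method == "local":
        mask = img > ndimage.uniform_filter(img, size=51)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if min_area > 0:
        lab, n = ndimage.label(mask)
        if n:
            sizes = np.bincount(lab.ravel())
            mask = sizes[lab] >= min_area
            mask[lab == 0] = False
    if not mask.any():
        raise ValueError("empty nuclear mask (threshold removed all foreground)")
    return mask


def perinuclear_band(nuclear: np.ndarray, pixel_size: float,
                     band_um: float = 3.0) -> np.ndarray:
    """Pixels within ``band_um`` micrometres outside the nuclear mask.

    Uses the Euclidean distance transform with physical sampling, so the
    threshold is sub-pixel: a pixel belongs to the band iff its centre is
    within ``band_um`` of the nearest nuclear pixel centre.
    """
    if band_um < 0:
        raise ValueError("band_um must be >= 0")
    nuclear = np.asarray(nuclear, dtype=bool)
    if band_um == 0:
        return np.zeros_like(nuclear)
    if band_um < pixel_size:
        warnings.warn("perinuclear band narrower than one pixel; may be empty")
    edt = ndimage.distance_transform_edt(~nuclear, sampling=pixel_size)
    return (~nuclear) & (edt <= band_um + 1e-9)


def compartment_fractions(image: CompartmentImage, band_um: float = 3.0,
                          nuclear: np.ndarray | None = None,
                          threshold_method: str = "otsu",
                          subtract_background: bool = True,
                          min_nucleus_area: int = 20) -> CompartmentFractions:
    """Partition the marker signal into nuclear, perinuclear and
    cytoplasmic/membrane fractions of the total cell-area signal.

    Cell area is the provided ``image.cell_mask`` when given, otherwise the
    thresholded marker channel united with the nuclear mask (the marker is
    assumed to fill the cell).  Background, estimated as the median marker
    intensity outside the cell area, is subtracted and negatives clipped to
    zero before integrating.  Compartments partition the cell area exactly:
    nuclear, then the perinuclear band clipped to the cell, then the rest.
    """
    from skimage.filters import threshold_otsu

    marker = image.marker_channel
    if nuclear is None:
        nuclear = nuclear_mask(image.nuclear_channel, method=threshold_method,
                               min_area=min_nucleus_area)
    nuclear = np.asarray(nuclear, dtype=bool)
    if image.cell_mask is not None:
        cell = image.cell_mask | nuclear
    else:
        cell = (marker > threshold_otsu(marker)) | nuclear
    band = perinuclear_band(nuclear, image.pixel_size, band_um)

    if subtract_background and (~cell).any():
        background = float(np.median(marker[~cell]))
    else:
        background = 0.0
    signal = np.clip(marker - background, 0.0, None)

    nuc = nuclear & cell
    peri = band & cell & ~nuc
    cyto = cell & ~nuc & ~band
    if not cyto.any():
        warnings.warn("no cytoplasmic area: cell area equals nuclear + band")
    total = float(signal[cell].sum())
    if total <= 0:
        raise ValueError("no marker signal within the cell area")
    fractions = np.array([signal[m].sum() for m in (nuc, peri, cyto)]) / total
    return CompartmentFractions(
        f_nuclear=float(fractions[0]), f_perinuclear=float(fractions[1]),
        f_cytoplasmic=float(fractions[2]), band_um=band_um,
        threshold_method=threshold_method, background_level=background,
        image_id=image.image_id)


COMPARTMENT_COLUMNS = ("f_nuclear", "f_perinuclear", "f_cytoplasmic")


def compare_conditions(fractions: pd.DataFrame, condition_col: str = "condition",
                       method: str = "welch") -> pd.DataFrame:
    """Per-compartment two-sample comparison between two conditions.

    ``fractions`` holds one row per image with the three fraction columns
    and a two-level condition column (e.g. control vs silenced).  The
    default test is Welch's t; ``method='ranksum'`` uses Mann-Whitney U.
    Effect is mean(second level) - mean(first level) with levels in sorted
    order.  No multiplicity correction is applied (three related
    compartments of the same signal).
    """
    levels = sorted(fractions[condition_col].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {levels}")
    a = fractions[fractions[condition_col] == levels[0]]
    b = fractions[fractions[condition_col] == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 images per condition for a test")
    rows = []
    for col in COMPARTMENT_COLUMNS:
        x, y = a[col].to_numpy(), b[col].to_numpy()
        effect = float(y.mean() - x.mean())
        if method == "welch":
            if x.var() == 0 and y.var() == 0:  # degenerate: no within-group spread
                t, p = (0.0, 1.0) if effect == 0 else (np.inf, 0.0)
            else:
                t, p = stats.ttest_ind(y, x, equal_var=False)
        elif method == "ranksum":
            t, p = stats.mannwhitneyu(y, x, alternative="two-sided")
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"compartment": col, "effect": effect,
                     "statistic": float(t), "p_value": float(p),
                     "method": method,
                     "reference": levels[0], "comparison": levels[1]})
    return pd.DataFrame(rows)
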