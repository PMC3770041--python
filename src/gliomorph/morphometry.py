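"""Per-nucleus and per-field morphometry on calibrated label images.

Seven parameters are measured.  Per nucleus: major axis (MAJX, µm),
minor axis (MINX, µm) of the moment-equivalent ellipse, nuclear area
(NA, µm²), nuclear perimeter (NP, µm) and nuclear roundness
NR = (4*pi*NA / NP^2) * 100, which is 100 for a perfect circle and
smaller for irregular outlines.  Per field: nuclear density (ND, nuclei
per mm² of field area) and percent total nuclear area (%TNA, percent of
field pixels covered by nuclei).

The perimeter estimator is a weighted contour: the 0.5-level
marching-squares boundary of the binary mask, smoothed by a circular
moving average over five contour points, measured as a closed polyline.
The naive boundary-pixel count overestimates circle perimeters by up to
~27%; the smoothed contour stays within 1% of the true circumference for
digitized disks of radius >= 10 px, which keeps NR of disks in [98, 102].
For a single-pixel region the estimator returns the smoothed unit-pixel
diamond, ~0.566 px (≈ 2*sqrt(2)/5) times the pixel pitch.

Selection rules mirror routine practice on histology fields: the five
fields of maximum cellularity, and per case the 100 largest nuclei that
are clearly separated (no 8-adjacent foreign label) and do not touch the
raster border.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage import measure as skmeasure

from .config import InvalidParameterError

logger = logging.getLogger("gliomorph")

#: Circular moving-average window (contour points) of the perimeter estimator.
PERIMETER_SMOOTHING_WINDOW = 5


class EmptyRegionError(ValueError):
    """The requested region has no pixels."""


class DegenerateRegionError(ValueError):
    """The region is too small or collinear for shape measurement."""


class DisconnectedRegionError(ValueError):
    """Perimeter is defined for a single connected region only."""


@dataclass
class CalibrationSpec:
    """Physical calibration of a label raster."""

    microns_per_pixel: float

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise InvalidParameterError("microns_per_pixel must be > 0")

    def field_area_mm2(self, shape: tuple[int, int]) -> float:
        h, w = shape
        return h * w * self.microns_per_pixel**2 / 1.0e6


@dataclass
class NucleusRecord:
    """Measured shape parameters of one nucleus."""

    sample_id: str
    field_id: int
    label_id: int
    majx_um: float
    minx_um: float
    na_um2: float
    np_um: float
    nr_pct: float
    border_touching: bool
    separated: bool


@dataclass
class FieldRecord:
    """Measured density parameters of one field."""

    sample_id: str
    field_id: int
    nucleus_count: int
    nd_per_mm2: float
    tna_pct: float
    nuclei: list[NucleusRecord] = dc_field(default_factory=list, repr=False)


def nucleus_area(mask: np.ndarray, cal: CalibrationSpec) -> float:
    """NA: pixel count times the pixel area."""
    count = int(np.count_nonzero(mask))
    if count == 0:
        raise EmptyRegionError("empty region")
    return count * cal.microns_per_pixel**2


def nucleus_perimeter(mask: np.ndarray, cal: CalibrationSpec) -> float:
    """NP via the smoothed marching-squares contour (see module docstring)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyRegionError("empty region")
    if skmeasure.label(mask, connectivity=2).max() > 1:
        raise DisconnectedRegionError("region is not connected")
    contours = skmeasure.find_contours(np.pad(mask, 1).astype(float), 0.5)
    total = 0.0
    for c in contours:
        c = c[:-1]  # closed contour: last point repeats the first
        if len(c) > 2:
            c = np.column_stack([
                uniform_filter1d(c[:, 0], PERIMETER_SMOOTHING_WINDOW, mode="wrap"),
                uniform_filter1d(c[:, 1], PERIMETER_SMOOTHING_WINDOW, mode="wrap"),
            ])
        d = np.diff(np.vstack([c, c[:1]]), axis=0)
        total += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return total * cal.microns_per_pixel


def nucleus_axes(mask: np.ndarray, cal: CalibrationSpec) -> tuple[float, float]:
    """(MAJX, MINX): axes of the moment-equivalent ellipse.

    ``4 * sqrt(eigenvalues)`` of the pixel-coordinate covariance matrix,
    scaled to microns — exact for ideal filled ellipses and stable under
    rotation, unlike Feret (caliper) diameters.
    """
    mask = np.asarray(mask).astype(np.uint8)
    if np.count_nonzero(mask) < 3:
        raise DegenerateRegionError("need >= 3 pixels for axes")
    props = skmeasure.regionprops(mask)[0]
    major = props.axis_major_length * cal.microns_per_pixel
    minor = props.axis_minor_length * cal.microns_per_pixel
    if minor == 0:
        raise DegenerateRegionError("collinear region has no minor axis")
    return float(major), float(minor)


def nuclear_roundness(na: float, np_: float) -> float:
    """NR = (4*pi*NA / NP^2) * 100; 100 for a perfect circle."""
    if na < 0 or np_ < 0:
        raise InvalidParameterError("area and perimeter must be >= 0")
    if np_ == 0:
        raise ZeroDivisionError("zero perimeter")
    if na == 0:
        raise InvalidParameterError("area must be > 0")
    return float(4.0 * np.pi * na / np_**2 * 100.0)


def _crop_with_context(label_image: np.ndarray, label_id: int):
    """Mask crop padded by one pixel of surrounding labels."""
    rows, cols = np.nonzero(label_image == label_id)
    if rows.size == 0:
        raise KeyError(f"label {label_id} not present")
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    h, w = label_image.shape
    rr0, cc0 = max(r0 - 1, 0), max(c0 - 1, 0)
    crop = label_image[rr0:min(r1 + 2, h), cc0:min(c1 + 2, w)]
    border = r0 == 0 or c0 == 0 or r1 == h - 1 or c1 == w - 1
    return crop, border


def _measure_from_crop(crop: np.ndarray, label_id: int, border: bool,
                       cal: CalibrationSpec, sample_id: str,
                       field_id: int) -> NucleusRecord:
    mask = crop == label_id
    na = nucleus_area(mask, cal)
    np_um = nucleus_perimeter(mask, cal)
    majx, minx = nucleus_axes(mask, cal)
    # 8-adjacency to any foreign nonzero label breaks "clearly separated"
    grown = np.zeros_like(mask)
    r, c = np.nonzero(mask)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            rr = np.clip(r + dr, 0, mask.shape[0] - 1)
            cc = np.clip(c + dc, 0, mask.shape[1] - 1)
            grown[rr, cc] = True
    neighbours = crop[grown & ~mask]
    separated = not np.any((neighbours != 0) & (neighbours != label_id))
    return NucleusRecord(
        sample_id=sample_id, field_id=field_id, label_id=int(label_id),
        majx_um=majx, minx_um=minx, na_um2=na, np_um=np_um,
        nr_pct=nuclear_roundness(na, np_um),
        border_touching=bool(border), separated=bool(separated),
    )


def measure_nucleus(label_id: int, label_image: np.ndarray,
                    cal: CalibrationSpec, sample_id: str = "",
                    field_id: int = 0) -> NucleusRecord:
    """Measure one labelled nucleus (raises ``KeyError`` if absent)."""
    crop, border = _crop_with_context(label_image, label_id)
    return _measure_from_crop(crop, label_id, border, cal, sample_id, field_id)


def measure_field(label_image: np.ndarray, cal: CalibrationSpec,
                  sample_id: str = "", field_id: int = 0) -> FieldRecord:
    """Measure every nucleus of a field plus ND and %TNA.

    ND and %TNA count all nuclei and all nonzero pixels regardless of the
    separation/border flags (those pixels exist in the field); nuclei too
    small or degenerate for shape measurement are counted in ND/%TNA but
    excluded from the per-nucleus records, with a logged warning.
    """
    label_image = np.asarray(label_image)
    if label_image.size == 0:
        raise InvalidParameterError("zero-sized image")
    area_mm2 = cal.field_area_mm2(label_image.shape)
    nonzero = int(np.count_nonzero(label_image))
    tna = 100.0 * nonzero / label_image.size
    records: list[NucleusRecord] = []
    props = skmeasure.regionprops(label_image)
    h, w = label_image.shape
    for p in props:
        r0, c0, r1, c1 = p.bbox
        rr0, cc0 = max(r0 - 1, 0), max(c0 - 1, 0)
        crop = label_image[rr0:min(r1 + 1, h), cc0:min(c1 + 1, w)]
        border = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        try:
            records.append(_measure_from_crop(crop, p.label, border, cal,
                                              sample_id, field_id))
        except (DegenerateRegionError, DisconnectedRegionError) as exc:
            logger.warning("%s field %d label %d skipped: %s",
                           sample_id, field_id, p.label, exc)
    count = len(props)
    return FieldRecord(
        sample_id=sample_id, field_id=field_id, nucleus_count=count,
        nd_per_mm2=count / area_mm2, tna_pct=tna, nuclei=records,
    )


def select_fields(fields: list[FieldRecord], k: int = 5) -> list[FieldRecord]:
    """The ``k`` fields of maximum cellularity (ties: lower field_id)."""
    if not fields:
        raise InvalidParameterError("no fields to select from")
    ranked = sorted(fields, key=lambda f: (-f.nucleus_count, f.field_id))
    if len(fields) < k:
        logger.warning("only %d fields available (requested %d)",
                       len(fields), k)
        return ranked
    return ranked[:k]


def select_nuclei(records: list[NucleusRecord],
                  n: int = 100) -> list[NucleusRecord]:
    """The ``n`` largest clearly-separated, non-border nuclei by NA.

    Mirrors the manual convention of choosing nuclei "clearly separated
    from others and relatively larger in size"; the size bias of taking
    the largest is deliberate and documented.
    """
    eligible = [r for r in records if r.separated and not r.border_touching]
    eligible.sort(key=lambda r: (-r.na_um2, r.field_id, r.label_id))
    if len(eligible) < n:
        logger.warning("only %d eligible nuclei (requested %d)",
                       len(eligible), n)
    return eligible[:n]


def summarize_sample(sample_id: str, group: str, grade_code: int,
                     fields: list[FieldRecord],
                     selected_nuclei: list[NucleusRecord],
                     age_years: float | None = None):
    """Per-sample means: shape parameters over the selected nuclei, ND and
    %TNA over the selected fields.  Returns a ``SampleRecord``."""
    from .stats import SampleRecord

    if not fields or not selected_nuclei:
        raise InvalidParameterError(
            "need at least one field and one selected nucleus")
    return SampleRecord(
        sample_id=sample_id, group=group, grade_code=grade_code,
        mean_majx=float(np.mean([r.majx_um for r in selected_nuclei])),
        mean_minx=float(np.mean([r.minx_um for r in selected_nuclei])),
        mean_na=float(np.mean([r.na_um2 for r in selected_nuclei])),
        mean_np=float(np.mean([r.np_um for r in selected_nuclei])),
        mean_nr=float(np.mean([r.nr_pct for r in selected_nuclei])),
        mean_nd=float(np.mean([f.nd_per_mm2 for f in fields])),
        mean_tna=float(np.mean([f.tna_pct for f in fields])),
        age_years=age_years,
    )
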