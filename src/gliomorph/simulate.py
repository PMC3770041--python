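"""Synthetic cohort generation: placement and rasterization of nucleus fields.

Each simulated case draws a per-sample mean nuclear area and a placement
density from the between-sample distributions of its group, then fills
``fields_per_sample`` high-power fields with non-overlapping nuclei
(rejection sampling, minimum inter-boundary gap of one pixel).  Pixel
membership in the rendered label raster is pixel-center-in-polygon; the
physical origin sits at the top-left pixel center, x along columns and y
along rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .config import CohortConfig, GroupSpec, InvalidParameterError
from .shapes import GroundTruthNucleus, generate_nucleus_polygon

logger = logging.getLogger("gliomorph")

#: Rejection-sampling cap per nucleus; beyond this the field is emitted
#: with fewer nuclei (density saturation at very high ND).
MAX_PLACEMENT_ATTEMPTS = 1000


class PlacementError(ValueError):
    """Nuclei overlap or leave the field bounds."""


@dataclass
class SimulatedField:
    """One rendered high-power field with its ground truth."""

    sample_id: str
    field_id: int
    label_image: np.ndarray = dc_field(repr=False)
    nuclei: list[GroundTruthNucleus] = dc_field(repr=False)
    requested_count: int = 0
    field_mean_area_um2: float = float("nan")

    @property
    def placed_count(self) -> int:
        return len(self.nuclei)


@dataclass
class SimulatedSample:
    """One simulated case: drawn parameters plus its fields."""

    sample_id: str
    group: str
    grade_code: int
    mean_area_um2: float
    density_per_mm2: float
    fields: list[SimulatedField] = dc_field(repr=False)


@dataclass
class SyntheticCohort:
    """A full simulated study with per-nucleus ground truth."""

    config: CohortConfig
    samples: list[SimulatedSample]

    def ground_truth_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            for f in s.fields:
                for nuc in f.nuclei:
                    rows.append({
                        "sample_id": nuc.sample_id,
                        "field_id": nuc.field_id,
                        "label_id": nuc.label_id,
                        "centroid_x_um": nuc.centroid[0],
                        "centroid_y_um": nuc.centroid[1],
                        "true_area_um2": nuc.true_area_um2,
                        "true_perimeter_um": nuc.true_perimeter_um,
                        "true_majx_um": nuc.true_majx_um,
                        "true_minx_um": nuc.true_minx_um,
                        "true_nr": nuc.true_nr,
                    })
        return pd.DataFrame(rows)

    def sample_manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "grade_code": s.grade_code,
                "mean_area_um2": s.mean_area_um2,
                "density_per_mm2": s.density_per_mm2,
            }
            for s in self.samples
        ])

    def field_manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "sample_id": f.sample_id,
                "field_id": f.field_id,
                "field_mean_area_um2": f.field_mean_area_um2,
                "requested_count": f.requested_count,
                "placed_count": f.placed_count,
            }
            for s in self.samples
            for f in s.fields
        ])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int | None = None) -> np.ndarray | float:
    """Normal(mean, sd) redrawn until > 0 (sd == 0 returns the mean)."""
    if sd == 0:
        return mean if size is None else np.full(size, mean)
    n = 1 if size is None else size
    out = rng.normal(mean, sd, n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out <= 0
    return float(out[0]) if size is None else out


def _rasterize(poly: Polygon, shape: tuple[int, int], mpp: float,
               image: np.ndarray, label: int) -> None:
    """Write ``label`` into every pixel whose center lies inside ``poly``."""
    h, w = shape
    xmin, ymin, xmax, ymax = poly.bounds
    j0 = max(int(np.ceil(xmin / mpp)), 0)
    j1 = min(int(np.floor(xmax / mpp)), w - 1)
    i0 = max(int(np.ceil(ymin / mpp)), 0)
    i1 = min(int(np.floor(ymax / mpp)), h - 1)
    if j1 < j0 or i1 < i0:
        return
    jj, ii = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1))
    inside = shapely.contains_xy(poly, jj.ravel() * mpp, ii.ravel() * mpp)
    image[ii.ravel()[inside], jj.ravel()[inside]] = label


def render_field(nuclei: list[GroundTruthNucleus],
                 config: CohortConfig) -> np.ndarray:
    """Rasterize placed nuclei into an integer label image.

    Raises :class:`PlacementError` if any polygon leaves the field bounds
    or two polygons come closer than one pixel (the simulator's
    separation contract), and :class:`InvalidParameterError` if the label
    count exceeds the 16-bit raster capacity.
    """
    shape = config.raster_shape
    mpp = config.microns_per_pixel
    if len(nuclei) > np.iinfo(np.uint16).max:
        raise InvalidParameterError(
            f"{len(nuclei)} labels exceed uint16 raster capacity")
    image = np.zeros(shape, dtype=np.uint16)
    if not nuclei:
        return image

    polys = [Polygon(n.boundary) for n in nuclei]
    bounds = np.array([p.bounds for p in polys])
    w_um, h_um = config.field_width_um, config.field_height_um
    if (bounds[:, 0] < 0).any() or (bounds[:, 1] < 0).any() \
            or (bounds[:, 2] > w_um).any() or (bounds[:, 3] > h_um).any():
        raise PlacementError("a polygon lies outside the field bounds")
    # pairwise separation: bbox prefilter, exact distance on candidates
    for i, p in enumerate(polys):
        near = np.flatnonzero(
            (bounds[:i, 0] < bounds[i, 2] + mpp)
            & (bounds[:i, 2] > bounds[i, 0] - mpp)
            & (bounds[:i, 1] < bounds[i, 3] + mpp)
            & (bounds[:i, 3] > bounds[i, 1] - mpp)
        )
        for j in near:
            if p.distance(polys[j]) < mpp:
                raise PlacementError(
                    f"nuclei {j} and {i} violate the 1-px separation gap")
    for label, (nuc, poly) in enumerate(zip(nuclei, polys), start=1):
        _rasterize(poly, shape, mpp, image, label)
    return image


def _place_field(areas: np.ndarray, spec: GroupSpec, config: CohortConfig,
                 rng: np.random.Generator, sample_id: str,
                 field_id: int) -> list[GroundTruthNucleus]:
    """Place nuclei of the given areas without overlap; drops the ones
    that cannot be placed within the attempt cap."""
    mpp = config.microns_per_pixel
    gap = mpp
    w_um, h_um = config.field_width_um, config.field_height_um
    placed: list[GroundTruthNucleus] = []
    placed_polys: list[Polygon] = []
    placed_bounds: list[tuple[float, float, float, float]] = []
    bounds_arr = np.empty((0, 4))

    for area in areas:
        aspect = max(1.0, rng.normal(spec.aspect_ratio_mean, spec.aspect_ratio_sd))
        proto = generate_nucleus_polygon(float(area), aspect,
                                         spec.irregularity, rng)
        proto = proto.rotated(rng.uniform(0.0, np.pi))
        b = proto.boundary
        half_w = (b[:, 0].max() - b[:, 0].min()) / 2.0
        half_h = (b[:, 1].max() - b[:, 1].min()) / 2.0
        off_x = -(b[:, 0].max() + b[:, 0].min()) / 2.0  # bbox-centre shift
        off_y = -(b[:, 1].max() + b[:, 1].min()) / 2.0
        lo_x, hi_x = gap + half_w, w_um - gap - half_w
        lo_y, hi_y = gap + half_h, h_um - gap - half_h
        if hi_x <= lo_x or hi_y <= lo_y:
            logger.warning("%s field %d: nucleus larger than field, skipped",
                           sample_id, field_id)
            continue
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            cx = rng.uniform(lo_x, hi_x)
            cy = rng.uniform(lo_y, hi_y)
            cand = proto.translated(cx + off_x, cy + off_y)
            cb = cand.boundary
            cbounds = (cb[:, 0].min(), cb[:, 1].min(),
                       cb[:, 0].max(), cb[:, 1].max())
            if bounds_arr.size:
                near = np.flatnonzero(
                    (bounds_arr[:, 0] < cbounds[2] + gap)
                    & (bounds_arr[:, 2] > cbounds[0] - gap)
                    & (bounds_arr[:, 1] < cbounds[3] + gap)
                    & (bounds_arr[:, 3] > cbounds[1] - gap)
                )
            else:
                near = ()
            cand_poly = None
            ok = True
            if len(near):
                cand_poly = Polygon(cb)
                for j in near:
                    if cand_poly.distance(placed_polys[j]) < gap:
                        ok = False
                        break
            if ok:
                cand.sample_id = sample_id
                cand.field_id = field_id
                cand.label_id = len(placed) + 1
                placed.append(cand)
                placed_polys.append(cand_poly if cand_poly is not None
                                    else Polygon(cb))
                placed_bounds.append(cbounds)
                bounds_arr = np.asarray(placed_bounds)
                break
        else:
            logger.warning(
                "%s field %d: placement cap hit, nucleus dropped "
                "(density saturation)", sample_id, field_id)
    return placed


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic study described by ``config``.

    Sampling hierarchy per case: per-sample mean nuclear area ~
    truncated Normal(na_mean, na_sd); placement density ~ truncated
    Normal(density_mean, density_sd); per field, a field mean area ~
    truncated Normal(sample mean, field_cv * sample mean), a nucleus
    count ~ Poisson(density * field area) and nucleus areas ~ truncated
    Normal(field mean, within_sample_cv * field mean).  Fully
    reproducible for a given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    field_area = config.field_area_mm2
    samples: list[SimulatedSample] = []
    for spec in config.group_specs:
        codes = sorted(spec.grade_codes)
        probs = np.array([spec.grade_codes[c] for c in codes], dtype=float)
        for k in range(spec.n_samples):
            sample_id = f"{spec.label}{k + 1:02d}"
            grade = int(rng.choice(codes, p=probs / probs.sum()))
            mean_area = _truncated_normal(rng, spec.na_mean_um2, spec.na_sd_um2)
            density = _truncated_normal(rng, spec.density_mean_per_mm2,
                                        spec.density_sd_per_mm2)
            fields = []
            for fid in range(config.fields_per_sample):
                fmean = _truncated_normal(rng, mean_area,
                                          spec.field_cv * mean_area)
                count = int(rng.poisson(density * field_area))
                areas = _truncated_normal(rng, fmean,
                                          spec.within_sample_cv * fmean,
                                          size=count)
                nuclei = _place_field(np.atleast_1d(areas), spec, config,
                                      rng, sample_id, fid)
                image = render_field(nuclei, config)
                fields.append(SimulatedField(
                    sample_id=sample_id, field_id=fid, label_image=image,
                    nuclei=nuclei, requested_count=count,
                    field_mean_area_um2=float(fmean)))
            samples.append(SimulatedSample(
                sample_id=sample_id, group=spec.label, grade_code=grade,
                mean_area_um2=float(mean_area),
                density_per_mm2=float(density), fields=fields))
    return SyntheticCohort(config=config, samples=samples)
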