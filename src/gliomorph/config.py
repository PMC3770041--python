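"""Cohort and calibration configuration.

A :class:`CohortConfig` describes a three-group study — non-neoplastic
control brain tissue (CG), low-grade glioma (LGG, WHO grade II) and
high-grade glioma (HGG, WHO grades III-IV) — as a set of
:class:`GroupSpec` entries plus the imaging geometry shared by all
simulated high-power fields.  :func:`default_cohort_config` returns the
published reference-cohort parameterization (10 / 14 / 16 cases, five
fields per case).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Canonical group labels, in grade order.
GROUP_LABELS = ("CG", "LGG", "HGG")


class InvalidParameterError(ValueError):
    """A configuration or operation parameter violates its contract."""


@dataclass
class GroupSpec:
    """Generative parameters for one study group.

    Between-sample variation (``na_sd_um2``, ``density_sd_per_mm2``) is the
    spread of per-case means; ``within_sample_cv`` is the nucleus-level
    coefficient of variation of area inside one case, and ``field_cv`` the
    coefficient of variation of the per-field mean area around the case
    mean (regional heterogeneity; 0 gives a homogeneous case).
    """

    label: str
    n_samples: int
    #: WHO grade code -> mixing proportion (0 = control, 2/3/4 = WHO II/III/IV).
    grade_codes: dict[int, float]
    na_mean_um2: float
    na_sd_um2: float
    within_sample_cv: float
    density_mean_per_mm2: float
    density_sd_per_mm2: float
    aspect_ratio_mean: float = 1.5
    aspect_ratio_sd: float = 0.15
    irregularity: float = 0.15
    field_cv: float = 0.0

    def validate(self) -> None:
        if self.label not in GROUP_LABELS:
            raise InvalidParameterError(f"unknown group label {self.label!r}")
        if self.n_samples < 1:
            raise InvalidParameterError("n_samples must be >= 1")
        if self.na_mean_um2 <= 0 or self.density_mean_per_mm2 <= 0:
            raise InvalidParameterError("group means must be > 0")
        if min(self.na_sd_um2, self.density_sd_per_mm2) < 0:
            raise InvalidParameterError("group SDs must be >= 0")
        if not 0 <= self.irregularity < 0.5:
            raise InvalidParameterError("irregularity must lie in [0, 0.5)")
        if self.aspect_ratio_mean < 1:
            raise InvalidParameterError("aspect_ratio_mean must be >= 1")
        if self.within_sample_cv < 0 or self.field_cv < 0:
            raise InvalidParameterError("coefficients of variation must be >= 0")
        total = sum(self.grade_codes.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"grade mixing proportions must sum to 1 (got {total})"
            )


@dataclass
class CohortConfig:
    """Full simulation configuration: groups plus imaging geometry."""

    group_specs: list[GroupSpec]
    fields_per_sample: int = 5
    field_width_um: float = 346.0
    field_height_um: float = 260.0
    microns_per_pixel: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if not self.group_specs:
            raise InvalidParameterError("at least one group spec is required")
        for spec in self.group_specs:
            spec.validate()
        if self.fields_per_sample < 1:
            raise InvalidParameterError("fields_per_sample must be >= 1")
        if min(self.field_width_um, self.field_height_um, self.microns_per_pixel) <= 0:
            raise InvalidParameterError("physical dimensions must be > 0")

    @property
    def field_area_mm2(self) -> float:
        """Field area in mm², from the physical field dimensions."""
        return self.field_width_um * self.field_height_um / 1.0e6

    @property
    def raster_shape(self) -> tuple[int, int]:
        """(rows, cols) of the rendered label raster."""
        return (
            int(round(self.field_height_um / self.microns_per_pixel)),
            int(round(self.field_width_um / self.microns_per_pixel)),
        )

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["group_specs"] = [
            {**g, "grade_codes": {int(k): float(v) for k, v in g["grade_codes"].items()}}
            for g in doc["group_specs"]
        ]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise InvalidParameterError(f"config file {path} is not a mapping")
        if "group_specs" not in doc:
            raise InvalidParameterError("missing config key: group_specs")
        group_fields = {f.name for f in dataclasses.fields(GroupSpec)}
        required = {f.name for f in dataclasses.fields(GroupSpec)
                    if f.default is dataclasses.MISSING
                    and f.default_factory is dataclasses.MISSING}
        groups = []
        for g in doc.pop("group_specs"):
            missing = required - set(g)
            if missing:
                raise InvalidParameterError(
                    f"group spec missing key(s): {sorted(missing)}")
            unknown = set(g) - group_fields
            if unknown:
                raise InvalidParameterError(
                    f"unknown group spec key(s): {sorted(unknown)}")
            groups.append(GroupSpec(**{
                **g, "grade_codes": {int(k): float(v)
                                     for k, v in g["grade_codes"].items()}}))
        cfg_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - cfg_fields
        if unknown:
            raise InvalidParameterError(
                f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(group_specs=groups, **doc)
        cfg.validate()
        return cfg


def single_group_config(label: str, seed: int = 0) -> CohortConfig:
    """The reference configuration restricted to one group.

    Useful for recovery experiments that target one group's generative
    parameters (e.g. high-grade area or control density) without
    simulating the full study.
    """
    base = default_cohort_config(seed=seed)
    specs = [g for g in base.group_specs if g.label == label]
    if not specs:
        raise InvalidParameterError(f"unknown group label {label!r}")
    base.group_specs = specs
    return base


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Reference-cohort defaults.

    Group means/SDs of nuclear area and density follow the published
    glioma morphometry reference values (see ``gliomorph.reference``);
    nucleus-level spread, aspect ratio and boundary irregularity are not
    published and carry stated defaults (see the methods note).  The field
    is 346 µm x 260 µm (~0.09 mm², a typical 400x digital camera field) at
    0.25 µm/px.
    """
    return CohortConfig(
        group_specs=[
            GroupSpec(
                label="CG", n_samples=10, grade_codes={0: 1.0},
                na_mean_um2=23.44, na_sd_um2=4.01, within_sample_cv=0.15,
                density_mean_per_mm2=1107.0, density_sd_per_mm2=138.0,
                aspect_ratio_mean=1.51, irregularity=0.10, field_cv=0.0,
            ),
            GroupSpec(
                label="LGG", n_samples=14, grade_codes={2: 1.0},
                na_mean_um2=42.62, na_sd_um2=7.26, within_sample_cv=0.30,
                density_mean_per_mm2=3232.0, density_sd_per_mm2=1596.0,
                aspect_ratio_mean=1.48, irregularity=0.16, field_cv=0.15,
            ),
            GroupSpec(
                label="HGG", n_samples=16, grade_codes={3: 3 / 16, 4: 13 / 16},
                na_mean_um2=55.22, na_sd_um2=13.48, within_sample_cv=0.30,
                density_mean_per_mm2=4350.0, density_sd_per_mm2=1089.0,
                aspect_ratio_mean=1.51, irregularity=0.20, field_cv=0.15,
            ),
        ],
        seed=seed,
    )
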