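"""Stage orchestration: simulate -> measure -> analyze, on files or in memory.

Stage boundaries are plain files (TIFF label images, CSV tables, YAML
config) so each stage can be run, tested and replaced independently; the
in-memory variants skip the disk round trip for programmatic use.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from pathlib import Path

import pandas as pd

from .config import CohortConfig, InvalidParameterError
from .distribution import area_histogram, gaussian_deviation, group_gaussian_curves
from .io import (FIELD_COLUMNS, NUCLEUS_COLUMNS, SAMPLE_COLUMNS,
                 read_label_image, records_to_frame, write_cohort,
                 write_run_manifest)
from .morphometry import (CalibrationSpec, measure_field, select_fields,
                          select_nuclei, summarize_sample)
from .simulate import SyntheticCohort, generate_cohort
from .stats import (SampleRecord, pairwise_tests_from_summaries,
                    run_group_analysis)

logger = logging.getLogger("gliomorph")

_FIELD_FILE_RE = re.compile(r"^(?P<sample>.+)_f(?P<field>\d+)\.(tif|tiff|png)$")

DEFAULT_FIELDS_SELECTED = 5
DEFAULT_NUCLEI_SELECTED = 100


def simulate_run(config: CohortConfig, outdir: str | Path) -> SyntheticCohort:
    """Generate a cohort and write it to ``outdir`` with a manifest."""
    cohort = generate_cohort(config)
    files = write_cohort(cohort, outdir)
    write_run_manifest(Path(outdir), "simulate", config.seed,
                       {"n_samples": len(cohort.samples)}, files)
    return cohort


def measure_cohort(cohort: SyntheticCohort,
                   k_fields: int = DEFAULT_FIELDS_SELECTED,
                   n_nuclei: int = DEFAULT_NUCLEI_SELECTED,
                   ) -> tuple[pd.DataFrame, pd.DataFrame, list[SampleRecord]]:
    """Measure an in-memory cohort end to end.

    Returns (per-nucleus frame, per-field frame, per-sample records);
    the per-sample records apply the field- and nucleus-selection rules.
    """
    cal = CalibrationSpec(cohort.config.microns_per_pixel)
    nucleus_rows, field_rows, sample_records = [], [], []
    for sample in cohort.samples:
        field_records = [
            measure_field(f.label_image, cal, sample.sample_id, f.field_id)
            for f in sample.fields
        ]
        selected_fields = select_fields(field_records, k_fields)
        pooled = [r for f in selected_fields for r in f.nuclei]
        selected = select_nuclei(pooled, n_nuclei)
        sample_records.append(summarize_sample(
            sample.sample_id, sample.group, sample.grade_code,
            selected_fields, selected))
        for f in field_records:
            field_rows.append(f)
            nucleus_rows.extend(f.nuclei)
    return (records_to_frame(nucleus_rows, NUCLEUS_COLUMNS),
            records_to_frame(field_rows, FIELD_COLUMNS),
            sample_records)


def _samples_to_frame(samples: list[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(s, {"sample_id": "sample_id",
                                         "group": "group",
                                         "grade_code": "grade_code"}.get(c, c))
                          for c in SAMPLE_COLUMNS} for s in samples],
                        columns=SAMPLE_COLUMNS)


def measure_run(indir: str | Path, microns_per_pixel: float,
                outdir: str | Path,
                k_fields: int = DEFAULT_FIELDS_SELECTED,
                n_nuclei: int = DEFAULT_NUCLEI_SELECTED) -> pd.DataFrame:
    """Measure every ``<sample>_f<k>`` label image under ``indir``.

    Writes per-nucleus, per-field and per-sample CSVs to ``outdir`` and
    returns the per-sample frame.  Group/grade labels are taken from
    ``samples_manifest.csv`` when present (simulated cohorts); otherwise
    every sample is labelled group ``UNK`` with grade -1 in the CSV only.
    """
    indir, outdir = Path(indir), Path(outdir)
    images = sorted(p for p in indir.iterdir()
                    if _FIELD_FILE_RE.match(p.name))
    if not images:
        raise InvalidParameterError(f"no field images found under {indir}")
    cal = CalibrationSpec(microns_per_pixel)

    labels: dict[str, tuple[str, int]] = {}
    manifest = indir / "samples_manifest.csv"
    if manifest.exists():
        mf = pd.read_csv(manifest)
        labels = {r.sample_id: (r.group, int(r.grade_code))
                  for r in mf.itertuples()}

    by_sample: dict[str, list[tuple[int, Path]]] = defaultdict(list)
    n_bad = 0
    for p in images:
        m = _FIELD_FILE_RE.match(p.name)
        by_sample[m.group("sample")].append((int(m.group("field")), p))

    nucleus_rows, field_rows, sample_rows = [], [], []
    for sample_id in sorted(by_sample):
        field_records = []
        for field_id, path in sorted(by_sample[sample_id]):
            try:
                img = read_label_image(path)
            except Exception as exc:  # corrupt file: report, continue
                logger.error("failed to read %s: %s", path, exc)
                n_bad += 1
                continue
            field_records.append(measure_field(img, cal, sample_id, field_id))
        if not field_records:
            continue
        selected_fields = select_fields(field_records, k_fields)
        pooled = [r for f in selected_fields for r in f.nuclei]
        selected = select_nuclei(pooled, n_nuclei)
        group, grade = labels.get(sample_id, ("UNK", -1))
        row = {"sample_id": sample_id, "group": group, "grade_code": grade}
        if selected:
            rec = summarize_sample(sample_id, "CG", 0, selected_fields, selected)
            row.update({c: getattr(rec, c) for c in SAMPLE_COLUMNS[3:]})
        sample_rows.append(row)
        for f in field_records:
            field_rows.append(f)
            nucleus_rows.extend(f.nuclei)
    if n_bad:
        logger.error("%d image file(s) could not be read", n_bad)

    outdir.mkdir(parents=True, exist_ok=True)
    nuc = records_to_frame(nucleus_rows, NUCLEUS_COLUMNS)
    fld = records_to_frame(field_rows, FIELD_COLUMNS)
    smp = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    files = []
    for name, frame in (("nuclei.csv", nuc), ("fields.csv", fld),
                        ("samples.csv", smp)):
        p = outdir / name
        frame.to_csv(p, index=False)
        files.append(p)
    write_run_manifest(outdir, "measure", None,
                       {"microns_per_pixel": microns_per_pixel}, files)
    return smp


def analyze_samples(samples: list[SampleRecord], outdir: str | Path,
                    nuclei_frame: pd.DataFrame | None = None) -> None:
    """Group analysis + area-distribution exports for measured samples."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = run_group_analysis(samples)
    files = []
    for name, frame in (("group_summaries.csv", analysis.summary_frame()),
                        ("pairwise_tests.csv", analysis.ttest_frame()),
                        ("correlations.csv", analysis.correlation_frame())):
        p = outdir / name
        frame.to_csv(p, index=False)
        files.append(p)

    group_stats = {g: (analysis.summaries["NA"][g].mean,
                       analysis.summaries["NA"][g].sd)
                   for g in analysis.summaries["NA"]}
    curves = group_gaussian_curves(group_stats)
    rows = []
    for group, dist in curves.items():
        for lo, hi, exp in zip(dist.bin_edges[:-1], dist.bin_edges[1:],
                               dist.expected_counts):
            rows.append({"group": group, "bin_lo": lo, "bin_hi": hi,
                         "expected": exp})
    p = outdir / "group_area_model.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    files.append(p)

    if nuclei_frame is not None and len(nuclei_frame):
        dev_rows, dist_rows = [], []
        usable = nuclei_frame[nuclei_frame["separated"]
                              & ~nuclei_frame["border_touching"]]
        for sample_id, sub in usable.groupby("sample_id"):
            areas = sub["na_um2"].to_numpy()
            dist = area_histogram(areas)
            for lo, hi, obs, exp in zip(dist.bin_edges[:-1],
                                        dist.bin_edges[1:],
                                        dist.observed_counts,
                                        dist.expected_counts):
                dist_rows.append({"sample_id": sample_id, "bin_lo": lo,
                                  "bin_hi": hi, "observed": obs,
                                  "expected": exp})
            if len(areas) >= 20 and areas.std() > 0:
                score = gaussian_deviation(areas)
                dev_rows.append({"sample_id": sample_id,
                                 "ks_statistic": score.statistic,
                                 "p_value_approx": score.p_value,
                                 "peak_height_ratio": score.peak_height_ratio,
                                 "range_ratio": score.range_ratio,
                                 "n": score.n})
        for name, rows_ in (("area_distributions.csv", dist_rows),
                            ("gaussian_deviation.csv", dev_rows)):
            p = outdir / name
            pd.DataFrame(rows_).to_csv(p, index=False)
            files.append(p)
    write_run_manifest(outdir, "analyze", None, None, files)


def analyze_run(input_csv: str | Path, outdir: str | Path,
                from_summary: bool = False) -> None:
    """File-based analyze stage.

    ``from_summary`` consumes a (parameter, group, n, mean, sd) table —
    e.g. transcribed published cells — and recomputes the pairwise
    pooled t-tests; otherwise a per-sample CSV from the measure stage is
    analysed in full.
    """
    input_csv, outdir = Path(input_csv), Path(outdir)
    # keep_default_na: the parameter label "NA" (nuclear area) must not
    # be parsed as a missing value
    df = pd.read_csv(input_csv, keep_default_na=False, na_values=[""])
    outdir.mkdir(parents=True, exist_ok=True)
    if from_summary:
        required = {"parameter", "group", "n", "mean", "sd"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidParameterError(
                f"summary CSV missing columns: {sorted(missing)}")
        if df["group"].nunique() < 2:
            raise InvalidParameterError("need >= 2 groups")
        summaries = {
            param: {r.group: (float(r.mean), float(r.sd), int(r.n))
                    for r in sub.itertuples()}
            for param, sub in df.groupby("parameter")
        }
        tests = pairwise_tests_from_summaries(summaries)
        rows = [{"parameter": param, "pair": f"{pair[0]}_vs_{pair[1]}",
                 "t": t.t_statistic, "df": t.df, "p_value": t.p_value,
                 "significant": t.significant}
                for param, per_pair in tests.items()
                for pair, t in per_pair.items()]
        p = outdir / "pairwise_tests.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        write_run_manifest(outdir, "analyze", None,
                           {"from_summary": True}, [p])
        return
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidParameterError(
            f"sample CSV missing columns: {sorted(missing)}")
    if df["group"].nunique() < 2:
        raise InvalidParameterError("need >= 2 groups")
    samples = [SampleRecord(**{c: row[c] for c in SAMPLE_COLUMNS})
               for _, row in df.iterrows()]
    nuclei_csv = input_csv.parent / "nuclei.csv"
    nuclei = pd.read_csv(nuclei_csv) if nuclei_csv.exists() else None
    analyze_samples(samples, outdir, nuclei_frame=nuclei)
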