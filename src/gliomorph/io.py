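"""File I/O: label TIFF/PNG images, CSV tables, run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .simulate import SyntheticCohort

#: Per-nucleus measurement CSV columns.
NUCLEUS_COLUMNS = ["sample_id", "field_id", "label_id", "majx_um", "minx_um",
                   "na_um2", "np_um", "nr_pct", "border_touching", "separated"]
FIELD_COLUMNS = ["sample_id", "field_id", "nucleus_count", "nd_per_mm2",
                 "tna_pct"]
SAMPLE_COLUMNS = ["sample_id", "group", "grade_code", "mean_majx", "mean_minx",
                  "mean_na", "mean_np", "mean_nr", "mean_nd", "mean_tna"]


def field_image_name(sample_id: str, field_id: int) -> str:
    return f"{sample_id}_f{field_id}.tif"


def write_label_image(path: str | Path, image: np.ndarray) -> None:
    """16-bit single-channel label TIFF (byte-stable across reruns)."""
    tifffile.imwrite(path, image.astype(np.uint16))


def read_label_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel label image, "
                         f"got shape {img.shape}")
    return img.astype(np.int64)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> list[Path]:
    """Write a simulated cohort: per-field TIFFs, ground truth, manifests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for sample in cohort.samples:
        for fld in sample.fields:
            p = outdir / field_image_name(sample.sample_id, fld.field_id)
            write_label_image(p, fld.label_image)
            written.append(p)
    for name, frame in (("ground_truth.csv", cohort.ground_truth_frame()),
                        ("samples_manifest.csv", cohort.sample_manifest_frame()),
                        ("fields_manifest.csv", cohort.field_manifest_frame())):
        p = outdir / name
        frame.to_csv(p, index=False)
        written.append(p)
    p = outdir / "config.yaml"
    cohort.config.to_yaml(p)
    written.append(p)
    return written


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_manifest(outdir: str | Path, stage: str, seed: int | None,
                       config_snapshot: dict | None,
                       files: list[Path]) -> Path:
    """JSON manifest of one pipeline stage: config, seed, output hashes."""
    outdir = Path(outdir)
    doc = {
        "stage": stage,
        "tool": "gliomorph",
        "version": __version__,
        "seed": seed,
        "config": config_snapshot,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {str(p.name): sha256_file(p) for p in sorted(files)},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(doc, indent=2, default=str))
    return path


def records_to_frame(records, columns) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        rows.append({c: d[c] for c in columns})
    return pd.DataFrame(rows, columns=columns)
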