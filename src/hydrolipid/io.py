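"""Plain-text and TIFF I/O for the pipeline's tabular and image artifacts.

Growth tables and light-curve traces travel as headered CSV; images as
single-page 16-bit grayscale TIFF and stacks as multi-page TIFF; ground
truth as CSV side-cars keyed by artifact filename.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .growth import GrowthCurve
from .pam import DarkReference, LightCurveRecord, LightCurveStep

GROWTH_COLUMNS = ["time_h", "concentration_cells_per_ml", "replicate", "condition"]
TRACE_COLUMNS = ["par_umol_m2_s", "f_prime", "fm_prime"]


def write_growth_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=GROWTH_COLUMNS)


def read_growth_csv(path: str | Path) -> list[GrowthCurve]:
    """One GrowthCurve per (replicate, condition) group."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(GROWTH_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"growth CSV missing columns: {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    if "condition" not in df.columns:
        df["condition"] = None
    curves = []
    for (rep, cond), grp in df.groupby(["replicate", "condition"], dropna=False,
                                       sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                times=grp["time_h"].to_numpy(),
                concentrations=grp["concentration_cells_per_ml"].to_numpy(),
                replicate_id=rep,
                condition=None if pd.isna(cond) else cond,
            )
        )
    return curves


def write_light_curve_csv(record: LightCurveRecord, path: str | Path) -> None:
    """Trace CSV: a `# f0=...,fm=...` metadata line, then per-step rows."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# f0={record.dark.F0!r},fm={record.dark.Fm!r}\n")
        pd.DataFrame(
            {
                "par_umol_m2_s": [s.E for s in record.steps],
                "f_prime": [s.F_prime for s in record.steps],
                "fm_prime": [s.Fm_prime for s in record.steps],
            }
        ).to_csv(fh, index=False)


def read_light_curve_csv(path: str | Path) -> LightCurveRecord:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("trace CSV must start with a '# f0=...,fm=...' line")
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split(","))
        df = pd.read_csv(fh, float_precision="round_trip")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    dark = DarkReference(F0=float(meta["f0"]), Fm=float(meta["fm"]))
    steps = [
        LightCurveStep(E=row.par_umol_m2_s, F_prime=row.f_prime, Fm_prime=row.fm_prime)
        for row in df.itertuples()
    ]
    return LightCurveRecord(dark=dark, steps=steps)


def write_image(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.uint16),
                     photometric="minisblack")


def write_stack(frames: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(frames, dtype=np.uint16),
                     photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_image_set(
    images: Sequence[np.ndarray], directory: str | Path, prefix: str = "cell"
) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        p = directory / f"{prefix}_{i:04d}.tif"
        write_image(img, p)
        paths.append(p)
    return paths
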