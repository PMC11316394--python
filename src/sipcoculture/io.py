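"""Reading and writing the pipeline's on-disk formats.

Ion-count images travel as one uint32 TIFF per channel plus a uint16
label-mask TIFF and a ROI annotation CSV; tabular data (growth series,
ground truth, plate tables) are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .sims_quant import CHANNELS, IonImageStack, ROISet

GROWTH_COLUMNS = ["time_h", "condition", "replicate", "partner", "density", "unit"]
DENSITY_UNITS = {"CFU/ml", "cells/ml"}


def write_field(
    stack: IonImageStack, rois: ROISet, out_dir: str | Path, prefix: str
) -> list[Path]:
    """Write one field: per-channel TIFFs, mask TIFF, ROI CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for ch, img in stack.channels.items():
        p = out_dir / f"{prefix}_{ch}.tif"
        tifffile.imwrite(
            p, img.astype(np.uint32),
            resolution=(1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
            metadata={"channel": ch, **{k: str(v) for k, v in stack.meta.items()}},
        )
        written.append(p)
    mask_path = out_dir / f"{prefix}_mask.tif"
    tifffile.imwrite(mask_path, rois.mask.astype(np.uint16))
    written.append(mask_path)
    roi_path = out_dir / f"{prefix}_rois.csv"
    rois.annotations.to_csv(roi_path, index=False)
    written.append(roi_path)
    return written


def read_field(
    out_dir: str | Path, prefix: str, pixel_size_um: float = 0.1, meta: dict | None = None
) -> tuple[IonImageStack, ROISet]:
    """Read a field written by :func:`write_field`."""
    out_dir = Path(out_dir)
    channels = {}
    for ch in CHANNELS:
        p = out_dir / f"{prefix}_{ch}.tif"
        if p.exists():
            channels[ch] = tifffile.imread(p)
    if not channels:
        raise FileNotFoundError(f"no channel TIFFs for prefix {prefix!r} in {out_dir}")
    mask = tifffile.imread(out_dir / f"{prefix}_mask.tif")
    ann = pd.read_csv(out_dir / f"{prefix}_rois.csv")
    stack = IonImageStack(channels=channels, pixel_size_um=pixel_size_um,
                          meta=dict(meta or {}))
    return stack, ROISet(mask=mask, annotations=ann)


def write_growth_csv(growth: pd.DataFrame, path: str | Path) -> None:
    missing = set(GROWTH_COLUMNS) - set(growth.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    growth[GROWTH_COLUMNS].to_csv(path, index=False)


def read_growth_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(GROWTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"growth CSV {path} missing columns: {sorted(missing)}")
    bad_units = set(df["unit"]) - DENSITY_UNITS
    if bad_units:
        raise ValueError(
            f"growth CSV {path} column 'unit' contains unsupported values "
            f"{sorted(bad_units)}; expected {sorted(DENSITY_UNITS)}"
        )
    return df
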