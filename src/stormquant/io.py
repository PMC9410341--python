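"""File I/O for the pipeline's standard interchange formats.

ECG traces travel as two-column CSV (time_s, voltage_mv) with a JSON
metadata sidecar; movies as multi-page TIFF in ImageJ-compatible TCYX
axis order with pixel size and per-frame trigger phase in a JSON sidecar;
slices as single-page TIFF plus mask TIFFs.  Ground-truth objects are
written as JSON sidecars next to the data they describe.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from stormquant.ecg import ECGTrace
from stormquant.fri import FRISlice
from stormquant.imaging import CalciumMovie

__all__ = [
    "write_ecg_csv",
    "read_ecg_csv",
    "write_movie_tiff",
    "read_movie_tiff",
    "write_slice_tiff",
    "read_slice_tiff",
    "write_ground_truth",
]


def write_ecg_csv(trace: ECGTrace, stem: str | Path) -> Path:
    """Write ``<stem>.csv`` (time_s, voltage_mv) and ``<stem>.json`` metadata."""
    stem = Path(stem)
    pd.DataFrame(
        {"time_s": trace.times_s, "voltage_mv": trace.samples}
    ).to_csv(stem.with_suffix(".csv"), index=False)
    meta = {
        "sampling_rate_hz": trace.sampling_rate_hz,
        "start_time_s": trace.start_time_s,
        "subject_id": trace.subject_id,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return stem.with_suffix(".csv")


def read_ecg_csv(stem: str | Path) -> ECGTrace:
    stem = Path(stem)
    df = pd.read_csv(stem.with_suffix(".csv"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return ECGTrace(
        samples=df["voltage_mv"].to_numpy(),
        sampling_rate_hz=meta["sampling_rate_hz"],
        start_time_s=meta.get("start_time_s", 0.0),
        subject_id=meta.get("subject_id", ""),
    )


def write_movie_tiff(movie: CalciumMovie, stem: str | Path) -> Path:
    """Write ``<stem>.tif`` as TCYX (Ca channel first) plus JSON sidecar."""
    stem = Path(stem)
    stack = np.stack([movie.ca, movie.neutrophil], axis=1).astype(np.float32)
    tifffile.imwrite(stem.with_suffix(".tif"), stack, imagej=True,
                     metadata={"axes": "TCYX"})
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "trigger_phase": movie.trigger_phase.tolist(),
        "channel_order": ["ca", "neutrophil"],
        "fov_id": movie.fov_id,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return stem.with_suffix(".tif")


def read_movie_tiff(stem: str | Path) -> CalciumMovie:
    stem = Path(stem)
    stack = tifffile.imread(stem.with_suffix(".tif"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return CalciumMovie(
        ca=stack[:, 0],
        neutrophil=stack[:, 1],
        pixel_size_um=meta["pixel_size_um"],
        trigger_phase=np.asarray(meta["trigger_phase"], dtype=float),
        fov_id=meta.get("fov_id", ""),
    )


def write_slice_tiff(sl: FRISlice, stem: str | Path) -> Path:
    """Write the slice image and its masks as single-page TIFFs + metadata."""
    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".tif"), sl.image.astype(np.float32))
    for name, mask in (
        ("remote", sl.remote_mask),
        ("target", sl.target_mask),
        ("background", sl.background_mask),
    ):
        if mask is not None:
            tifffile.imwrite(
                stem.parent / f"{stem.name}_{name}.tif",
                mask.astype(np.uint8),
            )
    meta = {"slice_id": sl.slice_id, "assay": sl.assay}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return stem.with_suffix(".tif")


def read_slice_tiff(stem: str | Path) -> FRISlice:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())

    def _mask(name: str) -> np.ndarray | None:
        p = stem.parent / f"{stem.name}_{name}.tif"
        return tifffile.imread(p).astype(bool) if p.exists() else None

    return FRISlice(
        image=tifffile.imread(stem.with_suffix(".tif")).astype(float),
        remote_mask=_mask("remote"),
        target_mask=_mask("target"),
        background_mask=_mask("background"),
        slice_id=meta.get("slice_id", ""),
        assay=meta.get("assay", "annexin"),
    )


def write_ground_truth(truth, path: str | Path) -> Path:
    """Write any generator ground-truth object (``.to_dict()``) as JSON."""
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1))
    return path
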