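"""Readers and writers for the standard on-disk formats.

NIfTI-1 (via nibabel) for 3-D/4-D volumes, CSV for frame schedules, plasma
samples and cell counts, JSON for reports, YAML for configuration. CT and
PET volumes are assumed co-registered, as produced by a hybrid scanner.
"""
from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    CellCountRecord,
    DynamicScan,
    FrameSchedule,
    LobeMaskVolume,
    PlasmaCurve,
    ScalarVolume,
    VolumeGrid,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_volume",
    "write_volume",
    "read_lobe_mask",
    "write_lobe_mask",
    "read_schedule",
    "write_schedule",
    "read_dynamic_scan",
    "write_dynamic_scan",
    "read_plasma_csv",
    "write_plasma_csv",
    "read_cell_counts",
    "write_report",
]


class FormatError(ValueError):
    """Raised when an input file is not in the expected format."""


def _load_nifti(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    return img


def _grid_from_img(img: nib.Nifti1Image, **grid_kw: Any) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    dims = img.shape[:3]
    return VolumeGrid(tuple(int(d) for d in dims), tuple(float(z) for z in zooms), **grid_kw)


def read_volume(path: str | Path, expected_kind: str, **grid_kw: Any) -> ScalarVolume:
    """Read a 3-D NIfTI volume as a :class:`ScalarVolume` of ``expected_kind``."""
    img = _load_nifti(path)
    if len(img.shape) != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {img.shape}")
    grid = _grid_from_img(img, **grid_kw)
    values = np.asanyarray(img.dataobj, dtype=float)
    return ScalarVolume(grid, values, expected_kind)


def write_volume(vol: ScalarVolume, path: str | Path) -> None:
    affine = np.diag(list(vol.grid.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.values.astype(np.float64), affine), str(path))


def read_lobe_mask(
    path: str | Path, role_labels: Mapping[str, int], **grid_kw: Any
) -> LobeMaskVolume:
    img = _load_nifti(path)
    if len(img.shape) != 3:
        raise FormatError(f"{path}: expected a 3-D label volume, got shape {img.shape}")
    grid = _grid_from_img(img, **grid_kw)
    labels = np.asanyarray(img.dataobj)
    labels = np.rint(labels).astype(np.int32)
    return LobeMaskVolume(grid, labels, dict(role_labels))


def write_lobe_mask(mask: LobeMaskVolume, path: str | Path) -> None:
    affine = np.diag(list(mask.grid.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), affine), str(path))


def read_schedule(path: str | Path) -> FrameSchedule:
    """Read a frame schedule from CSV (start_s, duration_s) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        entries = json.loads(path.read_text())
        frames = [(float(e["start_s"]), float(e["duration_s"])) for e in entries]
    else:
        df = pd.read_csv(path)
        required = {"start_s", "duration_s"}
        if not required.issubset(df.columns):
            raise FormatError(f"{path}: schedule CSV must have columns {sorted(required)}")
        frames = list(zip(df["start_s"].astype(float), df["duration_s"].astype(float)))
    return FrameSchedule(tuple(frames))


def write_schedule(schedule: FrameSchedule, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps([{"start_s": s, "duration_s": d} for s, d in schedule.frames], indent=1)
        )
    else:
        pd.DataFrame(schedule.frames, columns=["start_s", "duration_s"]).to_csv(path, index=False)


def read_dynamic_scan(path: str | Path, schedule_path: str | Path, **grid_kw: Any) -> DynamicScan:
    """Read a 4-D NIfTI plus its frame schedule; frame counts must agree."""
    img = _load_nifti(path)
    if len(img.shape) != 4:
        raise FormatError(f"{path}: expected a 4-D dynamic scan, got shape {img.shape}")
    schedule = read_schedule(schedule_path)
    if img.shape[3] != len(schedule):
        raise FormatError(
            f"{path}: scan has {img.shape[3]} frames but schedule "
            f"{schedule_path} has {len(schedule)} rows"
        )
    grid = _grid_from_img(img, **grid_kw)
    data = np.asanyarray(img.dataobj, dtype=float)
    frames = np.moveaxis(data, 3, 0)
    return DynamicScan(grid, schedule, frames)


def write_dynamic_scan(scan: DynamicScan, path: str | Path, schedule_path: str | Path) -> None:
    affine = np.diag(list(scan.grid.spacing) + [1.0])
    data = np.moveaxis(scan.frames, 0, 3)
    nib.save(nib.Nifti1Image(data.astype(np.float64), affine), str(path))
    write_schedule(scan.schedule, schedule_path)


def read_plasma_csv(path: str | Path, dense: bool = False) -> PlasmaCurve:
    df = pd.read_csv(path)
    if not {"time_min", "activity"}.issubset(df.columns):
        raise FormatError(f"{path}: plasma CSV must have columns time_min, activity")
    return PlasmaCurve(df["time_min"].to_numpy(float), df["activity"].to_numpy(float), dense=dense)


def write_plasma_csv(curve: PlasmaCurve, path: str | Path) -> None:
    pd.DataFrame({"time_min": curve.times_min, "activity": curve.activities}).to_csv(
        path, index=False
    )


def read_cell_counts(path: str | Path) -> list[CellCountRecord]:
    df = pd.read_csv(path)
    required = {
        "lobe_role",
        "returned_volume_ml",
        "total_cells",
        "eosinophils",
        "neutrophils",
        "mononuclear",
    }
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: cell-count CSV must have columns {sorted(required)}")
    return [
        CellCountRecord(
            lobe_role=str(row.lobe_role),
            returned_volume_ml=float(row.returned_volume_ml),
            total_cells=float(row.total_cells),
            eosinophils=float(row.eosinophils),
            neutrophils=float(row.neutrophils),
            mononuclear=float(row.mononuclear),
        )
        for row in df.itertuples()
    ]


def write_report(
    results: Mapping[str, Any] | Sequence[Mapping[str, Any]],
    path: str | Path,
    format: str = "json",
    provenance: Mapping[str, Any] | None = None,
) -> None:
    """Write an analysis report as JSON or CSV with provenance metadata."""
    path = Path(path)
    provenance = dict(provenance or {})
    if format == "json":
        payload = {"provenance": provenance, "results": _jsonable(results)}
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif format == "csv":
        rows = results if isinstance(results, Sequence) else [results]
        if not rows:
            log.warning("writing empty report to %s", path)
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["# empty report"])
            return
        df = pd.DataFrame([dict(r) for r in rows])
        with open(path, "w", newline="") as fh:
            for key, val in provenance.items():
                fh.write(f"# {key}: {val}\n")
            df.to_csv(fh, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
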