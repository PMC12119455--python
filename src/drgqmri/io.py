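"""Reading and writing the pipeline's on-disk formats.

Multi-echo series are 4D NIfTI-1 files (4th dimension = echo index) with a
JSON sidecar carrying the echo times; label masks are integer 3D NIfTI-1
with a JSON label table (structure / level / side / rater per label);
quantitative maps are one float32 3D NIfTI-1 per map sharing the series
affine, with the QC report as JSON.  Voxel spacing is encoded in (and read
back from) the affine.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

import nibabel as nib
import numpy as np

from .features import LabelInfo, RoiMask
from .relaxometry import MultiEchoSeries, QuantMaps

__all__ = [
    "save_series",
    "load_series",
    "save_mask",
    "load_mask",
    "save_maps",
    "load_maps",
]

PathLike = Union[str, Path]


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def _spacing_of(img) -> tuple:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def save_series(series: MultiEchoSeries, path: PathLike) -> None:
    """Write a 4D NIfTI plus ``<stem>.json`` sidecar with echo times (ms)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float32),
                          _affine(series.voxel_spacing))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"echo_times_ms": list(series.echo_times),
         "voxel_spacing_mm": list(series.voxel_spacing)}, indent=1))


def load_series(path: PathLike) -> MultiEchoSeries:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    return MultiEchoSeries(data=np.asarray(img.dataobj, dtype=float),
                           echo_times=tuple(meta["echo_times_ms"]),
                           voxel_spacing=_spacing_of(img))


def save_mask(mask: RoiMask, path: PathLike) -> None:
    path = Path(path)
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(mask.spacing))
    nib.save(img, str(path))
    table = {str(lab): {"structure": info.structure, "level": info.level,
                        "side": info.side, "rater_id": info.rater_id}
             for lab, info in mask.label_table.items()}
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar.write_text(json.dumps(table, indent=1))


def load_mask(path: PathLike) -> RoiMask:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    raw = json.loads(sidecar.read_text())
    table = {int(lab): LabelInfo(d["structure"], d["level"], d["side"],
                                 d["rater_id"])
             for lab, d in raw.items()}
    return RoiMask(labels=np.asarray(img.dataobj).astype(np.int16),
                   spacing=_spacing_of(img), label_table=table)


_MAP_NAMES = ("t2", "m0", "b1", "r2_of_fit", "residual_rms", "qc_flags")


def save_maps(maps: QuantMaps, out_dir: PathLike, prefix: str = "") -> Dict[str, Path]:
    """Write each map as ``<prefix><name>.nii.gz``; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    aff = _affine(maps.voxel_spacing)
    for name in _MAP_NAMES:
        arr = getattr(maps, name)
        dtype = np.uint8 if name == "qc_flags" else np.float32
        p = out_dir / f"{prefix}{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(dtype), aff), str(p))
        written[name] = p
    return written


def load_maps(out_dir: PathLike, prefix: str = "") -> QuantMaps:
    out_dir = Path(out_dir)
    arrays = {}
    spacing = (1.0, 1.0, 1.0)
    for name in _MAP_NAMES:
        img = nib.load(str(out_dir / f"{prefix}{name}.nii.gz"))
        arrays[name] = np.asarray(img.dataobj,
                                  dtype=np.uint8 if name == "qc_flags" else float)
        spacing = _spacing_of(img)
    return QuantMaps(t2=arrays["t2"], m0=arrays["m0"], b1=arrays["b1"],
                     r2_of_fit=arrays["r2_of_fit"],
                     residual_rms=arrays["residual_rms"],
                     qc_flags=arrays["qc_flags"], voxel_spacing=spacing)
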