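"""NIfTI volume and JSON study-manifest I/O.

NIfTI has no field for activity/dose units, so every volume is written with a
JSON sidecar (same stem, ``.json``) carrying units, timestamp and nuclide
tag; reading refuses volumes without one.  Values are stored float32 (label
maps int16); the affine is diagonal spacing with the origin in the
translation column, matching the package's voxel-center world convention.

A study manifest is a single JSON file listing the density and label volumes,
the ordered activity frames with their times, and the study metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import RoiSet, ScalarVolume, VoxelGrid
from .phantom import StudyMeta


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(vol: ScalarVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI plus JSON sidecar; returns the sidecar path."""
    path = Path(path)
    if vol.units != "1" and np.any(vol.values < 0):
        idx = tuple(int(i) for i in np.argwhere(vol.values < 0)[0])
        raise ValueError(f"refusing to write negative {vol.units} value at voxel {idx}")
    is_label = np.issubdtype(vol.values.dtype, np.integer)
    data = vol.values.astype(np.int16 if is_label else np.float32)
    affine = np.diag(list(vol.grid.spacing) + [1.0])
    affine[:3, 3] = vol.grid.origin
    nib.save(nib.Nifti1Image(data, affine), str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "units": vol.units,
                "timestamp_h": vol.timestamp,
                "nuclide": vol.nuclide_tag,
                "integer_labels": bool(is_label),
            },
            indent=1,
        )
    )
    return sidecar


def read_volume(path: str | Path) -> ScalarVolume:
    """Read a NIfTI volume; requires its JSON sidecar for units/metadata."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"volume {path} has no units sidecar ({sidecar.name}); cannot establish units"
        )
    meta = json.loads(sidecar.read_text())
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} holds {data.ndim}-D data; expected a 3-D volume")
    affine = img.affine
    grid = VoxelGrid(
        shape=tuple(int(n) for n in data.shape),
        spacing=tuple(float(affine[i, i]) for i in range(3)),
        origin=tuple(float(affine[i, 3]) for i in range(3)),
    )
    if meta.get("integer_labels"):
        data = data.astype(np.int16)
    return ScalarVolume(
        grid,
        data,
        meta["units"],
        timestamp=meta.get("timestamp_h"),
        nuclide_tag=meta.get("nuclide"),
    )


@dataclass
class StudyBundle:
    """A study loaded from disk: what the analysis stages need, minus the
    generator's closed-form kinetics."""

    density: ScalarVolume
    labels: RoiSet
    frames: list[ScalarVolume]
    meta: StudyMeta
    imaging_nuclide: str


def write_manifest(study, out_dir: str | Path) -> Path:
    """Write a phantom/imaging study (volumes + manifest.json) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(study.density, out_dir / "density.nii.gz")
    write_volume(study.labels.label_volume, out_dir / "labels.nii.gz")
    frames = []
    for i, frame in enumerate(study.frames):
        name = f"frame_{i:02d}.nii.gz"
        write_volume(frame, out_dir / name)
        frames.append({"path": name, "time_h": frame.timestamp})
    manifest = {
        "subject_id": study.meta.subject_id,
        "injected_activity_mbq": study.meta.injected_activity_mbq,
        "subject_mass_kg": study.meta.subject_mass_kg,
        "injection_time_h": study.meta.injection_time_h,
        "imaging_nuclide": study.frames[0].nuclide_tag,
        "density": "density.nii.gz",
        "labels": "labels.nii.gz",
        "label_names": {str(k): v for k, v in study.labels.names.items()},
        "frames": frames,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_manifest(path: str | Path) -> StudyBundle:
    """Load a study manifest, validating schema and frame ordering."""
    path = Path(path)
    raw = json.loads(path.read_text())
    for key in ("injected_activity_mbq", "subject_mass_kg", "frames", "density", "labels"):
        if key not in raw:
            raise ValueError(f"manifest {path} lacks required field {key!r}")
    times = [f["time_h"] for f in raw["frames"]]
    for a, b in zip(times, times[1:]):
        if b <= a:
            raise ValueError(f"manifest frame times not strictly increasing: {a} then {b}")
    base = path.parent
    density = read_volume(base / raw["density"])
    label_vol = read_volume(base / raw["labels"])
    labels = RoiSet(label_vol, {int(k): v for k, v in raw.get("label_names", {}).items()})
    frames = [read_volume(base / f["path"]) for f in raw["frames"]]
    for frame, t in zip(frames, times):
        if frame.timestamp != t:
            raise ValueError(
                f"frame sidecar time {frame.timestamp} != manifest time {t}"
            )
    meta = StudyMeta(
        injected_activity_mbq=float(raw["injected_activity_mbq"]),
        subject_mass_kg=float(raw["subject_mass_kg"]),
        subject_id=str(raw.get("subject_id", "unknown")),
        injection_time_h=float(raw.get("injection_time_h", 0.0)),
    )
    return StudyBundle(density, labels, frames, meta, raw.get("imaging_nuclide", "Zr-89"))
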