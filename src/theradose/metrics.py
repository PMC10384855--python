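"""ROI-level quantification: SUV, time-activity tables, dose coefficients and
whole-body recovery QC.

SUV follows the body-weight convention

    SUV = (mean ROI activity concentration) / (A_inj · e^(−λ·t) / m_subject)

with λ the decay constant of the *imaging* nuclide and the implicit 1 g/mL
tissue equivalence bridging activity-per-volume and activity-per-mass, so SUV
is dimensionless and a uniform, non-excreting distribution scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import RoiSet, ScalarVolume
from .nuclides import Nuclide, decay_factor
from .phantom import StudyMeta
from .timeint import DoseMap


def suv(
    frame: ScalarVolume,
    rois: RoiSet,
    roi_name: str,
    meta: StudyMeta,
    imaging: Nuclide,
) -> float:
    """Mean body-weight SUV of one ROI at the frame's time point."""
    frame.require_units("Bq/mL", "activity frame")
    t = frame.require_timestamp()
    mask = rois.mask(roi_name)
    if not mask.any():
        raise ValueError(f"ROI {roi_name!r} has no voxels")
    mean_conc = float(frame.values[mask].mean())  # Bq/mL
    mass_g = meta.subject_mass_kg * 1000.0
    denom = meta.injected_activity_mbq * 1e6 * decay_factor(imaging, t) / mass_g
    return mean_conc / denom


def roi_timeseries(
    frames: list[ScalarVolume],
    rois: RoiSet,
    meta: StudyMeta,
    imaging: Nuclide,
) -> pd.DataFrame:
    """Per-ROI mean concentration (Bq/mL), SUV and voxel count at each frame."""
    rows = []
    for frame in frames:
        t = frame.require_timestamp()
        for name in sorted(rois.labels):
            mask = rois.mask(name)
            rows.append(
                {
                    "roi": name,
                    "time_h": t,
                    "mean_bq_per_ml": float(frame.values[mask].mean()),
                    "suv": suv(frame, rois, name, meta, imaging),
                    "voxels": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DoseCoefficientTable:
    """Mean absorbed dose per unit administered therapy activity, Gy/GBq."""

    coefficients: dict[str, float]
    subject_id: str = ""

    def __post_init__(self) -> None:
        for roi, c in self.coefficients.items():
            if c < 0:
                raise ValueError(f"negative dose coefficient for ROI {roi!r}: {c}")

    def __getitem__(self, roi: str) -> float:
        return self.coefficients[roi]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"roi": list(self.coefficients), "gy_per_gbq": list(self.coefficients.values())}
        )


def dose_coefficients(dose: DoseMap, rois: RoiSet, subject_id: str = "") -> DoseCoefficientTable:
    """Extract per-ROI Gy/GBq coefficients from a dose map whose input frames
    were normalized to 1 GBq administered therapy activity."""
    if dose.normalized_to_gbq is None:
        raise ValueError(
            "dose map provenance lacks the administered-activity normalization; "
            "integrate frames scaled to a reference activity first"
        )
    out = {}
    for name in sorted(rois.labels):
        mask = rois.mask(name)
        if not mask.any():
            raise ValueError(f"ROI {name!r} has no voxels")
        out[name] = float(dose.volume.values[mask].mean()) / dose.normalized_to_gbq
    return DoseCoefficientTable(out, subject_id)


@dataclass
class RecoveryResult:
    ratio: float
    tolerance: float
    passed: bool


def whole_body_recovery(
    frame: ScalarVolume,
    meta: StudyMeta,
    imaging: Nuclide,
    tolerance: float = 0.10,
) -> RecoveryResult:
    """QC check: decay-corrected whole-body activity of the (first) frame
    against the injected activity; passes iff |ratio − 1| ≤ tolerance."""
    frame.require_units("Bq/mL", "whole-body frame")
    t = frame.require_timestamp()
    measured_bq = frame.total() / decay_factor(imaging, t)
    ratio = measured_bq / (meta.injected_activity_mbq * 1e6)
    return RecoveryResult(ratio=ratio, tolerance=tolerance, passed=abs(ratio - 1.0) <= tolerance)
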