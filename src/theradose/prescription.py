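"""Activity prescription under organ-dose constraints.

Given per-ROI dose coefficients (Gy/GBq), the administered therapy activity
is the largest activity keeping the binding constraint organ at or below the
dose limit: ``A = limit / c_binding``.  The default limit is 3 Gy to the bone
marrow, the dose-limiting organ for this class of radiolabeled antibodies.

Two binding rules are supported: ``max_over_rois`` (safety-conservative: the
constraint ROI with the highest coefficient binds, so no marrow region
exceeds the limit) and ``named_roi:<name>`` (a designated ROI binds; the
bundled canine coefficient table is consistent with the left-shoulder marrow
having been used this way).  Projected per-organ doses are computed from the
exact (unrounded) activity; activities are reported to 3 decimals (GBq) and
doses to 2 (Gy).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .metrics import DoseCoefficientTable

MARROW_ROIS = ("marrow_spine", "marrow_left_shoulder", "marrow_right_shoulder")


@dataclass(frozen=True)
class PrescriptionPolicy:
    dose_limit_gy: float = 3.0
    constraint_rois: tuple[str, ...] = MARROW_ROIS
    binding_rule: str = "max_over_rois"  # or "named_roi:<roi>"

    def __post_init__(self) -> None:
        if self.dose_limit_gy <= 0:
            raise ValueError(f"dose limit must be > 0 Gy, got {self.dose_limit_gy}")
        if not self.constraint_rois:
            raise ValueError("constraint_rois must be non-empty")
        if self.binding_rule != "max_over_rois" and not self.binding_rule.startswith("named_roi:"):
            raise ValueError(
                f"binding_rule must be 'max_over_rois' or 'named_roi:<roi>', got {self.binding_rule!r}"
            )


@dataclass
class PrescriptionResult:
    prescribed_activity_gbq: float  # exact; round to 3 decimals for reporting
    binding_roi: str
    projected_doses_gy: dict[str, float]  # exact; round to 2 decimals for reporting
    policy: PrescriptionPolicy

    @property
    def reported_activity_gbq(self) -> float:
        return round(self.prescribed_activity_gbq, 3)


def prescribe(coeffs: DoseCoefficientTable, policy: PrescriptionPolicy) -> PrescriptionResult:
    """Prescribe the administered activity for one subject."""
    missing = [r for r in policy.constraint_rois if r not in coeffs.coefficients]
    if missing:
        raise ValueError(f"constraint ROIs missing from coefficient table: {missing}")
    if policy.binding_rule == "max_over_rois":
        binding = max(policy.constraint_rois, key=lambda r: coeffs[r])
    else:
        binding = policy.binding_rule.split(":", 1)[1]
        if binding not in coeffs.coefficients:
            raise ValueError(f"binding ROI {binding!r} missing from coefficient table")
    c = coeffs[binding]
    if c <= 0:
        raise ValueError(f"binding ROI {binding!r} has non-positive coefficient {c}")
    activity = policy.dose_limit_gy / c
    projected = {roi: coeffs[roi] * activity for roi in coeffs.coefficients}
    return PrescriptionResult(activity, binding, projected, policy)


#: ROI order of the reference canine report layout.
_REPORT_ROIS = (
    "heart", "liver", "spleen", "adrenal_left", "adrenal_right",
    "kidney_left", "kidney_right", "marrow_spine", "marrow_left_shoulder",
    "marrow_right_shoulder", "testes",
)


def render_report(
    result: PrescriptionResult, coeffs: DoseCoefficientTable, rois: tuple[str, ...] | None = None
) -> str:
    """Render the per-ROI coefficient/projected-dose table as CSV text.

    Organs absent from the coefficient table (e.g. testes in females) are
    rendered as ``-``.
    """
    if rois is None:
        known = set(_REPORT_ROIS)
        rois = _REPORT_ROIS + tuple(r for r in sorted(coeffs.coefficients) if r not in known)
    lines = ["roi,gy_per_gbq,projected_gy"]
    for roi in rois:
        if roi in coeffs.coefficients:
            lines.append(
                f"{roi},{coeffs[roi]:.2f},{result.projected_doses_gy[roi]:.2f}"
            )
        else:
            lines.append(f"{roi},-,-")
    lines.append(f"prescribed_activity_gbq,{result.reported_activity_gbq:.3f},")
    lines.append(f"binding_roi,{result.binding_roi},")
    return "\n".join(lines) + "\n"


def parse_report(text: str) -> tuple[float, str, dict[str, tuple[float, float]]]:
    """Parse a rendered report back into (activity, binding ROI, per-ROI rows)."""
    df = pd.read_csv(io.StringIO(text), dtype=str).fillna("")
    rows: dict[str, tuple[float, float]] = {}
    activity = None
    binding = ""
    for _, rec in df.iterrows():
        if rec["roi"] == "prescribed_activity_gbq":
            activity = float(rec["gy_per_gbq"])
        elif rec["roi"] == "binding_roi":
            binding = rec["gy_per_gbq"]
        elif rec["gy_per_gbq"] != "-":
            rows[rec["roi"]] = (float(rec["gy_per_gbq"]), float(rec["projected_gy"]))
    if activity is None:
        raise ValueError("report lacks a prescribed_activity_gbq row")
    return activity, binding, rows


def load_coefficient_tables(path: str | Path | None = None) -> dict[str, DoseCoefficientTable]:
    """Load per-subject dose-coefficient tables from CSV
    (columns subject,roi,gy_per_gbq).  Default: the bundled canine table
    (three beagles imaged with the Zr-89-labeled IGF2R antibody)."""
    if path is None:
        text = resources.files("theradose.data").joinpath("canine_dose_coefficients.csv").read_text()
        df = pd.read_csv(io.StringIO(text))
    else:
        df = pd.read_csv(path)
    out = {}
    for subject, grp in df.groupby("subject", sort=False):
        out[str(subject)] = DoseCoefficientTable(
            dict(zip(grp["roi"], grp["gy_per_gbq"].astype(float))), str(subject)
        )
    return out
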