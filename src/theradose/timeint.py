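"""Time integration of dose-rate maps into absorbed dose.

The imaged frames sample the dose-rate curve at a handful of time points;
absorbed dose is the trapezoidal integral over the scan window plus explicit
head (injection → first scan) and tail (beyond last scan) terms:

* head ``constant_backfill`` — the first dose rate is assumed to hold from
  injection: ``Ḋ₁·t₁`` (conservative, activity present from T0);
  ``zero_at_origin`` instead ramps linearly from zero: ``½·Ḋ₁·t₁``.
* tail ``physical_decay`` — beyond the last scan the biological distribution
  is frozen and only physical decay of the therapy nuclide remains, giving
  the closed-form residual ``Ḋ_last/λ``; ``none`` drops the tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose import DoseRateMap
from .grids import ScalarVolume
from .nuclides import Nuclide

HEAD_MODES = ("constant_backfill", "zero_at_origin")
TAIL_MODES = ("physical_decay", "none")


@dataclass
class DoseMap:
    """Per-voxel absorbed dose (Gy) with integration provenance."""

    volume: ScalarVolume
    frame_times_h: tuple[float, ...]
    head: str
    tail: str
    #: administered therapy activity (GBq) the input frames were normalized
    #: to, if any; required downstream for Gy/GBq coefficient extraction
    normalized_to_gbq: float | None = None

    def __post_init__(self) -> None:
        self.volume.require_units("Gy", "dose map")
        if len(self.frame_times_h) < 1:
            raise ValueError("dose map provenance must list at least one frame time")


def integrate_dose(
    maps: list[DoseRateMap],
    therapy: Nuclide,
    tail: str = "physical_decay",
    head: str = "constant_backfill",
    normalized_to_gbq: float | None = None,
) -> DoseMap:
    """Trapezoid-integrate an ordered series of dose-rate maps.

    Per voxel: ``D = head + Σᵢ (Ḋᵢ+Ḋᵢ₊₁)/2·(tᵢ₊₁−tᵢ) + tail`` with the head
    and tail terms described in the module docstring.
    """
    if head not in HEAD_MODES:
        raise ValueError(f"head must be one of {HEAD_MODES}, got {head!r}")
    if tail not in TAIL_MODES:
        raise ValueError(f"tail must be one of {TAIL_MODES}, got {tail!r}")
    if not maps:
        raise ValueError("need at least one dose-rate map")
    grid = maps[0].volume.grid
    times = []
    for m in maps:
        m.volume.require_units("Gy/h", "dose-rate map")
        if m.volume.grid != grid:
            raise ValueError("dose-rate maps are on different grids")
        times.append(m.volume.require_timestamp())
    for a, b in zip(times, times[1:]):
        if b <= a:
            raise ValueError(f"frame times must be strictly increasing, got {a} then {b}")

    rates = np.stack([m.volume.values for m in maps])
    dose = np.trapezoid(rates, x=np.asarray(times), axis=0) if len(maps) > 1 else np.zeros(grid.shape)

    if head == "constant_backfill":
        dose = dose + rates[0] * times[0]
    else:
        dose = dose + 0.5 * rates[0] * times[0]
    if tail == "physical_decay":
        dose = dose + rates[-1] / therapy.decay_constant

    vol = ScalarVolume(grid, dose, "Gy")
    return DoseMap(vol, tuple(times), head, tail, normalized_to_gbq)
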