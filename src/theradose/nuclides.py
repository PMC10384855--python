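"""Radionuclide decay physics and small radiochemistry calculators.

The theranostic workflow images with one radionuclide (Zr-89, a positron
emitter with t1/2 = 78.41 h) and treats with a chemically analogous label
(Lu-177, a beta-minus emitter with t1/2 = 159.53 h).  Assuming shared
biological kinetics, an imaged activity-concentration field can be decay
corrected voxel by voxel from the imaging to the therapy nuclide; everything
else in the dose pipeline then operates on the therapy-nuclide field.

Emission spectra are summarized as a small set of lines: a single "charged"
line carrying the total mean charged-particle energy per decay (beta mean
energy plus conversion/Auger electrons) and the principal photon lines.  The
shipped table (``data/nuclides.json``) can be overridden by loading a user
constants file of the same schema.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .grids import ScalarVolume

LN2 = math.log(2.0)
KEV_TO_J = 1.602176634e-16


@dataclass(frozen=True)
class EmissionLine:
    """One summarized emission: ``kind`` is ``"charged"`` or ``"photon"``;
    energy in keV per emission; yield in emissions per decay."""

    kind: str
    mean_energy_kev: float
    yield_per_decay: float

    def __post_init__(self) -> None:
        if self.kind not in ("charged", "photon"):
            raise ValueError(f"emission kind must be 'charged' or 'photon', got {self.kind!r}")
        if self.mean_energy_kev <= 0:
            raise ValueError(f"emission energy must be > 0, got {self.mean_energy_kev}")
        if not 0 < self.yield_per_decay <= 1:
            raise ValueError(f"emission yield must be in (0, 1], got {self.yield_per_decay}")


@dataclass(frozen=True)
class Nuclide:
    """A radionuclide: half-life (h), derived decay constant (1/h), emission
    table and an optional gamma dose-rate constant Γ in µSv·m²·MBq⁻¹·h⁻¹."""

    name: str
    half_life_h: float
    emissions: tuple[EmissionLine, ...] = ()
    gamma_dose_rate_constant: float | None = None

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError(f"half-life must be > 0, got {self.half_life_h}")
        object.__setattr__(self, "emissions", tuple(self.emissions))

    @property
    def decay_constant(self) -> float:
        """λ = ln 2 / t½ in 1/h."""
        return LN2 / self.half_life_h

    @property
    def charged_energy_j_per_decay(self) -> float:
        """Total mean charged-particle energy per decay, J."""
        return sum(
            e.mean_energy_kev * e.yield_per_decay * KEV_TO_J
            for e in self.emissions
            if e.kind == "charged"
        )

    @property
    def photon_lines(self) -> tuple[EmissionLine, ...]:
        return tuple(e for e in self.emissions if e.kind == "photon")

    @property
    def photon_energy_j_per_decay(self) -> float:
        return sum(
            e.mean_energy_kev * e.yield_per_decay * KEV_TO_J for e in self.photon_lines
        )


def _parse_constants(raw: dict) -> dict[str, Nuclide]:
    out = {}
    for name, spec in raw["nuclides"].items():
        lines = tuple(
            EmissionLine(e["kind"], float(e["mean_energy_kev"]), float(e["yield"]))
            for e in spec.get("emissions", ())
        )
        out[name] = Nuclide(
            name=name,
            half_life_h=float(spec["half_life_h"]),
            emissions=lines,
            gamma_dose_rate_constant=spec.get("gamma_dose_rate_constant"),
        )
    return out


def load_nuclides(path: str | Path | None = None) -> dict[str, Nuclide]:
    """Load a nuclide constants file (JSON); default is the shipped table."""
    if path is None:
        raw = json.loads(resources.files("theradose.data").joinpath("nuclides.json").read_text())
    else:
        raw = json.loads(Path(path).read_text())
    return _parse_constants(raw)


_BUILTIN: dict[str, Nuclide] | None = None


def get_nuclide(name: str) -> Nuclide:
    """Look up a nuclide in the shipped constants table."""
    global _BUILTIN
    if _BUILTIN is None:
        _BUILTIN = load_nuclides()
    try:
        return _BUILTIN[name]
    except KeyError:
        raise KeyError(f"unknown nuclide {name!r}; shipped table has {sorted(_BUILTIN)}") from None


def decay_factor(nuclide: Nuclide, elapsed_h: float | np.ndarray) -> float | np.ndarray:
    """Fraction of activity remaining after ``elapsed_h`` hours: exp(−λ·t)."""
    elapsed = np.asarray(elapsed_h, dtype=float)
    if np.any(elapsed < 0):
        bad = float(np.min(elapsed))
        raise ValueError(f"elapsed time must be >= 0 h, got {bad}")
    out = np.exp(-nuclide.decay_constant * elapsed)
    return float(out) if np.isscalar(elapsed_h) else out


def substitute_isotope(
    measured: ScalarVolume, imaging: Nuclide, therapy: Nuclide
) -> ScalarVolume:
    """Decay correct an imaged activity volume to the therapy nuclide.

    Per voxel ``A_th(t) = A_img(t) · exp(+λ_img·t) · exp(−λ_th·t)``: the
    physical decay of the imaging label is removed and the therapy label's
    decay is applied, so the biological (decay-corrected) distribution is
    preserved exactly.  Time origin is injection.
    """
    measured.require_units("Bq/mL", "measured activity volume")
    t = measured.require_timestamp()
    if measured.nuclide_tag != imaging.name:
        raise ValueError(
            f"volume is tagged {measured.nuclide_tag!r}, not the stated imaging "
            f"nuclide {imaging.name!r}"
        )
    ratio = math.exp((imaging.decay_constant - therapy.decay_constant) * t)
    return measured.with_values(measured.values * ratio, nuclide_tag=therapy.name)


def radiolabeling_yield(cpm_bottom: float, cpm_top: float) -> float:
    """Radiolabeling yield (%) from an instant thin-layer chromatography strip
    cut in half: labeled antibody stays at the origin (bottom), free chelated
    label runs with the front (top)."""
    if cpm_bottom < 0 or cpm_top < 0:
        raise ValueError(f"counts must be >= 0, got ({cpm_bottom}, {cpm_top})")
    total = cpm_bottom + cpm_top
    if total == 0:
        raise ValueError("both strip halves have zero counts; yield undefined")
    return 100.0 * cpm_bottom / total

def external_dose_rate(activity_mbq: float, nuclide: Nuclide, distance_m: float) -> float:
    """Point-source external dose-rate estimate Γ·A/d² in µSv/h.

    Screening upper bound: no self-attenuation by the subject, valid at
    distances large against body size.
    """
    if distance_m <= 0:
        raise ValueError(f"distance must be > 0 m, got {distance_m}")
    if activity_mbq < 0:
        raise ValueError(f"activity must be >= 0 MBq, got {activity_mbq}")
    if nuclide.gamma_dose_rate_constant is None:
        raise ValueError(f"nuclide {nuclide.name} has no gamma dose-rate constant")
    return nuclide.gamma_dose_rate_constant * activity_mbq / distance_m**2
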