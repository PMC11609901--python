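"""Domain types and delta/ratio conversion shared by all reduction stages.

Isotope deltas are stored and exchanged in permil (‰) throughout the
package; the fractional form of the delta definition is internal to
:func:`delta_from_ratio` / :func:`ratio_from_delta` only.  Hydrogen and
oxygen deltas are referenced to VSMOW, carbon to VPDB.

Missing isotope channels (e.g. no CO, hence no δ13C/δ18O, from a
chromium-filled reactor) are represented as *absent* map entries, never
as zero; downstream stages skip absent channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

#: Canonical isotope channel keys used across the package.
ISOTOPES = ("d2H", "d13C", "d18O")

#: Gas whose mass-spectrometer peak carries each element.
PEAK_GAS = {"H": "H2", "C": "CO", "O": "CO"}

ROLES = ("standard", "qc", "sample", "blank")
REACTORS = ("glassy_carbon", "chromium")
AUTOSAMPLERS = ("zero_blank", "argon_hood")
MATERIAL_CLASSES = ("cellulose", "sugar", "wood", "leaf", "other")


class InvalidInputError(ValueError):
    """A physically or structurally invalid input value."""


class DegenerateWatersError(InvalidInputError):
    """Two-water exchange estimate requested with identical waters."""


class CalibrationError(RuntimeError):
    """Scale calibration could not be established from the run."""


class GenerationError(RuntimeError):
    """Synthetic run generation was asked for an impossible configuration."""


class SchemaError(ValueError):
    """A delimited file or registry does not match the expected schema."""


# ---------------------------------------------------------------------------
# Delta notation
# ---------------------------------------------------------------------------

def delta_from_ratio(r_sample, r_standard):
    """Convert an isotope abundance ratio to a delta value in permil.

    δ = (R_sample / R_standard − 1) · 1000, where R is e.g. 2H/1H of the
    sample and of the international reference (VSMOW or VPDB).

    Parameters
    ----------
    r_sample : float or array_like
        Isotope ratio of the sample, ≥ 0.
    r_standard : float
        Isotope ratio of the reference scale, > 0.

    Returns
    -------
    float or ndarray
        Delta value in ‰.
    """
    r_standard = np.asarray(r_standard, dtype=float)
    r_sample = np.asarray(r_sample, dtype=float)
    if np.any(r_standard <= 0):
        raise InvalidInputError("reference isotope ratio must be positive")
    if np.any(r_sample < 0):
        raise InvalidInputError("sample isotope ratio must be non-negative")
    out = 1000.0 * (r_sample / r_standard - 1.0)
    return out if out.ndim else float(out)


def ratio_from_delta(delta_permil, r_standard):
    """Inverse of :func:`delta_from_ratio`: R_sample from δ (‰) and R_standard."""
    r_standard = np.asarray(r_standard, dtype=float)
    if np.any(r_standard <= 0):
        raise InvalidInputError("reference isotope ratio must be positive")
    out = (np.asarray(delta_permil, dtype=float) / 1000.0 + 1.0) * r_standard
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Records and runs
# ---------------------------------------------------------------------------

@dataclass
class AnalysisRecord:
    """One instrument analysis (one capsule dropped into the reactor).

    ``delta_raw`` maps isotope keys (:data:`ISOTOPES`) to raw permil values
    as reported by the IRMS; an absent key means the channel was not
    measured.  ``peak_area`` maps gas species ("H2", "CO") to peak areas in
    arbitrary integrator units.
    """

    position: int
    material_id: str
    role: str
    delta_raw: dict = field(default_factory=dict)
    peak_area: dict = field(default_factory=dict)
    mass_mg: Optional[float] = None
    time_min: Optional[float] = None

    def __post_init__(self):
        if self.position < 1:
            raise InvalidInputError(f"positions are 1-based, got {self.position}")
        if self.role not in ROLES:
            raise InvalidInputError(f"unknown role {self.role!r}")
        for iso, v in self.delta_raw.items():
            if iso not in ISOTOPES:
                raise InvalidInputError(f"unknown isotope key {iso!r}")
            if not np.isfinite(v):
                raise InvalidInputError(f"non-finite {iso} value at position {self.position}")
        for gas, a in self.peak_area.items():
            if a < 0:
                raise InvalidInputError(f"negative {gas} peak area at position {self.position}")


@dataclass
class RunSequence:
    """An ordered instrument run plus the metadata needed to reduce it."""

    records: list
    reactor: str = "glassy_carbon"
    equilibration_water_id: Optional[str] = None
    autosampler: str = "zero_blank"
    run_date: Optional[str] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.reactor not in REACTORS:
            raise InvalidInputError(f"unknown reactor {self.reactor!r}")
        if self.autosampler not in AUTOSAMPLERS:
            raise InvalidInputError(f"unknown autosampler {self.autosampler!r}")
        positions = [r.position for r in self.records]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise InvalidInputError("record positions must be strictly increasing")
        if self.reactor == "chromium":
            # Chromium scavenges sample oxygen as Cr2O3: no CO, hence no C/O deltas.
            for r in self.records:
                bad = {"d13C", "d18O"} & set(r.delta_raw)
                if bad:
                    raise InvalidInputError(
                        f"chromium-reactor run carries {sorted(bad)} at position {r.position}"
                    )

    def __len__(self):
        return len(self.records)

    def isotopes_present(self):
        """Isotope channels measured anywhere in the run, in canonical order."""
        present = set()
        for r in self.records:
            present.update(r.delta_raw)
        return tuple(i for i in ISOTOPES if i in present)


# ---------------------------------------------------------------------------
# Registries
# ---------------------------------------------------------------------------

@dataclass
class ReferenceMaterial:
    """A calibration / quality-control material with certified delta values.

    ``certified`` maps isotope keys to permil values on the VSMOW (H, O) or
    VPDB (C) scale; for hydrogen the certified value refers to the
    nonexchangeable (carbon-bound) pool.  ``x_e`` is the fraction of the
    material's hydrogen that exchanges with water vapor during
    equilibration, or ``None`` when unknown.
    """

    id: str
    material_class: str = "other"
    certified: dict = field(default_factory=dict)
    x_e: Optional[float] = None
    n_content_pct: float = 0.0
    s_content_pct: float = 0.0
    exchanges_h: bool = True

    def __post_init__(self):
        if self.material_class not in MATERIAL_CLASSES:
            raise InvalidInputError(f"unknown material class {self.material_class!r}")
        if self.x_e is not None and not (0.0 <= self.x_e < 1.0):
            raise InvalidInputError(f"x_e must lie in [0, 1), got {self.x_e}")
        for iso, v in self.certified.items():
            if iso not in ISOTOPES:
                raise InvalidInputError(f"unknown isotope key {iso!r}")
            if not -1000.0 <= v <= 1000.0:
                raise InvalidInputError(f"certified {iso} of {self.id} out of range: {v}")
        if not self.exchanges_h and self.x_e not in (None, 0.0):
            raise InvalidInputError(f"{self.id}: non-exchanging material with x_e != 0")


@dataclass
class EquilibrationWater:
    """Water used for vapor equilibration of the exchangeable OH hydrogen."""

    id: str
    delta2H: float
    uncertainty: float = 0.0

    def __post_init__(self):
        if self.delta2H <= -1000.0:
            raise InvalidInputError("water δ2H must exceed −1000 ‰")


# ---------------------------------------------------------------------------
# Reduction outputs
# ---------------------------------------------------------------------------

@dataclass
class ScaleMap:
    """Affine map from corrected measured ‰ to calibrated ‰: y = gain·x + offset."""

    gain: float
    offset: float

    def __post_init__(self):
        if self.gain <= 0:
            raise CalibrationError(f"calibration gain must be positive, got {self.gain}")

    def __call__(self, x):
        return self.gain * np.asarray(x, dtype=float) + self.offset


@dataclass
class CalibrationModel:
    """Fitted per-run correction parameters.

    ``reactor_carbon_fraction`` is the implied fraction f of CO carbon
    contributed by the glassy-carbon reactor, recovered from the δ13C
    calibration gain as f = 1 − 1/gain (the constant-contribution mixing
    measured = (1−f)·true + f·δ13C_reactor has slope 1−f, which the
    two-point calibration inverts).
    """

    scale_map: dict = field(default_factory=dict)          # isotope -> ScaleMap
    memory_fraction: dict = field(default_factory=dict)    # isotope -> m
    drift_slope: dict = field(default_factory=dict)        # isotope -> ‰/position
    drift_applied: dict = field(default_factory=dict)      # isotope -> bool
    reactor_carbon_fraction: Optional[float] = None
    flags: set = field(default_factory=set)

    def __post_init__(self):
        for iso, m in self.memory_fraction.items():
            if not 0.0 <= m <= 0.05:
                raise InvalidInputError(f"memory fraction for {iso} outside [0, 0.05]: {m}")


@dataclass
class ReducedResult:
    """Final calibrated values for one analysis."""

    position: int
    material_id: str
    role: str
    d13C: Optional[float] = None
    d18O: Optional[float] = None
    d2H_e: Optional[float] = None   # calibrated, still equilibrated (pre exchange correction)
    d2H_ne: Optional[float] = None
    x_e_used: Optional[float] = None
    flags: set = field(default_factory=set)


def results_frame(results: Iterable[ReducedResult]):
    """Tabulate reduced results as a pandas DataFrame (one row per analysis)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "position": r.position,
                "material_id": r.material_id,
                "role": r.role,
                "d13C": r.d13C,
                "d18O": r.d18O,
                "d2H_e": r.d2H_e,
                "d2H_ne": r.d2H_ne,
                "x_e_used": r.x_e_used,
                "flags": ";".join(sorted(r.flags)),
            }
        )
    return pd.DataFrame(rows)
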