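"""Forward simulator for raw triple-isotope instrument runs.

Generates run sequences with the structure used in routine practice — a
standard block at the start, samples with a quality-control standard
interleaved every ~12 analyses, and a closing standard block — and imposes
the instrument effects the reduction pipeline must remove, each with known
truth:

1. exchangeable-H mixing with the equilibration water (δ2H only; skipped
   for non-exchanging materials such as polyethylene foil),
2. reactor-carbon mixing for δ13C in a glassy-carbon reactor,
3. linear instrument drift in position,
4. first-order memory carry-over,
5. i.i.d. Gaussian noise per isotope at typical triple-analysis precision
   (σ = 3.0 / 0.2 / 0.3 ‰ for δ2H / δ13C / δ18O).

The memory carry-over is recursive in the measured signal,
measured_i = (value_i + m·measured_{i−1})/(1+m), i.e. a carry fraction
m/(1+m) of the previous analysis; this parameterisation is the exact
conjugate of the difference-form memory correction with the same m, so the
standard correction inverts it without approximation.

An optional equilibration-loss model reproduces the behaviour of cellulose
on an argon-flushed autosampler, where the effective exchangeable fraction
relaxes from an initial toward a steady-state value over the first ~2 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    AnalysisRecord,
    EquilibrationWater,
    GenerationError,
    ReferenceMaterial,
    RunSequence,
)
from .exchange import DEFAULT_ALPHA_EW, forward_equilibrated_delta

#: Per-isotope 1-sigma analytical noise (‰) of a triple analysis.
DEFAULT_NOISE_SD = {"d2H": 3.0, "d13C": 0.2, "d18O": 0.3}

ISO_OF_GAS = {"H2": "d2H", "CO": "d13C"}


def default_materials() -> dict:
    """A realistic in-house registry: four calibration standards spanning the
    working isotope range, a sucrose quality control, a non-exchanging
    polyethylene foil, and five bulk materials covering 0.2–10.4 %N for
    reactor-comparison work."""
    mats = [
        ReferenceMaterial("CEL-LOW", "cellulose",
                          {"d2H": -150.0, "d13C": -30.0, "d18O": 20.0}, x_e=0.20),
        ReferenceMaterial("CEL-HIGH", "cellulose",
                          {"d2H": -50.0, "d13C": -22.0, "d18O": 30.0}, x_e=0.20),
        ReferenceMaterial("SUC-LOW", "sugar",
                          {"d2H": -110.0, "d13C": -14.0, "d18O": 25.0}, x_e=0.36),
        ReferenceMaterial("SUC-HIGH", "sugar",
                          {"d2H": -10.0, "d13C": -10.0, "d18O": 36.0}, x_e=0.36),
        ReferenceMaterial("QC-SUC", "sugar",
                          {"d2H": -85.0, "d13C": -25.6, "d18O": 31.0}, x_e=0.36),
        ReferenceMaterial("PEF", "other", {"d2H": -100.0, "d13C": -31.0},
                          exchanges_h=False),
        ReferenceMaterial("BEECH-WOOD", "wood",
                          {"d2H": -118.1, "d13C": -26.0, "d18O": 26.0},
                          x_e=0.15, n_content_pct=0.20),
        ReferenceMaterial("ALGAE", "other",
                          {"d2H": -112.7, "d13C": -20.0, "d18O": 24.0},
                          x_e=0.26, n_content_pct=1.27, s_content_pct=2.29),
        ReferenceMaterial("LEAVES", "leaf",
                          {"d2H": -107.5, "d13C": -27.0, "d18O": 25.0},
                          x_e=0.19, n_content_pct=2.94),
        ReferenceMaterial("FUNGUS", "other",
                          {"d2H": -27.2, "d13C": -24.0, "d18O": 22.0},
                          x_e=0.29, n_content_pct=4.67),
        ReferenceMaterial("INSECT", "other",
                          {"d2H": -121.3, "d13C": -23.0, "d18O": 18.0},
                          x_e=0.17, n_content_pct=10.42),
    ]
    return {m.id: m for m in mats}


def default_waters() -> dict:
    """The two in-house equilibration waters (δ2H −160 and −412 ‰ VSMOW)."""
    return {
        "W1": EquilibrationWater("W1", -160.0, 1.0),
        "W2": EquilibrationWater("W2", -412.0, 1.0),
    }


@dataclass
class EquilibrationLoss:
    """Exponential relaxation of the effective x_e on the autosampler.

    x_e(t) = steadystate + (initial − steadystate)·exp(−t/τ) with
    τ = relaxation_minutes / 3, so the loss is ≈95% relaxed at the stated
    relaxation window.  Applies only to cellulose-class materials on an
    argon-hood autosampler.
    """

    initial_xe: float = 0.13
    steadystate_xe: float = 0.07
    relaxation_minutes: float = 120.0

    def __post_init__(self):
        if self.relaxation_minutes <= 0:
            raise GenerationError("relaxation_minutes must be positive")


def generate_equilibration_loss(loss: EquilibrationLoss, t_minutes):
    """Effective x_e at time ``t_minutes`` since the run start."""
    tau = loss.relaxation_minutes / 3.0
    t = np.asarray(t_minutes, dtype=float)
    out = loss.steadystate_xe + (loss.initial_xe - loss.steadystate_xe) * np.exp(-t / tau)
    return out if out.ndim else float(out)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic run."""

    seed: int = 0
    n_samples: int = 24
    qc_interval: int = 12
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    memory_fraction: float = 0.02
    drift_slope: dict = field(default_factory=dict)   # isotope -> ‰/position
    reactor: str = "glassy_carbon"
    reactor_carbon_fraction: float = 0.15
    reactor_delta13C: float = -25.0
    water_id: Optional[str] = "W1"
    autosampler: str = "zero_blank"
    equilibration_loss: Optional[EquilibrationLoss] = None
    #: Optional affine instrument-scale distortion per isotope: (gain, offset).
    scale_distortion: dict = field(default_factory=dict)
    calibration_ids: tuple = ("CEL-LOW", "CEL-HIGH", "SUC-LOW", "SUC-HIGH")
    qc_id: str = "QC-SUC"
    block_replicates: int = 3
    qc_block_replicates: int = 3
    sample_class: str = "cellulose"
    sample_xe: float = 0.20
    minutes_per_analysis: float = 15.0

    def __post_init__(self):
        if self.qc_interval < 1:
            raise GenerationError("qc_interval must be ≥ 1")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise GenerationError("noise SDs must be non-negative")
        if not 0.0 <= self.reactor_carbon_fraction < 0.5:
            raise GenerationError("reactor carbon fraction must lie in [0, 0.5)")


def _sequence_plan(config):
    """Material/role layout: [standard block, samples + QC, standard block]."""
    block = []
    for mid in config.calibration_ids:
        block += [(mid, "standard")] * config.block_replicates
    block += [(config.qc_id, "qc")] * config.qc_block_replicates
    plan = list(block)
    for k in range(config.n_samples):
        plan.append((f"SAMPLE-{k + 1:03d}", "sample"))
        if (k + 1) % config.qc_interval == 0 and k + 1 < config.n_samples:
            plan.append((config.qc_id, "qc"))
    plan += block
    return plan


def generate_run(config: GeneratorConfig, materials: Optional[dict] = None,
                 waters: Optional[dict] = None):
    """Generate a raw run and its truth table.

    Returns
    -------
    run : RunSequence
        Raw (uncorrected, uncalibrated) analyses.
    truth : pandas.DataFrame
        One row per analysis with the true deltas (``d2H_ne``, ``d13C``,
        ``d18O``), the effective exchange fraction and timing, against
        which the reduction can be checked.

    Notes
    -----
    Deterministic for a given ``config.seed``.  Sample materials are drawn
    uniformly within the span of the calibration standards, as a sample
    batch bracketed by the standards would be.
    """
    materials = default_materials() if materials is None else materials
    waters = default_waters() if waters is None else waters
    missing = [m for m in (*config.calibration_ids, config.qc_id) if m not in materials]
    if missing:
        raise GenerationError(f"registry lacks required material(s): {', '.join(missing)}")
    if config.qc_id not in materials:
        raise GenerationError("registry lacks a QC material")
    water = None
    if config.water_id is not None:
        if config.water_id not in waters:
            raise GenerationError(f"unknown equilibration water {config.water_id}")
        water = waters[config.water_id]

    rng = np.random.default_rng(config.seed)
    triple = config.reactor == "glassy_carbon"
    cal_mats = [materials[m] for m in config.calibration_ids]
    span = {
        iso: (min(m.certified[iso] for m in cal_mats if iso in m.certified),
              max(m.certified[iso] for m in cal_mats if iso in m.certified))
        for iso in ("d2H", "d13C", "d18O")
    }

    plan = _sequence_plan(config)
    # true deltas per analysis
    true_rows = []
    sample_truth = {}
    for pos, (mid, role) in enumerate(plan, start=1):
        if role == "sample":
            if mid not in sample_truth:
                sample_truth[mid] = {
                    iso: float(rng.uniform(*span[iso])) for iso in span
                }
            cert = sample_truth[mid]
            xe = config.sample_xe
            mclass = config.sample_class
            exchanges = True
        else:
            mat = materials[mid]
            cert = mat.certified
            xe = mat.x_e if mat.exchanges_h else 0.0
            mclass = mat.material_class
            exchanges = mat.exchanges_h
        true_rows.append(
            dict(position=pos, material_id=mid, role=role, material_class=mclass,
                 d2H_ne=cert.get("d2H"), d13C=cert.get("d13C"),
                 d18O=cert.get("d18O"), x_e=xe if exchanges else 0.0,
                 exchanges_h=exchanges)
        )

    m = config.memory_fraction
    prev_measured: dict[str, float] = {}
    records = []
    for row in true_rows:
        t = (row["position"] - 1) * config.minutes_per_analysis
        row["time_min"] = t
        deltas = {}
        # 1. exchange mixing (δ2H)
        if row["d2H_ne"] is not None:
            if water is not None and row["exchanges_h"]:
                xe_eff = row["x_e"]
                if (
                    config.equilibration_loss is not None
                    and config.autosampler == "argon_hood"
                    and row["material_class"] == "cellulose"
                ):
                    xe_eff = float(
                        generate_equilibration_loss(config.equilibration_loss, t)
                    )
                row["x_e_effective"] = xe_eff
                deltas["d2H"] = float(
                    forward_equilibrated_delta(row["d2H_ne"], water.delta2H,
                                               xe_eff, DEFAULT_ALPHA_EW)
                )
            else:
                row["x_e_effective"] = 0.0
                deltas["d2H"] = row["d2H_ne"]
        # 2. reactor carbon mixing (δ13C, glassy carbon only); chromium traps
        # sample oxygen as Cr2O3, so no CO and no C/O channels at all.
        if triple:
            if row["d13C"] is not None:
                f = config.reactor_carbon_fraction
                deltas["d13C"] = (1.0 - f) * row["d13C"] + f * config.reactor_delta13C
            if row["d18O"] is not None:
                deltas["d18O"] = row["d18O"]
        for iso in list(deltas):
            v = deltas[iso]
            # optional affine instrument-scale distortion
            if iso in config.scale_distortion:
                a, b = config.scale_distortion[iso]
                v = a * v + b
            # 3. linear drift
            v += config.drift_slope.get(iso, 0.0) * (row["position"] - 1)
            # 4. recursive memory carry-over (conjugate of the difference-form
            #    correction: the correction with the same m inverts it exactly)
            if iso in prev_measured:
                v = (v + m * prev_measured[iso]) / (1.0 + m)
            prev_measured[iso] = v
            # 5. analytical noise.  noise_sd is the precision of the final
            # *calibrated* value (how instrument precision is quoted), so the
            # raw-scale injection is scaled by the inverse calibration gain —
            # the reactor-carbon damping (1−f) for δ13C, and any configured
            # scale-distortion gain.
            sd = config.noise_sd.get(iso, 0.0)
            if sd > 0:
                scale = config.scale_distortion.get(iso, (1.0, 0.0))[0]
                if iso == "d13C" and triple:
                    scale *= 1.0 - config.reactor_carbon_fraction
                v += float(rng.normal(0.0, sd * scale))
            deltas[iso] = v
        mass = 1.0
        areas = {"H2": 60.0 * mass}
        if triple:
            areas["CO"] = 40.0 * mass
        records.append(
            AnalysisRecord(position=row["position"], material_id=row["material_id"],
                           role=row["role"], delta_raw=deltas, peak_area=areas,
                           mass_mg=mass, time_min=t)
        )

    run = RunSequence(records=records, reactor=config.reactor,
                      equilibration_water_id=config.water_id,
                      autosampler=config.autosampler, seed=config.seed)
    truth = pd.DataFrame(true_rows).drop(columns=["exchanges_h"])
    return run, truth
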