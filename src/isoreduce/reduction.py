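"""Run-level corrections, applied in a fixed order.

For each isotope channel of a run the pipeline is

    memory correction → drift correction → two-point scale calibration,

followed, for δ2H, by the exchangeable-hydrogen correction.  Memory and
drift are sequence effects on the measured values and must be removed
before the affine scale calibration; the exchange correction operates on
calibrated permil values because the two-pool algebra is written with
VSMOW-scale water deltas.

The glassy-carbon reactor contributes a roughly constant ~15% of the CO
carbon, so raw δ13C is a damped mixture (1−f)·δ_sample + f·δ_reactor;
being affine, this is absorbed — and thereby corrected — by the δ13C
two-point calibration, whose fitted gain implies f = 1 − 1/gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import (
    CalibrationModel,
    CalibrationError,
    InvalidInputError,
    ReducedResult,
    RunSequence,
    ScaleMap,
    ISOTOPES,
)
from .exchange import (
    DEFAULT_ALPHA_EW,
    XE_OUT_OF_RANGE_FLAG,
    default_xe,
    forward_equilibrated_delta,
    nonexchangeable_delta,
)

#: Default grid over which the memory fraction is searched (0–5% in 0.1% steps).
MEMORY_GRID = np.round(np.arange(0.0, 0.0501, 0.001), 4)

#: Default drift gate: slopes smaller than this (‰/position) are not applied.
DRIFT_SLOPE_THRESHOLD = 0.005

PRE_STEADY_STATE_FLAG = "pre-steady-state"


# ---------------------------------------------------------------------------
# Memory correction
# ---------------------------------------------------------------------------

def apply_memory_correction(values, m):
    """First-order memory correction of an ordered series of permil values.

    corrected_i = measured_i + m·(measured_i − measured_{i−1}); the first
    element has no predecessor and is returned unchanged.  ``m`` is the
    memory fraction (typically 0.01–0.03).
    """
    if not 0.0 <= m < 0.5:
        raise InvalidInputError(f"memory fraction outside [0, 0.5): {m}")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v.copy()
    out = v.copy()
    out[1:] += m * (v[1:] - v[:-1])
    return out


@dataclass
class MemoryFit:
    """Result of the iterative memory-fraction search."""

    m: float
    pooled_sd: float
    warnings: list = field(default_factory=list)


def _pooled_within_sd(values, groups):
    """Pooled within-group sample SD (n−1 weights); NaN when no group has ≥ 2."""
    ss = 0.0
    dof = 0
    for g in set(groups):
        x = values[np.asarray(groups) == g]
        if x.size >= 2:
            ss += float(np.sum((x - x.mean()) ** 2))
            dof += x.size - 1
    return np.sqrt(ss / dof) if dof else np.nan


def fit_memory_fraction(run, isotope, materials, *, grid=None, detrend=True,
                        fit_mask=None):
    """Grid-search the memory fraction minimising reference-material scatter.

    For each candidate m the whole channel series is memory-corrected and
    the pooled within-material standard deviation of the standard-role
    analyses is evaluated; the argmin is returned, ties broken toward
    smaller m.  With ``detrend`` (default) a block-mean linear drift
    estimate is removed before the scatter is computed, so a genuine
    instrument drift does not bias the memory estimate.

    Requires at least one standard material with ≥ 3 replicates; otherwise
    m = 0 is returned with a warning.
    """
    grid = MEMORY_GRID if grid is None else np.asarray(grid, dtype=float)
    idx = [i for i, r in enumerate(run.records) if isotope in r.delta_raw]
    if fit_mask is None:
        fit_mask = np.ones(len(run.records), dtype=bool)
    values = np.array([run.records[i].delta_raw[isotope] for i in idx])
    positions = np.array([run.records[i].position for i in idx], dtype=float)
    mats = np.array([run.records[i].material_id for i in idx])
    is_std = np.array(
        [run.records[i].role == "standard" and fit_mask[i] for i in idx]
    )
    counts = {}
    for mid in mats[is_std]:
        counts[mid] = counts.get(mid, 0) + 1
    if not counts or max(counts.values()) < 3:
        return MemoryFit(0.0, np.nan, ["insufficient reference replicates; m = 0 assumed"])

    start_mask, end_mask = _block_masks(run, idx)
    sds = np.empty(grid.size)
    for k, m in enumerate(grid):
        corr = apply_memory_correction(values, m)
        if detrend:
            slope = _drift_slope_from_blocks(corr, positions, mats, is_std,
                                             start_mask, end_mask)
            if slope is not None:
                corr = corr - slope * positions
        sds[k] = _pooled_within_sd(corr[is_std], mats[is_std])
    return MemoryFit(float(grid[int(np.argmin(sds))]), float(np.nanmin(sds)))


# ---------------------------------------------------------------------------
# Drift correction
# ---------------------------------------------------------------------------

def _block_masks(run, idx):
    """Start/end standard-block membership for the channel subset ``idx``.

    A block is the maximal run prefix (suffix) consisting of standard and
    QC analyses.
    """
    roles = [r.role for r in run.records]
    n = len(roles)
    start_end = 0
    while start_end < n and roles[start_end] in ("standard", "qc"):
        start_end += 1
    end_start = n
    while end_start > 0 and roles[end_start - 1] in ("standard", "qc"):
        end_start -= 1
    start_mask = np.array([i < start_end for i in idx])
    end_mask = np.array([i >= end_start and i >= start_end for i in idx])
    return start_mask, end_mask


def _drift_slope_from_blocks(values, positions, material_ids, fit_ok,
                             start_mask, end_mask):
    """Linear drift slope (‰/position) from start-vs-end block means.

    For every material analysed in both terminal standard blocks the slope
    is (end mean − start mean)/(end mean position − start mean position);
    the per-material slopes are averaged.  Returns ``None`` when no
    material spans both blocks.
    """
    slopes = []
    for mid in np.unique(material_ids[fit_ok]):
        sel = (material_ids == mid) & fit_ok
        s, e = sel & start_mask, sel & end_mask
        if s.any() and e.any():
            dp = positions[e].mean() - positions[s].mean()
            if dp > 0:
                slopes.append((values[e].mean() - values[s].mean()) / dp)
    return float(np.mean(slopes)) if slopes else None


def drift_correction(values, positions, slope, *, threshold=DRIFT_SLOPE_THRESHOLD):
    """Remove a linear-in-position drift if the slope clears the gate.

    Returns ``(corrected, applied)``; below-threshold slopes (or ``None``)
    leave the series unchanged (``applied`` False — "no drift applied").
    The trend is anchored at position 1, so the run start is preserved;
    any constant offset introduced is absorbed by the scale calibration.
    """
    v = np.asarray(values, dtype=float)
    if slope is None or abs(slope) < threshold:
        return v.copy(), False
    p = np.asarray(positions, dtype=float)
    return v - slope * (p - 1.0), True


# ---------------------------------------------------------------------------
# Two-point scale calibration
# ---------------------------------------------------------------------------

def fit_two_point_calibration(measured, certified):
    """Affine scale map from per-material mean measured to certified ‰.

    With exactly two materials the line is exact; with more, an ordinary
    least-squares line.  The materials must span a non-degenerate range on
    both axes.
    """
    measured = np.asarray(measured, dtype=float)
    certified = np.asarray(certified, dtype=float)
    if measured.size != certified.size:
        raise InvalidInputError("measured/certified length mismatch")
    if measured.size < 2:
        raise CalibrationError("two-point calibration needs at least two materials")
    if np.ptp(measured) == 0 or np.ptp(certified) == 0:
        raise CalibrationError("calibration materials do not span a range")
    if measured.size == 2:
        gain = (certified[1] - certified[0]) / (measured[1] - measured[0])
        offset = certified[0] - gain * measured[0]
    else:
        gain, offset = np.polyfit(measured, certified, 1)
    return ScaleMap(gain=float(gain), offset=float(offset))


# ---------------------------------------------------------------------------
# Full run reduction
# ---------------------------------------------------------------------------

@dataclass
class ReduceOptions:
    """Tunable parameters of :func:`reduce_run`."""

    alpha_ew: float = DEFAULT_ALPHA_EW
    #: Fixed memory fraction (scalar or per-isotope dict); fitted when None.
    memory_fraction: Optional[object] = None
    memory_grid: Optional[np.ndarray] = None
    drift_threshold: float = DRIFT_SLOPE_THRESHOLD
    #: Override x_e (scalar, or dict keyed by material id); class/registry
    #: defaults apply when None.
    x_e: Optional[object] = None
    #: Analyses earlier than this (minutes) on an argon-hood autosampler are
    #: flagged pre-steady-state for cellulose materials and excluded from fits.
    steady_state_minutes: float = 120.0
    #: Material class assumed for sample-role analyses that are not in the
    #: registry (runs are normally of one sample type); sets their default
    #: x_e and their steady-state handling.
    sample_class: str = "cellulose"


@dataclass
class ReductionOutput:
    """Reduced per-analysis results plus the fitted calibration."""

    results: list
    calibration: CalibrationModel
    warnings: list = field(default_factory=list)


def _option_for(opt, isotope):
    if opt is None:
        return None
    if isinstance(opt, dict):
        return opt.get(isotope)
    return opt


def _presteady_mask(run, materials, options):
    """True where a record may enter calibration/memory/drift fits."""
    ok = np.ones(len(run.records), dtype=bool)
    if run.autosampler != "argon_hood":
        return ok
    for i, rec in enumerate(run.records):
        mat = materials.get(rec.material_id)
        if mat is not None:
            mclass = mat.material_class
        elif rec.role == "sample":
            mclass = options.sample_class
        else:
            continue
        if (
            mclass == "cellulose"
            and rec.time_min is not None
            and rec.time_min < options.steady_state_minutes
        ):
            ok[i] = False
    return ok


def _resolve_xe(rec, mat, options, flags):
    from .exchange import CLASS_DEFAULT_XE

    override = options.x_e
    if isinstance(override, dict) and rec.material_id in override:
        return float(override[rec.material_id])
    if override is not None and not isinstance(override, dict):
        if mat is not None and not mat.exchanges_h:
            return 0.0
        return float(override)
    if mat is not None:
        xe = default_xe(mat)
    elif rec.role == "sample":
        # unregistered samples take the run's sample-class default
        xe = CLASS_DEFAULT_XE.get(options.sample_class)
    else:
        xe = None
    if xe is None:
        flags.add("x_e unknown; no exchange correction")
        return 0.0
    return xe


def reduce_run(run: RunSequence, materials: dict, waters: dict,
               options: Optional[ReduceOptions] = None) -> ReductionOutput:
    """Reduce a raw run to calibrated δ13C, δ18O and δ2H_ne values.

    Parameters
    ----------
    run : RunSequence
        The raw instrument run.
    materials : dict
        material_id → :class:`~isoreduce.core.ReferenceMaterial`; every
        non-blank analysis must reference a registered material.
    waters : dict
        water_id → :class:`~isoreduce.core.EquilibrationWater`.
    options : ReduceOptions, optional

    Notes
    -----
    Hydrogen standards are calibrated against their *expected equilibrated*
    values (forward two-pool mixing of the certified nonexchangeable δ2H
    with the run's equilibration water at the material's x_e); the exchange
    correction is then applied uniformly to all calibrated records.  This
    keeps the calibration well defined even though certified values refer
    to the nonexchangeable pool while the instrument sees equilibrated
    material.
    """
    options = options or ReduceOptions()
    unknown = sorted(
        {r.material_id for r in run.records
         if r.role in ("standard", "qc") and r.material_id not in materials}
    )
    if unknown:
        raise InvalidInputError(f"material(s) not in registry: {', '.join(unknown)}")

    water = None
    if run.equilibration_water_id is not None:
        if run.equilibration_water_id not in waters:
            raise InvalidInputError(
                f"equilibration water not in registry: {run.equilibration_water_id}"
            )
        water = waters[run.equilibration_water_id]

    n = len(run.records)
    fit_ok = _presteady_mask(run, materials, options)
    rec_flags = [set() for _ in range(n)]
    for i, keep in enumerate(fit_ok):
        if not keep:
            rec_flags[i].add(PRE_STEADY_STATE_FLAG)

    calibrated = {}          # isotope -> dict record_index -> value
    model = CalibrationModel()
    warnings: list[str] = []

    for isotope in run.isotopes_present():
        idx = [i for i, r in enumerate(run.records) if isotope in r.delta_raw]
        values = np.array([run.records[i].delta_raw[isotope] for i in idx])
        positions = np.array([run.records[i].position for i in idx], dtype=float)
        mats = np.array([run.records[i].material_id for i in idx])
        is_std = np.array(
            [run.records[i].role == "standard" and fit_ok[i] for i in idx]
        )

        # 1. memory — applied exactly once per channel
        m_fixed = _option_for(options.memory_fraction, isotope)
        if m_fixed is None:
            fit = fit_memory_fraction(run, isotope, materials,
                                      grid=options.memory_grid, fit_mask=fit_ok)
            m = fit.m
            warnings.extend(f"{isotope}: {w}" for w in fit.warnings)
        else:
            m = float(m_fixed)
        corrected = apply_memory_correction(values, m)
        model.memory_fraction[isotope] = m

        # 2. drift
        start_mask, end_mask = _block_masks(run, idx)
        if not start_mask.any() or not end_mask.any():
            slope = None
            warnings.append(f"{isotope}: single standard block — no drift correction")
        else:
            slope = _drift_slope_from_blocks(corrected, positions, mats, is_std,
                                             start_mask, end_mask)
        corrected, applied = drift_correction(corrected, positions, slope,
                                              threshold=options.drift_threshold)
        model.drift_slope[isotope] = slope if slope is not None else 0.0
        model.drift_applied[isotope] = applied
        if slope is not None and not applied:
            warnings.append(f"{isotope}: no drift applied (|slope| below threshold)")

        # 3. two-point scale calibration (QC and pre-steady-state excluded)
        meas_means, expect = [], []
        for mid in sorted(set(mats[is_std])):
            mat = materials[mid]
            if isotope not in mat.certified:
                continue
            sel = is_std & (mats == mid)
            meas_means.append(float(corrected[sel].mean()))
            cert = mat.certified[isotope]
            if isotope == "d2H" and water is not None and mat.exchanges_h:
                xe_std = default_xe(mat)
                if xe_std is None:
                    continue
                cert = forward_equilibrated_delta(cert, water.delta2H, xe_std,
                                                  options.alpha_ew)
            expect.append(cert)
        try:
            smap = fit_two_point_calibration(meas_means, expect)
        except CalibrationError as exc:
            warnings.append(f"{isotope}: channel skipped — {exc}")
            for i in idx:
                rec_flags[i].add(f"{isotope}: calibration failed")
            continue
        model.scale_map[isotope] = smap
        calibrated[isotope] = dict(zip(idx, smap(corrected)))

    if run.reactor == "glassy_carbon" and "d13C" in model.scale_map:
        model.reactor_carbon_fraction = 1.0 - 1.0 / model.scale_map["d13C"].gain

    # 4. exchange-correction dispatch and assembly
    results = []
    for i, rec in enumerate(run.records):
        flags = rec_flags[i]
        mat = materials.get(rec.material_id)
        res = ReducedResult(position=rec.position, material_id=rec.material_id,
                            role=rec.role, flags=flags)
        if "d13C" in calibrated and i in calibrated["d13C"]:
            res.d13C = float(calibrated["d13C"][i])
        if "d18O" in calibrated and i in calibrated["d18O"]:
            res.d18O = float(calibrated["d18O"][i])
        if "d2H" in calibrated and i in calibrated["d2H"]:
            res.d2H_e = float(calibrated["d2H"][i])
            if water is None:
                res.x_e_used = 0.0
                res.d2H_ne = res.d2H_e
                flags.add("no equilibration water; δ2H reported uncorrected")
            else:
                xe = _resolve_xe(rec, mat, options, flags)
                if not 0.0 <= xe < 1.0:
                    flags.add(XE_OUT_OF_RANGE_FLAG)
                res.x_e_used = xe
                res.d2H_ne = float(
                    nonexchangeable_delta(res.d2H_e, water.delta2H, xe,
                                          options.alpha_ew)
                ) if xe < 1.0 else None
        results.append(res)

    return ReductionOutput(results=results, calibration=model, warnings=warnings)
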