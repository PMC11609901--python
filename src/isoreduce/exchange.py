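"""Exchangeable-hydrogen correction.

Hydroxyl-bound hydrogen in carbohydrates exchanges with ambient water, so
the raw δ2H of an equilibrated sample is a two-pool mixture of the
carbon-bound (nonexchangeable) signal and the equilibration water,
fractionated by the equilibrium factor α_e−w:

    δ2H_e = (1 − x_e)·δ2H_ne + x_e·(α·δ2H_w + 1000·(α − 1))

Equilibrating the same material with two isotopically distant waters
identifies the exchangeable fraction

    x_e = (δ2H_e1 − δ2H_e2) / (α·(δ2H_w1 − δ2H_w2))

and a single equilibration with known x_e yields the nonexchangeable value

    δ2H_ne = (δ2H_e1 − x_e·α·δ2H_w1 − 1000·x_e·(α − 1)) / (1 − x_e).

All deltas are in permil on the VSMOW scale.  The default α_e−w = 1.082
applies to cellulose and is taken to hold for other carbohydrates, whose
exchangeable hydrogen likewise sits on hydroxyl groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DegenerateWatersError, EquilibrationWater, InvalidInputError

#: Equilibrium fractionation factor between exchangeable H and water, carbohydrates.
DEFAULT_ALPHA_EW = 1.082

#: Typical exchangeable fractions by material class (single-equilibration runs).
CLASS_DEFAULT_XE = {"cellulose": 0.20, "wood": 0.15, "sugar": 0.36}

#: Flag attached when a two-water estimate falls outside the physical [0, 1) range.
XE_OUT_OF_RANGE_FLAG = "x_e outside [0, 1)"


@dataclass
class ExchangeParameters:
    """Fractionation factor and equilibration waters for one reduction."""

    alpha_ew: float = DEFAULT_ALPHA_EW
    water1: EquilibrationWater | None = None
    water2: EquilibrationWater | None = None

    def __post_init__(self):
        if not 1.0 < self.alpha_ew < 1.2:
            raise InvalidInputError(f"alpha_ew outside plausible (1.0, 1.2): {self.alpha_ew}")
        if (
            self.water1 is not None
            and self.water2 is not None
            and self.water1.delta2H == self.water2.delta2H
        ):
            raise DegenerateWatersError("the two equilibration waters must differ in δ2H")


def exchanged_fraction(d_e1, d_e2, d_w1, d_w2, alpha_ew=DEFAULT_ALPHA_EW):
    """Exchangeable H fraction x_e from two equilibrations with distinct waters.

    Parameters are permil values: the two measured equilibrated sample
    deltas ``d_e1``/``d_e2`` and the corresponding water deltas
    ``d_w1``/``d_w2``.  The estimate is returned unclamped — values outside
    [0, 1) indicate noise or an equilibration failure and are the caller's
    responsibility to flag (see :data:`XE_OUT_OF_RANGE_FLAG`).
    """
    if alpha_ew <= 0:
        raise InvalidInputError("alpha_ew must be positive")
    d_w1 = np.asarray(d_w1, dtype=float)
    d_w2 = np.asarray(d_w2, dtype=float)
    if np.any(d_w1 == d_w2):
        raise DegenerateWatersError("equilibration waters have identical δ2H")
    out = (np.asarray(d_e1, float) - np.asarray(d_e2, float)) / (alpha_ew * (d_w1 - d_w2))
    return out if out.ndim else float(out)


def nonexchangeable_delta(d_e1, d_w1, x_e, alpha_ew=DEFAULT_ALPHA_EW):
    """δ2H of the carbon-bound hydrogen from one equilibration and a known x_e.

    ``x_e`` ≥ 1 is rejected; a (noise-driven) negative ``x_e`` is accepted
    and simply extrapolates the two-pool algebra.
    """
    x_e = np.asarray(x_e, dtype=float)
    if np.any(x_e >= 1.0):
        raise InvalidInputError("x_e must be below 1")
    out = (
        np.asarray(d_e1, float)
        - x_e * alpha_ew * np.asarray(d_w1, float)
        - 1000.0 * x_e * (alpha_ew - 1.0)
    ) / (1.0 - x_e)
    return out if out.ndim else float(out)


def forward_equilibrated_delta(d_ne, d_w, x_e, alpha_ew=DEFAULT_ALPHA_EW):
    """Forward two-pool mixing: equilibrated δ2H from a nonexchangeable value.

    Algebraic inverse of :func:`nonexchangeable_delta`; used by the run
    simulator to impose a known exchange state.
    """
    x_e = np.asarray(x_e, dtype=float)
    if np.any((x_e < 0) | (x_e >= 1.0)):
        raise InvalidInputError("x_e must lie in [0, 1)")
    out = (1.0 - x_e) * np.asarray(d_ne, float) + x_e * (
        alpha_ew * np.asarray(d_w, float) + 1000.0 * (alpha_ew - 1.0)
    )
    return out if out.ndim else float(out)


def default_xe(material) -> float | None:
    """Resolve the x_e to assume for a material in a single-equilibration run.

    Order of precedence: non-exchanging materials (x_e = 0), the material's
    own registered x_e, then the class-typical default; ``None`` when no
    value can be resolved.
    """
    if not material.exchanges_h:
        return 0.0
    if material.x_e is not None:
        return material.x_e
    return CLASS_DEFAULT_XE.get(material.material_class)


def paired_run_exchange_fraction(results1, results2, water1, water2,
                                 alpha_ew=DEFAULT_ALPHA_EW):
    """Per-material x_e from the same materials reduced in two runs.

    ``results1``/``results2`` are :class:`~isoreduce.core.ReducedResult`
    collections from runs equilibrated with ``water1`` and ``water2``; the
    estimator is applied to each shared material's mean *calibrated
    equilibrated* δ2H (``d2H_e``), the quantity the two-water identity is
    written in.

    Returns a dict material_id → x_e.
    """
    def _means(results):
        acc: dict[str, list] = {}
        for r in results:
            if r.d2H_e is not None:
                acc.setdefault(r.material_id, []).append(r.d2H_e)
        return {k: float(np.mean(v)) for k, v in acc.items()}

    m1, m2 = _means(results1), _means(results2)
    shared = sorted(set(m1) & set(m2))
    return {
        mid: exchanged_fraction(m1[mid], m2[mid], water1.delta2H, water2.delta2H, alpha_ew)
        for mid in shared
    }
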