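"""Quality control, precision statistics, and reactor-comparison analyses.

Includes sequence validation, QC-material precision (the run's working
definition of analytical precision), element content from peak areas, the
glassy-carbon vs chromium reactor δ2H_ne comparison for nitrogen-bearing
materials, and the nitrogen-bias regression used to flag materials whose
high N content may bias δ2H through HCN formation in a glassy-carbon
reactor.

A reference comparison dataset of five bulk materials spanning 0.2–10.4 %N
(wood, algae, leaves, fungus, insect) is bundled as ``data/table2.csv``;
the stored nitrogen-bias regression used by :func:`interference_flags` is
fitted from it at first use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import InvalidInputError, ReducedResult, RunSequence, results_frame

#: Minimum certified span (‰) the calibration standards should cover.
DEFAULT_MIN_SPAN = {"d2H": 50.0, "d13C": 5.0, "d18O": 5.0}

#: N content (%) above which a glassy-carbon δ2H result is flagged.
N_CONTENT_THRESHOLD = 5.0
#: S content (%) above which possible H2S interference is flagged.
S_CONTENT_THRESHOLD = 1.0


def load_reactor_comparison_table() -> pd.DataFrame:
    """The bundled five-material glassy-carbon vs chromium comparison."""
    with resources.files("isoreduce.data").joinpath("table2.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# Sequence validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.warnings


def validate_sequence(run: RunSequence, materials: Optional[dict] = None,
                      qc_interval: int = 12,
                      min_span: Optional[dict] = None) -> ValidationReport:
    """Check the run layout against the standard sequence design.

    Warns (never raises) when: a terminal standard block is missing; no QC
    analyses are interleaved with the samples, or their spacing exceeds
    ~1.5× the configured interval; or the calibration standards span less
    than the configured range for a measured isotope (certified values are
    used when a registry is supplied, raw measured values otherwise).
    """
    min_span = DEFAULT_MIN_SPAN if min_span is None else min_span
    report = ValidationReport()
    roles = [r.role for r in run.records]
    n = len(roles)
    if n == 0:
        report.warnings.append("empty run")
        return report

    start = 0
    while start < n and roles[start] in ("standard", "qc"):
        start += 1
    end = n
    while end > 0 and roles[end - 1] in ("standard", "qc"):
        end -= 1
    if start == 0 or "standard" not in roles[:start]:
        report.warnings.append("no initial standard block")
    if end == n or "standard" not in roles[end:] or end <= start:
        report.warnings.append("no terminal standard block")

    sample_section = list(range(start, max(end, start)))
    if any(roles[i] == "sample" for i in sample_section):
        qc_pos = [i for i in sample_section if roles[i] == "qc"]
        gaps = []
        prev = start - 1
        for i in [*qc_pos, max(end, start)]:
            gaps.append(i - prev - 1)
            prev = i
        if not qc_pos and sum(1 for i in sample_section if roles[i] == "sample") > qc_interval:
            report.warnings.append("no quality control interleaved with samples")
        elif gaps and max(gaps) > 1.5 * qc_interval:
            report.warnings.append(
                f"QC spacing up to {max(gaps)} samples exceeds ~{qc_interval}"
            )

    std_ids = {r.material_id for r in run.records if r.role == "standard"}
    for iso in run.isotopes_present():
        if materials is not None:
            vals = [
                materials[mid].certified[iso]
                for mid in std_ids
                if mid in materials and iso in materials[mid].certified
            ]
        else:
            vals = [
                r.delta_raw[iso] for r in run.records
                if r.role == "standard" and iso in r.delta_raw
            ]
        span = float(np.ptp(vals)) if len(vals) >= 2 else 0.0
        if span < min_span.get(iso, 0.0):
            report.warnings.append(
                f"calibration span {span:.1f}‰ in {iso} below {min_span[iso]:.0f}‰"
            )
    return report


# ---------------------------------------------------------------------------
# Precision and element content
# ---------------------------------------------------------------------------

def qc_precision(results: Iterable[ReducedResult], qc_material: str,
                 min_replicates: int = 3) -> dict:
    """Per-isotope sample SD (n−1) of the calibrated QC analyses.

    Uses the calibrated values before exchange correction for hydrogen
    (``d2H_e``), i.e. the precision of the measurement itself; the
    exchange correction further scales δ2H_ne scatter by 1/(1−x_e).
    Channels with fewer than ``min_replicates`` replicates are reported as
    ``None``.
    """
    sub = [r for r in results if r.material_id == qc_material and r.role == "qc"]
    out = {}
    for iso, attr in (("d2H", "d2H_e"), ("d13C", "d13C"), ("d18O", "d18O")):
        vals = [getattr(r, attr) for r in sub if getattr(r, attr) is not None]
        out[iso] = float(np.std(vals, ddof=1)) if len(vals) >= min_replicates else None
    return out


def element_content(area, mass_mg, ref_area, ref_mass_mg, ref_content_pct):
    """Total element content (%) from peak areas, relative to a reference.

    content% = ref% · (area/mass) / (ref_area/ref_mass).  Used e.g. to
    detect weighing mistakes or sugar loss from leaking capsules.
    """
    if ref_area <= 0 or mass_mg <= 0 or ref_mass_mg <= 0 or area < 0:
        raise InvalidInputError("areas must be ≥ 0 and masses/reference area > 0")
    return float(ref_content_pct * (area / mass_mg) / (ref_area / ref_mass_mg))


# ---------------------------------------------------------------------------
# Reactor comparison and nitrogen bias
# ---------------------------------------------------------------------------

def split_reactor_comparison(table: pd.DataFrame):
    """Split a stored comparison table into per-reactor summary frames
    suitable for :func:`reactor_difference_table`."""
    carbon = pd.DataFrame({
        "material_id": table["material"],
        "d2H_ne": table["d2H_ne_carbon"],
        "x_e": table["x_e_carbon"],
        "n_pct": table["n_pct"],
    })
    chromium = pd.DataFrame({
        "material_id": table["material"],
        "d2H_ne": table["d2H_ne_chromium"],
        "x_e": table["x_e_chromium"],
    })
    return carbon, chromium


def _summary(obj) -> pd.DataFrame:
    """Per-material mean δ2H_ne (and x_e / N% where present)."""
    if isinstance(obj, pd.DataFrame):
        df = obj.copy()
    else:
        df = results_frame(obj).rename(columns={"x_e_used": "x_e"})
    keep = [c for c in ("material_id", "d2H_ne", "x_e", "n_pct") if c in df.columns]
    return df[keep].dropna(subset=["d2H_ne"]).groupby(
        "material_id", sort=False).mean(numeric_only=True)


def reactor_difference_table(carbon, chromium, materials: Optional[dict] = None
                             ) -> pd.DataFrame:
    """Per-material δ2H_ne comparison between the two HTC reactor types.

    ``carbon`` and ``chromium`` are reduced-result collections (or
    per-material frames with ``material_id`` and ``d2H_ne`` columns) from a
    glassy-carbon and a chromium run of the same materials.  The returned
    frame holds, per shared material, both δ2H_ne means, their difference
    ``diff`` = glassy carbon − chromium (unrounded; round to 0.1‰ for
    display), the exchange fractions where available, and N% when a
    registry or input column supplies it.  No shared materials → empty
    frame (the caller should treat this as a warning).
    """
    a, b = _summary(carbon), _summary(chromium)
    rows = []
    for mid in [m for m in a.index if m in b.index]:
        row = {
            "material_id": mid,
            "d2H_ne_carbon": float(a.loc[mid, "d2H_ne"]),
            "d2H_ne_chromium": float(b.loc[mid, "d2H_ne"]),
            "diff": float(a.loc[mid, "d2H_ne"] - b.loc[mid, "d2H_ne"]),
        }
        if "x_e" in a.columns:
            row["x_e_carbon"] = float(a.loc[mid, "x_e"])
        if "x_e" in b.columns:
            row["x_e_chromium"] = float(b.loc[mid, "x_e"])
        if materials is not None and mid in materials:
            row["n_pct"] = materials[mid].n_content_pct
        elif "n_pct" in a.columns:
            row["n_pct"] = float(a.loc[mid, "n_pct"])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    warnings: list = field(default_factory=list)


def nitrogen_bias_regression(table: pd.DataFrame, n_col="n_pct",
                             diff_col="diff") -> RegressionResult:
    """OLS of the between-reactor δ2H_ne difference (‰) on N content (%).

    Unweighted ordinary least squares with intercept; slope in ‰ per %N.
    Two points give a degenerate exact fit (r² reported as 1 with a
    warning); fewer than two raise.
    """
    df = table.dropna(subset=[n_col, diff_col])
    if len(df) < 2:
        raise InvalidInputError("nitrogen-bias regression needs ≥ 2 materials")
    warnings = []
    if len(df) == 2:
        warnings.append("degenerate two-point fit; r² = 1 by construction")
    x = sm.add_constant(df[n_col].to_numpy(dtype=float))
    fit = sm.OLS(df[diff_col].to_numpy(dtype=float), x).fit()
    r2 = 1.0 if len(df) == 2 else float(fit.rsquared)
    return RegressionResult(slope=float(fit.params[1]), intercept=float(fit.params[0]),
                            r_squared=r2, n=len(df), warnings=warnings)


_STORED_N_REGRESSION: Optional[RegressionResult] = None


def stored_nitrogen_regression() -> RegressionResult:
    """Nitrogen-bias regression fitted to the bundled comparison dataset."""
    global _STORED_N_REGRESSION
    if _STORED_N_REGRESSION is None:
        tbl = load_reactor_comparison_table()
        _STORED_N_REGRESSION = nitrogen_bias_regression(tbl)
    return _STORED_N_REGRESSION


def interference_flags(material, run: RunSequence,
                       n_threshold: float = N_CONTENT_THRESHOLD,
                       s_threshold: float = S_CONTENT_THRESHOLD) -> list:
    """Warnings for chemistry that can bias δ2H in a glassy-carbon reactor.

    High-N materials form HCN during pyrolysis, diverting hydrogen from
    H2; the predicted bias is read off the stored nitrogen regression.
    High-S materials may form H2S.  A chromium reactor scavenges all
    reactive elements except hydrogen, so no nitrogen flag applies there.
    """
    flags = []
    if run.reactor != "glassy_carbon":
        return flags
    n_pct = getattr(material, "n_content_pct", 0.0) or 0.0
    s_pct = getattr(material, "s_content_pct", 0.0) or 0.0
    if n_pct > n_threshold:
        reg = stored_nitrogen_regression()
        bias = reg.slope * n_pct + reg.intercept
        flags.append(
            f"N content {n_pct:.2f}% may bias δ2H (predicted ≈ {bias:+.1f}‰); "
            "consider a chromium-reactor cross-check"
        )
    if s_pct > s_threshold:
        flags.append(f"S content {s_pct:.2f}%: possible H2S interference")
    return flags
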