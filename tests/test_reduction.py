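import numpy as np
import pytest
from hypothesis import given, strategies as st

import isoreduce as ir
from isoreduce.core import CalibrationError, InvalidInputError
from isoreduce.reduction import MEMORY_GRID, drift_correction

ZERO = {"d2H": 0.0, "d13C": 0.0, "d18O": 0.0}


class TestMemoryCorrection:
    def test_zero_memory_is_identity(self):
        series = [-100.0, -50.0, -120.0]
        assert np.array_equal(ir.apply_memory_correction(series, 0.0), series)

    def test_constant_series_unchanged(self):
        out = ir.apply_memory_correction([-100.0, -100.0], 0.03)
        assert np.array_equal(out, [-100.0, -100.0])

    def test_difference_form(self):
        out = ir.apply_memory_correction([0.0, -100.0], 0.02)
        assert out == pytest.approx([0.0, -102.0], abs=1e-12)

    def test_empty_series(self):
        assert ir.apply_memory_correction([], 0.02).size == 0

    def test_rejects_out_of_range_fraction(self):
        with pytest.raises(InvalidInputError):
            ir.apply_memory_correction([0.0, 1.0], 0.5)

    def test_not_idempotent(self):
        # the pipeline must apply it exactly once: a second pass moves values
        series = [0.0, -100.0, -20.0]
        once = ir.apply_memory_correction(series, 0.02)
        twice = ir.apply_memory_correction(once, 0.02)
        assert not np.allclose(once, twice)


class TestMemoryFit:
    def test_recovers_true_fraction_noise_free(self, materials, waters):
        cfg = ir.GeneratorConfig(seed=2, noise_sd=dict(ZERO), memory_fraction=0.02)
        run, _ = ir.generate_run(cfg, materials, waters)
        for iso in ("d2H", "d13C", "d18O"):
            assert ir.fit_memory_fraction(run, iso, materials).m == pytest.approx(0.02)

    def test_zero_memory_fits_zero(self, materials, waters):
        cfg = ir.GeneratorConfig(seed=2, noise_sd=dict(ZERO), memory_fraction=0.0)
        run, _ = ir.generate_run(cfg, materials, waters)
        assert ir.fit_memory_fraction(run, "d2H", materials).m == 0.0

    def test_drift_does_not_bias_fit(self, materials, waters):
        cfg = ir.GeneratorConfig(
            seed=2, noise_sd=dict(ZERO), memory_fraction=0.02,
            drift_slope={iso: 0.01 for iso in ZERO},
        )
        run, _ = ir.generate_run(cfg, materials, waters)
        fit = ir.fit_memory_fraction(run, "d2H", materials)
        assert abs(fit.m - 0.02) <= 0.001 + 1e-12  # within one grid step

    def test_insufficient_replicates_returns_zero_with_warning(self, materials):
        recs = [
            ir.AnalysisRecord(position=i, material_id="CEL-LOW", role="standard",
                              delta_raw={"d2H": -150.0})
            for i in (1, 2)
        ]
        run = ir.RunSequence(records=recs)
        fit = ir.fit_memory_fraction(run, "d2H", materials)
        assert fit.m == 0.0 and fit.warnings

    def test_fitted_range_typical_runs(self, materials, waters):
        """At typical noise the fitted memory stays in the 1–3% working range
        on average (individual runs scatter across the grid)."""
        ms = []
        for seed in range(20):
            run, _ = ir.generate_run(ir.GeneratorConfig(seed=seed), materials, waters)
            ms.append(ir.fit_memory_fraction(run, "d2H", materials).m)
        assert 0.01 <= np.mean(ms) <= 0.03
        assert all(m in MEMORY_GRID for m in ms)


class TestDriftCorrection:
    def test_exact_removal_of_linear_trend(self):
        pos = np.arange(1, 51, dtype=float)
        values = -100.0 + 0.01 * (pos - 1)
        corrected, applied = drift_correction(values, pos, slope=0.01)
        assert applied
        residual = np.polyfit(pos, corrected, 1)[0]
        assert abs(residual) < 1e-12

    def test_below_threshold_not_applied(self):
        pos = np.arange(1, 11, dtype=float)
        values = np.full(10, -25.0)
        corrected, applied = drift_correction(values, pos, slope=0.004)
        assert not applied and np.array_equal(corrected, values)

    def test_none_slope_passthrough(self):
        corrected, applied = drift_correction([1.0, 2.0], [1, 2], slope=None)
        assert not applied

    def test_channel_independence(self, materials, waters):
        cfg = ir.GeneratorConfig(seed=3, noise_sd=dict(ZERO),
                                 drift_slope={"d2H": 0.02})
        run, _ = ir.generate_run(cfg, materials, waters)
        out = ir.reduce_run(run, materials, waters)
        assert out.calibration.drift_applied["d2H"]
        assert not out.calibration.drift_applied["d13C"]
        assert not out.calibration.drift_applied["d18O"]


class TestTwoPointCalibration:
    def test_exact_standards_identity(self):
        smap = ir.fit_two_point_calibration([-30.0, -10.0], [-30.0, -10.0])
        assert smap.gain == pytest.approx(1.0) and smap.offset == pytest.approx(0.0)

    def test_reactor_carbon_mixing_inverted(self):
        # measured = 0.85·true + 0.15·(−25): {−10, −30} → {−12.25, −29.25}
        measured = [0.85 * t + 0.15 * -25.0 for t in (-10.0, -30.0)]
        assert measured == pytest.approx([-12.25, -29.25])
        smap = ir.fit_two_point_calibration(measured, [-10.0, -30.0])
        assert smap(-20.75) == pytest.approx(-20.0, abs=1e-9)
        assert 1.0 - 1.0 / smap.gain == pytest.approx(0.15, abs=1e-12)

    def test_failure_modes(self):
        with pytest.raises(CalibrationError):
            ir.fit_two_point_calibration([-20.0], [-20.0])
        with pytest.raises(CalibrationError):
            ir.fit_two_point_calibration([-20.0, -10.0], [-15.0, -15.0])

    @given(
        gain=st.floats(0.7, 1.4),
        offset=st.floats(-20.0, 20.0),
        n_std=st.integers(2, 5),
    )
    def test_affine_distortion_recovered_exactly(self, gain, offset, n_std):
        certified = np.linspace(-30.0, -5.0, n_std)
        measured = (certified - offset) / gain  # instrument applies inverse map
        smap = ir.fit_two_point_calibration(measured, certified)
        assert np.allclose(smap(measured), certified, atol=1e-9)


class TestReduceRun:
    def test_identity_pipeline(self, materials, waters):
        """With every effect off and no equilibration, reduction is the
        identity on raw deltas."""
        cfg = ir.GeneratorConfig(seed=5, noise_sd=dict(ZERO), memory_fraction=0.0,
                                 reactor_carbon_fraction=0.0, water_id=None)
        run, _ = ir.generate_run(cfg, materials, waters)
        out = ir.reduce_run(run, materials, waters)
        for rec, res in zip(run.records, out.results):
            assert res.d13C == pytest.approx(rec.delta_raw["d13C"], abs=1e-9)
            assert res.d18O == pytest.approx(rec.delta_raw["d18O"], abs=1e-9)
            assert res.d2H_ne == pytest.approx(rec.delta_raw["d2H"], abs=1e-9)

    @pytest.mark.parametrize(
        "m_true, drift, f",
        [(0.0, 0.0, 0.0), (0.02, 0.01, 0.15), (0.03, 0.02, 0.2), (0.01, 0.0, 0.1)],
    )
    def test_zero_noise_closure(self, materials, waters, m_true, drift, f):
        """The reduction recovers generator truth exactly at zero noise for
        any combination of memory, drift and reactor-carbon mixing."""
        cfg = ir.GeneratorConfig(
            seed=6, noise_sd=dict(ZERO), memory_fraction=m_true,
            drift_slope={iso: drift for iso in ZERO}, reactor_carbon_fraction=f,
        )
        run, truth = ir.generate_run(cfg, materials, waters)
        out = ir.reduce_run(run, materials, waters)
        t = truth.set_index("position")
        for res in out.results:
            row = t.loc[res.position]
            assert res.d2H_ne == pytest.approx(row.d2H_ne, abs=1e-6)
            assert res.d13C == pytest.approx(row.d13C, abs=1e-6)
            assert res.d18O == pytest.approx(row.d18O, abs=1e-6)
        for iso in ("d2H", "d13C", "d18O"):
            assert abs(out.calibration.memory_fraction[iso] - m_true) <= 0.001 + 1e-12
        if f > 0:
            assert out.calibration.reactor_carbon_fraction == pytest.approx(f, abs=0.005)

    def test_chromium_run_hydrogen_only(self, materials, waters):
        cfg = ir.GeneratorConfig(seed=7, noise_sd=dict(ZERO), reactor="chromium")
        run, truth = ir.generate_run(cfg, materials, waters)
        out = ir.reduce_run(run, materials, waters)
        t = truth.set_index("position")
        for res in out.results:
            assert res.d13C is None and res.d18O is None
            assert res.d2H_ne == pytest.approx(t.loc[res.position].d2H_ne, abs=1e-6)
        assert out.calibration.reactor_carbon_fraction is None

    def test_missing_calibration_channel_skipped(self, waters):
        mats = ir.default_materials()
        for m in mats.values():
            m.certified.pop("d18O", None)
        cfg = ir.GeneratorConfig(seed=8, noise_sd=dict(ZERO))
        run, _ = ir.generate_run(cfg)  # generated from full registry
        out = ir.reduce_run(run, mats, waters)
        assert any("d18O" in w for w in out.warnings)
        assert all(res.d18O is None for res in out.results)
        assert all(res.d13C is not None for res in out.results)

    def test_unknown_standard_material_is_an_error(self, materials, waters):
        run, _ = ir.generate_run(ir.GeneratorConfig(seed=9), materials, waters)
        mats = {k: v for k, v in materials.items() if k != "CEL-LOW"}
        with pytest.raises(InvalidInputError, match="CEL-LOW"):
            ir.reduce_run(run, mats, waters)

    def test_presteady_state_exclusion(self, materials, waters):
        loss = ir.EquilibrationLoss(0.13, 0.07, 120.0)
        cfg = ir.GeneratorConfig(seed=10, noise_sd=dict(ZERO),
                                 autosampler="argon_hood", equilibration_loss=loss)
        run, _ = ir.generate_run(cfg, materials, waters)
        out = ir.reduce_run(run, materials, waters)
        flagged = {r.position for r in out.results if "pre-steady-state" in r.flags}
        # cellulose-class analyses within the first 120 min only
        expected = {
            rec.position for rec in run.records
            if rec.time_min < 120
            and materials.get(rec.material_id, None) is not None
            and materials[rec.material_id].material_class == "cellulose"
        }
        assert flagged == expected and flagged

    def test_zero_blank_autosampler_never_flagged(self, materials, waters):
        run, _ = ir.generate_run(ir.GeneratorConfig(seed=10), materials, waters)
        out = ir.reduce_run(run, materials, waters)
        assert all("pre-steady-state" not in r.flags for r in out.results)

    def test_xe_override(self, materials, waters):
        cfg = ir.GeneratorConfig(seed=12, noise_sd=dict(ZERO))
        run, _ = ir.generate_run(cfg, materials, waters)
        out = ir.reduce_run(run, materials, waters,
                            ir.ReduceOptions(x_e={"SAMPLE-001": 0.1}))
        by_id = {r.material_id: r for r in out.results if r.role == "sample"}
        assert by_id["SAMPLE-001"].x_e_used == 0.1
        assert by_id["SAMPLE-002"].x_e_used == 0.2
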