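import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from goldpath.assays import (
    AssayError,
    OutOfRangeError,
    ParticleGeometry,
    StandardCurve5PL,
    dose_convert,
    endotoxin_classify,
    endotoxin_threshold,
    fit_5pl,
    invert_5pl,
    log2_dose,
    spike_recovery_interference,
    surface_to_volume,
    viability_percent,
)


class TestViability:
    def test_hand_arithmetic(self, wst_plate):
        # (0.8 - 0.2) / (1.2 - 0.2) = 0.6
        assert viability_percent(wst_plate, "X") == pytest.approx(60.0)

    def test_identical_to_control_is_100(self, wst_plate):
        p = wst_plate.copy()
        p.loc[p["role"] == "cells_treatment", "A440"] = 1.2
        assert viability_percent(p, "X") == pytest.approx(100.0)

    def test_zero_numerator_is_0(self, wst_plate):
        p = wst_plate.copy()
        p.loc[p["role"] == "cells_treatment", "A440"] = 0.2
        assert viability_percent(p, "X") == pytest.approx(0.0)

    def test_nonpositive_denominator_errors(self, wst_plate):
        p = wst_plate.copy()
        p.loc[p["role"] == "cells_control", "A440"] = 0.1
        with pytest.raises(AssayError):
            viability_percent(p, "X")

    @given(gain=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_gain_invariance(self, gain):
        """Viability is unchanged when every absorbance is scaled by a
        common positive detector gain."""
        rows = [("cells_treatment", "X", 0.9, 0.1),
                ("medium_treatment", "X", 0.25, 0.05),
                ("cells_control", "", 1.3, 0.1),
                ("medium_control", "", 0.25, 0.05)]
        p = pd.DataFrame(rows, columns=["role", "treatment", "A440", "A620"])
        v0 = viability_percent(p, "X")
        p2 = p.copy()
        p2[["A440", "A620"]] *= gain
        assert viability_percent(p2, "X") == pytest.approx(v0, rel=1e-9)


class TestElisa5PL:
    TRUE = StandardCurve5PL(lower=0.05, upper=2.4, c50=120.0, slope=-1.3,
                            asymmetry=1.6)

    def _standards(self):
        conc = np.concatenate([[0.0], 500.0 / 2.0 ** np.arange(8)])
        return conc, np.asarray(self.TRUE.eval(conc), float)

    def test_noiseless_recovery_within_1pct(self):
        conc, od = self._standards()
        fit = fit_5pl(conc, od)
        assert fit.lower == pytest.approx(self.TRUE.lower, rel=0.01, abs=1e-3)
        assert fit.upper == pytest.approx(self.TRUE.upper, rel=0.01)
        assert fit.c50 == pytest.approx(self.TRUE.c50, rel=0.01)
        assert fit.slope == pytest.approx(self.TRUE.slope, rel=0.01)
        assert fit.asymmetry == pytest.approx(self.TRUE.asymmetry, rel=0.01)

    def test_blank_maps_to_lower_asymptote(self):
        assert self.TRUE.eval(0.0) == pytest.approx(self.TRUE.lower)
        with pytest.raises(OutOfRangeError):
            self.TRUE.invert(self.TRUE.lower)  # blank OD: below range

    def test_inflection_midpoint_of_asymmetric_logistic(self):
        c = self.TRUE
        expected = c.lower + (c.upper - c.lower) / 2.0 ** c.asymmetry
        assert c.eval(c.c50) == pytest.approx(expected, rel=1e-12)

    def test_invert_eval_roundtrip_1e8(self):
        for x in np.geomspace(2.0, 490.0, 40):
            od = float(self.TRUE.eval(x))
            assert abs(self.TRUE.invert(od) - x) / x < 1e-8

    def test_dilution_factor_scales_result(self):
        od = float(self.TRUE.eval(50.0))
        assert invert_5pl(self.TRUE, od, dilution_factor=20) == pytest.approx(
            1000.0, rel=1e-8)

    def test_out_of_range_flagged_not_clipped(self):
        with pytest.raises(OutOfRangeError):
            self.TRUE.invert(self.TRUE.upper + 0.1)

    def test_too_few_standards(self):
        with pytest.raises(AssayError):
            fit_5pl([0, 10, 20, 40], [0.1, 0.5, 0.9, 1.4])

    def test_nonmonotone_standards_flagged(self):
        conc, od = self._standards()
        od = od.copy()
        od[3], od[4] = od[4], od[3]
        assert not fit_5pl(conc, od).monotone_standards


class TestEndotoxin:
    def test_threshold_at_100ug(self):
        assert endotoxin_threshold(100.0, 0.5) == pytest.approx(0.05)

    @pytest.mark.parametrize("eu, interference, expected", [
        (0.030, False, "A"),
        (0.070, False, "B"),
        (1.667, True, "C"),
    ])
    def test_reference_classifications(self, eu, interference, expected):
        assert endotoxin_classify(eu, 100.0, 0.5, interference) == expected

    @given(eu=st.floats(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_interference_always_c(self, eu):
        assert endotoxin_classify(eu, 100.0, 0.5, True) == "C"

    def test_negative_input_rejected(self):
        with pytest.raises(AssayError):
            endotoxin_classify(-0.1, 100.0)

    def test_spike_recovery_window(self):
        assert not spike_recovery_interference(0.02, 0.50, 0.5)   # 96%
        assert spike_recovery_interference(0.02, 0.10, 0.5)       # 16%


class TestDoseMetrics:
    ROD = ParticleGeometry("rod", radius_nm=7.0, length_nm=60.0,
                           mass_per_nM=1.324)
    SPHERE = ParticleGeometry("sphere", radius_nm=15.0)

    def test_nM_to_mass(self):
        assert dose_convert(25.0, self.ROD) == pytest.approx(33.1, abs=0.05)
        assert dose_convert(1.0, self.ROD) == pytest.approx(1.324)

    def test_log2_axis(self):
        assert log2_dose(28.6) == pytest.approx(4.84, abs=0.005)
        with pytest.raises(ValueError):
            log2_dose(0.0)

    def test_surface_to_volume_reference_values(self):
        rod = surface_to_volume(self.ROD)
        sph = surface_to_volume(self.SPHERE)
        assert rod == pytest.approx(0.32, abs=0.005)
        assert sph == pytest.approx(0.2, abs=1e-12)
        assert rod / sph == pytest.approx(1.6, abs=0.05)

    def test_surface_to_volume_monotone(self):
        rs = np.linspace(5, 50, 10)
        sv = [surface_to_volume(ParticleGeometry("sphere", r)) for r in rs]
        assert all(a > b for a, b in zip(sv, sv[1:]))
        sv_r = [surface_to_volume(ParticleGeometry("rod", r, 60.0)) for r in rs]
        assert all(a > b for a, b in zip(sv_r, sv_r[1:]))
        sv_h = [surface_to_volume(ParticleGeometry("rod", 7.0, h))
                for h in np.linspace(20, 100, 10)]
        assert all(a > b for a, b in zip(sv_h, sv_h[1:]))

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            ParticleGeometry("rod", radius_nm=7.0)  # no length
        with pytest.raises(ValueError):
            ParticleGeometry("sphere", radius_nm=0.0)
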