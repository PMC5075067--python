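"""fT>MIC computation and Monte Carlo probability of target attainment."""

import numpy as np
import pandas as pd
import pytest

from meropk import (CSF_50, CSF_100, PLASMA_40, DosingRegimen, PKPDTarget,
                    ValidationError, ft_above_mic, pkpd_breakpoint, pta,
                    pta_grid)
from meropk.pk_core import ConcentrationProfile
from meropk.pkpd import cohort_concentrations, pta_from_concentrations
from meropk.population import sample_individuals


def constant_profile(conc: float, n: int = 1000, tau: float = 8.0,
                     matrix: str = "plasma") -> ConcentrationProfile:
    times = np.linspace(0, tau, n, endpoint=False)
    vals = np.full(n, conc)
    zeros = np.zeros(n)
    plasma, csf = (vals, zeros) if matrix == "plasma" else (zeros, vals)
    return ConcentrationProfile(times, plasma, csf,
                                np.zeros((n, 3)))


class TestFtAboveMic:
    def test_constant_concentration_above_and_below(self):
        prof = constant_profile(10.0)
        # free plasma 9.8 > 8 for the whole interval
        assert ft_above_mic(prof, 8.0, PLASMA_40) == 1.0
        assert ft_above_mic(prof, 12.0, PLASMA_40) == 0.0

    def test_protein_binding_correction_is_applied(self):
        prof = constant_profile(10.0)
        # total 10 > 9.9 but free 9.8 < 9.9
        assert ft_above_mic(prof, 9.9, PLASMA_40) == 0.0
        assert ft_above_mic(prof, 9.9,
                            PKPDTarget("plasma", 0.4, 1.0)) == 1.0

    def test_monoexponential_crossing_time(self):
        """C(t) = 16 * 2^-t crosses MIC 1 at t = 4 h, i.e. fT>MIC = 0.5."""
        times = np.linspace(0, 8, 1000, endpoint=False)
        conc = 16.0 * 2.0 ** (-times)
        prof = ConcentrationProfile(times, conc, np.zeros_like(conc),
                                    np.zeros((1000, 3)))
        target = PKPDTarget("plasma", 0.5, 1.0)
        assert ft_above_mic(prof, 1.0, target) == pytest.approx(0.5, abs=1e-3)

    def test_invalid_mic_rejected(self):
        with pytest.raises(ValidationError):
            ft_above_mic(constant_profile(10.0), 0.0, PLASMA_40)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValidationError):
            PKPDTarget("serum", 0.4, 1.0)
        with pytest.raises(ValidationError):
            PKPDTarget("plasma", 1.5, 1.0)
        with pytest.raises(ValidationError):
            PKPDTarget("plasma", 0.4, 0.0)


@pytest.fixture(scope="module")
def cohort(pop_spec):
    return sample_individuals(pop_spec, 300, seed=5)


@pytest.fixture(scope="module")
def conc_2g_q8h_4h_d50(cohort):
    return cohort_concentrations(cohort, DosingRegimen(2000, 8, 4),
                                 drainage_ml_day=50)


class TestPTA:
    def test_tiny_mic_gives_full_attainment(self, conc_2g_q8h_4h_d50):
        plasma, csf = conc_2g_q8h_4h_d50
        for target in (PLASMA_40, CSF_50, CSF_100):
            out = pta_from_concentrations(plasma, csf, target, [1e-6])
            assert out["pta"].iloc[0] == 1.0

    def test_pta_non_increasing_in_mic(self, conc_2g_q8h_4h_d50):
        plasma, csf = conc_2g_q8h_4h_d50
        for target in (PLASMA_40, CSF_50, CSF_100):
            out = pta_from_concentrations(plasma, csf, target,
                                          [0.125, 0.5, 1, 4, 16])
            assert np.all(np.diff(out["pta"]) <= 0)

    def test_100pct_target_never_exceeds_50pct_target(self, conc_2g_q8h_4h_d50):
        plasma, csf = conc_2g_q8h_4h_d50
        mics = [0.125, 0.25, 0.5, 1, 2]
        p50 = pta_from_concentrations(plasma, csf, CSF_50, mics)["pta"]
        p100 = pta_from_concentrations(plasma, csf, CSF_100, mics)["pta"]
        assert np.all(p100 <= p50)

    def test_csf_pta_non_increasing_in_drainage(self, cohort):
        """More daily CSF drainage means lower CSF target attainment."""
        reg = DosingRegimen(2000, 8, 4)
        vals = []
        for drain in (0, 50, 150, 250):
            plasma, csf = cohort_concentrations(cohort, reg, drain)
            vals.append(pta_from_concentrations(plasma, csf, CSF_50,
                                                [1.0])["pta"].iloc[0])
        assert np.all(np.diff(vals) <= 0)
        assert vals[0] > vals[-1]  # strictly lower at the extreme

    def test_plasma_pta_invariant_to_drainage(self, cohort):
        reg = DosingRegimen(2000, 8, 4)
        vals = []
        for drain in (0, 50, 150, 250):
            plasma, csf = cohort_concentrations(cohort, reg, drain)
            vals.append(pta_from_concentrations(plasma, csf, PLASMA_40,
                                                [2, 8, 16])["pta"].to_numpy())
        spread = np.ptp(np.stack(vals), axis=0)
        assert np.all(spread <= 0.01)

    def test_pta_non_decreasing_in_finite_infusion_duration(self, cohort):
        """Prolonging a finite infusion never lowers PTA (shared cohort)."""
        for target, mic in ((PLASMA_40, 8.0), (CSF_50, 0.5)):
            vals = []
            for inf in (0.5, 1, 2, 3, 4):
                plasma, csf = cohort_concentrations(
                    cohort, DosingRegimen(2000, 8, inf), 50)
                vals.append(pta_from_concentrations(plasma, csf, target,
                                                    [mic])["pta"].iloc[0])
            assert np.all(np.diff(vals) >= 0)

    def test_continuous_infusion_highest_for_csf_targets(self, cohort):
        """CSF kinetics are slow, so removing infusion peaks costs nothing
        there and continuous infusion attains the most."""
        vals = []
        for inf in (0.5, 2, 4, 8):
            plasma, csf = cohort_concentrations(
                cohort, DosingRegimen(2000, 8, inf), 50)
            vals.append(pta_from_concentrations(plasma, csf, CSF_100,
                                                [0.5])["pta"].iloc[0])
        assert vals[-1] == max(vals)

    def test_replicate_runs_within_binomial_noise(self, pop_spec):
        out1 = pta(pop_spec, DosingRegimen(2000, 8, 4), CSF_50,
                   mics=[0.25, 0.5, 1, 2], n=1000, seed=101,
                   drainage_ml_day=50)
        out2 = pta(pop_spec, DosingRegimen(2000, 8, 4), CSF_50,
                   mics=[0.25, 0.5, 1, 2], n=1000, seed=202,
                   drainage_ml_day=50)
        assert np.all(np.abs(out1["pta"] - out2["pta"]) < 0.04)

    def test_empty_mic_list_rejected(self, conc_2g_q8h_4h_d50):
        plasma, csf = conc_2g_q8h_4h_d50
        with pytest.raises(ValidationError):
            pta_from_concentrations(plasma, csf, CSF_50, [])


class TestBreakpoint:
    def _grid(self, ptas):
        return pd.DataFrame({
            "regimen": "2g q8h", "infusion": "4", "infusion_h": 4.0,
            "drainage_ml_day": 50.0, "matrix": "csf", "target_fraction": 0.5,
            "mic_mg_l": [0.25, 0.5, 1.0, 2.0], "pta": ptas,
        })

    def test_full_attainment_returns_largest_mic(self):
        bp = pkpd_breakpoint(self._grid([1.0, 1.0, 1.0, 1.0]), 0.9)
        assert bp["breakpoint_mic_mg_l"].iloc[0] == 2.0

    def test_no_attainment_returns_nan(self):
        bp = pkpd_breakpoint(self._grid([0.1, 0.0, 0.0, 0.0]), 0.9)
        assert np.isnan(bp["breakpoint_mic_mg_l"].iloc[0])

    def test_threshold_crossing(self):
        bp = pkpd_breakpoint(self._grid([0.99, 0.95, 0.40, 0.1]), 0.9)
        assert bp["breakpoint_mic_mg_l"].iloc[0] == 0.5

    def test_grid_runs_full_factorial(self, pop_spec):
        grid = pta_grid(pop_spec, infusion_hours=(4, "CI"),
                        drainage_ml_day=(0, 150), mics=(0.5, 8.0),
                        n=20, seed=1)
        # 3 regimens x 2 infusions x 2 drainages x 3 targets x 2 MICs
        assert len(grid) == 3 * 2 * 2 * 3 * 2
        assert set(grid["infusion"]) == {"4", "CI"}
        bp = pkpd_breakpoint(grid, 0.9)
        assert len(bp) == 3 * 2 * 2 * 3
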