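import numpy as np
import pytest

from meropk import DosingRegimen, PKParameters, PopulationSpec


@pytest.fixture(scope="session")
def typical() -> PKParameters:
    """Published typical parameter values, no drainage."""
    return PKParameters()


@pytest.fixture(scope="session")
def pop_spec() -> PopulationSpec:
    """Published population: typical values + BSV + residual error."""
    return PopulationSpec()


@pytest.fixture(scope="session")
def noise_free_spec() -> PopulationSpec:
    """Population with no between-subject variability and no residual error."""
    return PopulationSpec(bsv_cv_pct={}, residual_cv_pct=0.0)


@pytest.fixture(scope="session")
def regimen_2g_q8h_4h() -> DosingRegimen:
    return DosingRegimen(dose_mg=2000, interval_h=8, infusion_h=4)


def random_parameters(rng: np.random.Generator) -> PKParameters:
    """A random valid parameter set, log-normally spread around the typical
    values (shared helper for oracle-equivalence and property tests)."""
    typ = PKParameters()
    scale = np.exp(rng.normal(0.0, 0.4, size=8))
    return PKParameters(
        v1_l=typ.v1_l * scale[0],
        v2_l=typ.v2_l * scale[1],
        v3_l=typ.v3_l * scale[2],
        cl1_l_per_h=typ.cl1_l_per_h * scale[3],
        q1_l_per_h=typ.q1_l_per_h * scale[4],
        q2_l_per_h=typ.q2_l_per_h * scale[5],
        pc=typ.pc * scale[6],
        drainage_l_per_day=float(rng.uniform(0.0, 0.35)),
    )
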