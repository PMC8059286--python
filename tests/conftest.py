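import numpy as np
import pandas as pd
import pytest

from iolopt import (DEFAULT_PARAMS, EyeBiometry, GeneratorConfig,
                    LensConstants, generate_cohort)

#: Three reference eyes spanning short, average and long geometry.
REFERENCE_EYES = (
    {"al_mm": 21.5, "km_d": 46.0, "acd_mm": 2.8, "iol_power_d": 28.0},
    {"al_mm": 23.65, "km_d": 43.5, "acd_mm": 3.2, "iol_power_d": 21.0},
    {"al_mm": 26.5, "km_d": 41.5, "acd_mm": 3.6, "iol_power_d": 14.0},
)

DEFAULT_CONSTANTS = {
    "srkt": LensConstants.srkt(119.0),
    "holladay1": LensConstants.holladay1(1.84),
    "hofferq": LensConstants.hofferq(5.64),
    "haigis": LensConstants.haigis(1.90),
}


@pytest.fixture(scope="session")
def reference_eyes():
    return [EyeBiometry(al_mm=e["al_mm"], acd_mm=e["acd_mm"], km_d=e["km_d"])
            for e in REFERENCE_EYES]


@pytest.fixture(scope="session")
def default_constants():
    return dict(DEFAULT_CONSTANTS)


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


def random_eye_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Valid biometry frame spanning realistic ranges, for property tests."""
    return pd.DataFrame({
        "al_mm": rng.uniform(20.5, 28.5, n),
        "acd_mm": rng.uniform(2.4, 4.2, n),
        "km_d": rng.uniform(39.5, 48.0, n),
        "ad_mm": rng.uniform(1.9, 3.7, n),
    })


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient default-config synthetic cohort (seeded)."""
    cfg = GeneratorConfig(n_patients=400, seed=11)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def unilateral_cohort_factory():
    """Factory for fixed-size single-eye cohorts with chosen world/offsets."""

    def make(n_eyes: int, seed: int, world_formula: str = "srkt",
             true_constant: float = 119.0, noise_sd: float = 0.4,
             offset_f: float = 0.0, offset_m: float = 0.0,
             prop_female: float = 0.5, **kwargs):
        cfg = GeneratorConfig(
            n_patients=n_eyes, prob_bilateral=0.0, prop_female=prop_female,
            world_formula=world_formula,
            true_constants={"female": true_constant, "male": true_constant},
            gender_offset_d={"female": offset_f, "male": offset_m},
            noise_sd_d=noise_sd, seed=seed, **kwargs)
        cohort, truth = generate_cohort(cfg)
        return cohort, cfg

    return make
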