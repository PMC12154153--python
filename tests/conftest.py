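import numpy as np
import pytest

from gaitprop.synth import CohortEffects, GaitParams, generate_cohort, generate_trial

# Generative fixed effects matching the magnitude of post-stroke propulsion
# deficits: paretic limb ~19 N below / non-paretic ~13 N above the predicted
# value at the mean speed, with a markedly shallower paretic speed slope.
AGRF_EFFECTS = CohortEffects(
    intercept=100.0,
    slope=126.6,
    offset_paretic=-19.4,
    offset_nonparetic=12.8,
    slope_offset_paretic=-40.2,
    slope_offset_nonparetic=-7.2,
)
AGRF_TRUTH = np.array([100.0, 126.6, -19.4, 12.8, -40.2, -7.2])
AGRF_SD_INTERCEPT = 25.0
AGRF_SD_RESID = 15.0


@pytest.fixture(scope="session")
def noiseless_params() -> GaitParams:
    return GaitParams(
        step_length_paretic=0.55,
        step_length_nonparetic=0.45,
        agrf_peak_paretic=80.0,
        agrf_peak_nonparetic=90.0,
        noise_sd_marker=0.0,
        noise_sd_force=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_params):
    return generate_trial(noiseless_params, 150.0)


@pytest.fixture(scope="session")
def agrf_cohort():
    """One simulated limb-level cohort at study-like size (30 participants)."""
    df = generate_cohort(30, AGRF_EFFECTS, AGRF_SD_INTERCEPT, AGRF_SD_RESID, seed=42)
    df["centered_speed"] = df["speed"] - df["speed"].mean()
    return df


def centered(df):
    df = df.copy()
    df["centered_speed"] = df["speed"] - df["speed"].mean()
    return df
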