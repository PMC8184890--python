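import numpy as np
import pandas as pd
import pytest

from prsurv import synthpop, survkit


@pytest.fixture(scope="session")
def small_panel():
    blocks = [synthpop.BlockSpec(10, (0.2, 0.4), 0.8),
              synthpop.BlockSpec(10, (0.2, 0.4), 0.8)]
    return synthpop.simulate_haplotypes(2000, blocks, seed=5)


@pytest.fixture(scope="session")
def trial_patients():
    arms = [synthpop.ArmSpec("a1", 250, True), synthpop.ArmSpec("a2", 250, True),
            synthpop.ArmSpec("c1", 150, False), synthpop.ArmSpec("c2", 150, False)]
    return synthpop.simulate_trial_cohort(
        800, arms, prs_log_hr=float(np.log(1.52)),
        covariate_effects=synthpop.CovariateEffects(
            gender_log_hr=0.3, tsh_log_hr=0.35,
            irae_os_log_hr=float(np.log(0.57))),
        seed=7)


@pytest.fixture(scope="session")
def trial_frame(trial_patients):
    return survkit.patients_to_frame(trial_patients)


def exponential_survival_frame(n, log_hr, seed, hazard=0.002,
                               censor=(300.0, 1500.0), x=None):
    """Simple right-censored cohort with a single covariate effect."""
    rng = np.random.default_rng(seed)
    if x is None:
        x = rng.normal(size=n)
    t = rng.exponential(1.0 / (hazard * np.exp(log_hr * x)))
    c = rng.uniform(*censor, size=n)
    return pd.DataFrame({
        "tstart": 0.0,
        "tstop": np.minimum(t, c),
        "status": (t <= c).astype(int),
        "x": x,
    })
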