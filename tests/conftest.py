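import numpy as np
import pandas as pd
import pytest

import hrphase as hp


def make_truth_cohort(cfg: hp.SimConfig):
    """Generate tables and an analysis cohort carrying the TRUE phase.

    Used by statistical-recovery tests that do not exercise the
    phase-extraction stage (generate_hr=False keeps them fast).
    """
    tables = hp.generate_cohort(cfg)
    cohort = tables.covariates.copy()
    cohort["phi"] = tables.truth["phase"].to_numpy()
    return tables, cohort


def sine_profile(phi_hours: float, amplitude: float = 10.0,
                 baseline: float = 70.0, noise_sd: float = 0.0,
                 rng: np.random.Generator | None = None,
                 bins: np.ndarray | None = None) -> pd.DataFrame:
    """Weekly profile sampled from the sine model on the 5-min grid."""
    if bins is None:
        bins = np.arange(0, 7 * 1440, 5)
    y = amplitude * np.sin(np.pi / 720.0 * (np.mod(bins, 1440) - 60.0 * phi_hours)) + baseline
    if noise_sd > 0:
        assert rng is not None
        y = y + rng.normal(0, noise_sd, bins.size)
    return pd.DataFrame({"bin_start": bins, "mean_hr": y,
                         "n_samples": np.ones(bins.size, dtype=int)})


@pytest.fixture(scope="session")
def small_tables():
    """A compact cohort with raw HR streams, shared across IO/pipeline tests."""
    cfg = hp.SimConfig(n_participants=40, n_days=40, seed=11)
    return hp.generate_cohort(cfg)
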