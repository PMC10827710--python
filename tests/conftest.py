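import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wmbias import DoGParams, SimConfig, simulate_trials

# property tests must be reproducible run-to-run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def plain_cohort() -> pd.DataFrame:
    """Small biased cohort without item attributes (a=2, w=0.03, κ=4)."""
    cfg = SimConfig(
        n_observers=10,
        trials_per_observer=60,
        kappa_by_position=(4.0, 4.0, 4.0, 4.0),
        bias_params={"default": DoGParams(a=2.0, w=0.03)},
        p_guess=0.1,
        seed=42,
    )
    return simulate_trials(cfg)


@pytest.fixture(scope="session")
def noise_cohort() -> pd.DataFrame:
    """Cohort with two stimulus-noise levels and confidence ratings."""
    cfg = SimConfig(
        n_observers=12,
        trials_per_observer=80,
        conditions="noise2level",
        bias_params={
            "default": DoGParams(a=2.0, w=0.03),
            "high": DoGParams(a=2.0, w=0.03),
            "low": DoGParams(a=2.0, w=0.03),
        },
        seed=7,
    )
    return simulate_trials(cfg)


@pytest.fixture()
def hand_trial() -> pd.DataFrame:
    """One fully specified trial for hand-checked expansions.

    Target at position 2 (orientation 10°), distractors 170°, 40°, 90°;
    the response reproduces the target exactly.
    """
    return pd.DataFrame(
        {
            "observer_id": ["obsA"],
            "experiment_id": ["hand"],
            "trial_index": [0],
            "ori_1": [170.0],
            "ori_2": [10.0],
            "ori_3": [40.0],
            "ori_4": [90.0],
            "noise_1": ["none"], "noise_2": ["none"],
            "noise_3": ["none"], "noise_4": ["none"],
            "colour_1": ["none"], "colour_2": ["none"],
            "colour_3": ["none"], "colour_4": ["none"],
            "precue_colour": ["none"],
            "target_position": [2],
            "response": [10.0],
            "confidence": pd.array([pd.NA], dtype="Int64"),
            "attention_pass": [True],
        }
    )


def make_trials(orientations, target_positions, responses, observer_id="obs1"):
    """Minimal canonical trial table from raw arrays (helper for unit tests)."""
    orientations = np.asarray(orientations, dtype=float)
    n = len(orientations)
    df = pd.DataFrame(
        {
            "observer_id": observer_id,
            "experiment_id": "unit",
            "trial_index": np.arange(n),
            **{f"ori_{k+1}": orientations[:, k] for k in range(4)},
            **{f"noise_{k+1}": "none" for k in range(4)},
            **{f"colour_{k+1}": "none" for k in range(4)},
            "precue_colour": "none",
            "target_position": np.asarray(target_positions, dtype=int),
            "response": np.asarray(responses, dtype=float),
            "confidence": pd.array([pd.NA] * n, dtype="Int64"),
            "attention_pass": True,
        }
    )
    return df
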