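import numpy as np
import pandas as pd
import pytest

import choicerep as cr


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-participant cohort at reduced triplet counts (both sessions,
    all three stimulation conditions), shared across analysis tests."""
    return cr.simulate_cohort(
        8,
        cr.DesignConfig(n_measurement_trials=150, n_triplets_per_block=20),
        rng_seed=3,
    )


@pytest.fixture(scope="session")
def small_report(small_cohort):
    return cr.preregistered_report(small_cohort.records)


def make_toy_targets(bias_types, choices, dts=None, participant_id=1):
    """Assemble a filtered-target frame by hand for analysis unit tests."""
    n = len(bias_types)
    dts = dts if dts is not None else [800.0] * n
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "session": 1,
            "block": 2,
            "stim": "sham",
            "sham_order": "sham_first",
            "trial_index": np.arange(n),
            "triplet_id": np.arange(n),
            "role": "target",
            "sn_value": 40,
            "lf_value": 80,
            "sn_distance": 2,
            "extra_distance": 4,
            "iti_before_ms": 500,
            "choice": choices,
            "dt_ms": dts,
            "timed_out": False,
            "bias_type": bias_types,
            "bias_choice": bias_types,
            "bias_success": True,
            "repeat": [c == b for c, b in zip(choices, bias_types)],
        }
    )


def make_toy_triplets(bias2_choices, bias_type="SN", participant_id=1):
    """Raw-log triplets with chosen bias-2 outcomes, for the success filter."""
    rows = []
    role = f"bias_{bias_type}"
    for t, b2 in enumerate(bias2_choices):
        for j, (r, ch) in enumerate(
            [(role, bias_type), (role, b2), ("target", "LF")]
        ):
            rows.append(
                {
                    "participant_id": participant_id,
                    "session": 1,
                    "block": 2,
                    "stim": "sham",
                    "sham_order": "sham_first",
                    "trial_index": 3 * t + j,
                    "triplet_id": t,
                    "role": r,
                    "sn_value": 40,
                    "lf_value": 80,
                    "sn_distance": 2,
                    "extra_distance": 4,
                    "iti_before_ms": None if (t == 0 and j == 0) else 500,
                    "choice": ch,
                    "dt_ms": 700.0,
                    "timed_out": False,
                }
            )
    return pd.DataFrame(rows)
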