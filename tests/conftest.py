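import numpy as np
import pandas as pd
import pytest

from avspan.ordinal import bin_per_digit
from avspan.simulate import SimulationConfig, score_study, simulate_study


@pytest.fixture(scope="session")
def default_bundle():
    """One full-scale synthetic study (41 participants x 120 trials)."""
    return simulate_study(SimulationConfig(seed=2024))


@pytest.fixture(scope="session")
def scored_default(default_bundle):
    return score_study(default_bundle, derive_clusters=False)


@pytest.fixture(scope="session")
def small_model_data():
    """Scaled-down scored dataset in modeling column layout."""
    bundle = simulate_study(SimulationConfig(seed=99, n_participants=12, n_sequences=8))
    scored = score_study(bundle, derive_clusters=False)
    d = scored.rename(
        columns={
            "participant": "Participant",
            "order": "Order",
            "condition": "Condition",
            "sequence_id": "Sequence",
        }
    )
    d["PerDigitBin"] = bin_per_digit(d["per_digit"])
    d["audio"] = d["Condition"].isin(["C_3-AudSupp", "C_4-AVRhythmSupp"]).astype(float)
    d["rhythm"] = d["Condition"].isin(["C_2-VisRhythmSupp", "C_4-AVRhythmSupp"]).astype(float)
    return d


def simulate_po_data(rng, n, beta, k=5, group_sd=0.0, n_groups=1):
    """Draw proportional-odds data with known coefficients (test oracle).

    Latent logistic variable + equally spaced thresholds; optional group
    intercepts for mixed-model recovery checks.
    """
    x = rng.normal(size=(n, len(beta)))
    eta = x @ np.asarray(beta)
    groups = rng.integers(0, n_groups, size=n)
    if group_sd > 0:
        b = rng.normal(0, group_sd, size=n_groups)
        eta = eta + b[groups]
    theta = np.linspace(-1.5, 1.5, k - 1)
    u = rng.logistic(size=n)
    y = np.sum(u + eta > theta[:, None], axis=0)
    df = pd.DataFrame(x, columns=[f"x{i}" for i in range(len(beta))])
    df["y"] = y
    df["Participant"] = groups
    return df
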