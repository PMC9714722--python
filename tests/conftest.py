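import numpy as np
import pandas as pd
import pytest

import persuasion_rl as pr

#: planted best action per state, distinct across states (cyclic)
PLANTED_BEST = np.arange(8) % 5


@pytest.fixture(scope="session")
def planted_truth():
    """Ground truth with a unique best action (margin 2 effort points,
    noise SD 1) planted in every state."""
    return pr.GroundTruth.planted(PLANTED_BEST, base=4.0, margin=2.0,
                                  rng=0, noise_sd=1.0)


@pytest.fixture(scope="session")
def planted_cohort(planted_truth):
    """~10,000 transitions from the planted ground truth (2,500 people,
    5 sessions each -> 4 transitions per person)."""
    config = pr.CohortConfig(n_people=2500, n_sessions=5, seed=11)
    records, traits = pr.generate_cohort(config, planted_truth)
    return records, traits


@pytest.fixture(scope="session")
def planted_samples(planted_cohort):
    records, _ = planted_cohort
    samples, prep = pr.prepare_training_frame(records, level=2)
    return samples, prep


def latent_policy_under(prep, truth, best=PLANTED_BEST):
    """Re-express a planted per-latent-state policy in the encoded state
    indexing induced by the preprocessor's (possibly permuted) feature
    choice. Valid when the chosen features equal the truth's signal
    features as a set."""
    assert set(prep.chosen) == set(truth.signal_features)
    expected = np.empty(8, dtype=int)
    for s in range(8):
        bits_chosen = pr.decode_state(s)[0]
        bit_of_feature = dict(zip(prep.chosen, bits_chosen))
        latent_bits = [bit_of_feature[f] for f in truth.signal_features]
        latent = int(pr.encode_state(latent_bits)[0])
        expected[s] = best[latent]
    return expected


@pytest.fixture(scope="session")
def random_mdp_batch():
    """100 random dense 8-state/5-action model estimates."""
    rng = np.random.default_rng(7)
    models = []
    for _ in range(100):
        reward = rng.uniform(-1, 1, size=(8, 5, 8))
        transition = rng.dirichlet(np.ones(8), size=(8, 5))
        support = np.ones((8, 5, 8))
        models.append(pr.ModelEstimate(reward=reward, transition=transition,
                                       support=support))
    return models


def make_transition_frame(states, actions, rewards, next_states, **extra):
    df = pd.DataFrame({
        "state": states, "action": actions,
        "reward": rewards, "next_state": next_states,
    })
    for k, v in extra.items():
        df[k] = v
    return df
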