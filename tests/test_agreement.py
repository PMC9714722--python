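"""Resampled policy agreement and Cohen's kappa."""

import numpy as np
import pytest
from scipy import stats

import persuasion_rl as pr
from conftest import make_transition_frame


def _typed_samples(rng, n=3000, planted=None, noise=0.3):
    """Transition frame with alternating activity types; optionally a
    planted per-state best action."""
    s = rng.integers(0, 8, n)
    a = rng.integers(0, 5, n)
    ns = rng.integers(0, 8, n)
    if planted is None:
        r = rng.uniform(-1, 1, n)
    else:
        r = np.where(a == planted[s], 0.7, -0.3) + rng.uniform(-noise, noise, n)
        r = np.clip(r, -1, 1)
    types = np.where(np.arange(n) % 2 == 0, "SMOKING", "PHYSICAL_ACTIVITY")
    return make_transition_frame(s, a, r, ns, activity_type=types,
                                 person_id=[f"p{i % 40}" for i in range(n)])


def test_kappa_identity_and_symmetry():
    rng = np.random.default_rng(0)
    a = rng.integers(0, 5, 160)
    b = rng.integers(0, 5, 160)
    assert pr.cohens_kappa(a, a) == 1.0
    assert pr.cohens_kappa(a, b) == pytest.approx(pr.cohens_kappa(b, a))


def test_kappa_hand_computed_cases():
    """Disjoint constant lists give 0 (p_o = p_e = 0); the crossed 2x2
    pattern gives 0 (p_o = p_e = 0.5)."""
    assert pr.cohens_kappa([0] * 8, [1] * 8) == 0.0
    assert pr.cohens_kappa([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)


def test_kappa_identical_constant_lists_is_one():
    assert pr.cohens_kappa([2] * 8, [2] * 8) == 1.0


def test_kappa_length_mismatch_errors():
    with pytest.raises(ValueError):
        pr.cohens_kappa([0, 1], [0, 1, 2])


@pytest.mark.parametrize(
    "kappa, label",
    [(-0.2, "poor"), (0.1, "slight"), (0.33, "fair"), (0.49, "moderate"),
     (0.7, "substantial"), (0.81, "almost perfect"), (1.0, "almost perfect")],
)
def test_landis_koch_bands(kappa, label):
    assert pr.interpret_kappa(kappa) == label


def test_interpret_kappa_rejects_out_of_range():
    with pytest.raises(ValueError):
        pr.interpret_kappa(1.5)


def test_resample_single_rep_recovers_strict_argmax():
    """One repetition on a dataset with a strict unique argmax per state
    reproduces that policy exactly."""
    rng = np.random.default_rng(1)
    planted = np.arange(8) % 5
    samples = _typed_samples(rng, n=6000, planted=planted, noise=0.1)
    pl = pr.resample_policies(samples, "BOTH", 2, n_per_type=2500, reps=1,
                              rng=0)
    np.testing.assert_array_equal(pl.labels, planted)


def test_resample_deterministic_under_seed():
    rng = np.random.default_rng(2)
    samples = _typed_samples(rng, n=2000)
    a = pr.resample_policies(samples, "SMOKING", 2, n_per_type=400, reps=10,
                             rng=42)
    b = pr.resample_policies(samples, "SMOKING", 2, n_per_type=400, reps=10,
                             rng=42)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_resample_insufficient_samples_errors():
    rng = np.random.default_rng(3)
    samples = _typed_samples(rng, n=100)
    with pytest.raises(ValueError):
        pr.resample_policies(samples, "SMOKING", 2, n_per_type=1000, reps=1)


def test_uniform_tie_breaking_frequencies():
    """With all rewards equal, every action is a maximizer everywhere and
    the random tie-break picks each about 20% of the time (chi-square
    p > 0.001 over 500 repetitions)."""
    rng = np.random.default_rng(4)
    n = 1000
    samples = _typed_samples(rng, n=n)
    samples["reward"] = 0.0
    pl = pr.resample_policies(samples, "BOTH", 2, n_per_type=200, reps=500,
                              rng=7)
    counts = np.bincount(pl.labels, minlength=5)
    chi2, p = stats.chisquare(counts)
    assert p > 0.001


def test_same_truth_cross_type_kappa_near_one():
    """When both activity types share the ground truth and signal is strong,
    cross-type agreement approaches 1."""
    rng = np.random.default_rng(5)
    planted = (np.arange(8) + 1) % 5
    samples = _typed_samples(rng, n=8000, planted=planted, noise=0.2)
    a = pr.resample_policies(samples, "SMOKING", 2, n_per_type=1000, reps=20,
                             rng=1)
    b = pr.resample_policies(samples, "BOTH", 2, n_per_type=1000, reps=20,
                             rng=2)
    assert pr.cohens_kappa(a, b) > 0.95


def test_within_type_agreement_exceeds_cross_type_with_split_truth():
    """When the two activity types have different planted optima, two
    independent draws of the same type agree at least as well (in
    expectation over seeds) as cross-type draws."""
    rng = np.random.default_rng(6)
    n = 6000
    s = rng.integers(0, 8, n)
    a = rng.integers(0, 5, n)
    ns = rng.integers(0, 8, n)
    types = np.where(np.arange(n) % 2 == 0, "SMOKING", "PHYSICAL_ACTIVITY")
    best_smoking = np.arange(8) % 5
    best_pa = (np.arange(8) + 2) % 5
    best = np.where(types == "SMOKING", best_smoking[s], best_pa[s])
    r = np.clip(np.where(a == best, 0.6, -0.2)
                + rng.uniform(-0.3, 0.3, n), -1, 1)
    samples = make_transition_frame(s, a, r, ns, activity_type=types,
                                    person_id=["p0"] * n)
    within, cross = [], []
    for seed in range(10):
        sm1 = pr.resample_policies(samples, "SMOKING", 2, n_per_type=800,
                                   reps=5, rng=seed)
        sm2 = pr.resample_policies(samples, "SMOKING", 2, n_per_type=800,
                                   reps=5, rng=seed + 100)
        pa = pr.resample_policies(samples, "PHYSICAL_ACTIVITY", 2,
                                  n_per_type=800, reps=5, rng=seed + 200)
        within.append(pr.cohens_kappa(sm1, sm2))
        cross.append(pr.cohens_kappa(sm1, pa))
    assert np.mean(within) > np.mean(cross)


def test_agreement_report_layout():
    rng = np.random.default_rng(7)
    samples = _typed_samples(rng, n=2000, planted=np.arange(8) % 5)
    report = pr.agreement_report(samples, levels=(2,), n_per_type=300,
                                 reps=5, rng=0)
    assert set(report["analysis"]) == {"main", "reference"}
    assert len(report) == 5
    assert set(report.columns) >= {"kappa", "interpretation", "level"}
    assert report["kappa"].between(-1, 1).all()
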