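"""Design-time calibration: Bayesian power, regression sample size, and the
sample-size vs Q-estimation-error study.

``bayes_power`` reproduces the Monte-Carlo design analysis: two conditions
with standard-normal outcomes and a given true mean difference; an
experiment "succeeds" when the directional Bayes factor for the second mean
exceeding the first reaches a threshold (19, i.e. posterior odds 19:1 under
equal prior odds). ``regression_sample_size`` implements Cohen's
noncentral-F sample-size rule for multiple regression. ``q_error_study``
quantifies how Q-value estimates and the induced greedy actions degrade as
the training set shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.utils.validation import check_random_state

from .actions import N_ACTIONS, N_STATES
from .mdp import estimate_models, value_iteration

#: Cohen's f-squared benchmarks for multiple regression.
EFFECT_SIZES = {"small": 0.02, "medium": 0.15, "large": 0.35}


@dataclass(frozen=True)
class PowerResult:
    """Outcome of the Monte-Carlo Bayesian power analysis."""

    power: float
    n_per_condition: int
    n_sims: int
    bf_threshold: float
    delta: float

    @property
    def mc_standard_error(self) -> float:
        return float(np.sqrt(self.power * (1 - self.power) / self.n_sims))


def directional_bayes_factor(x, y) -> float:
    """Bayes factor for "mean(y) > mean(x)" under a flat prior.

    With an improper flat prior on the mean difference and pooled variance,
    the posterior of the difference is a scaled t; the Bayes factor is the
    posterior odds p/(1-p) with p = P(mu_y - mu_x > 0 | data). Equal prior
    odds make BF >= 19 equivalent to p >= 0.95.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each condition needs at least two observations")
    nx, ny = x.size, y.size
    sp2 = (((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
           / (nx + ny - 2))
    se = np.sqrt(sp2 * (1 / nx + 1 / ny))
    t = (y.mean() - x.mean()) / se
    p = stats.t.cdf(t, nx + ny - 2)
    if p >= 1.0:
        return np.inf
    return float(p / (1 - p))


def bayes_power(
    n_per_cond: int,
    delta: float = 0.3,
    n_sims: int = 500,
    bf_threshold: float = 19.0,
    rng=None,
) -> PowerResult:
    """Monte-Carlo power of a two-condition design under a BF criterion.

    Per simulation, draws ``n_per_cond`` observations from N(0, 1) and from
    N(delta, 1) and computes the directional Bayes factor for the second
    mean being larger; power is the fraction of simulations with
    BF >= ``bf_threshold``.
    """
    if n_per_cond < 2:
        raise ValueError("n_per_cond must be at least 2")
    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    rng = check_random_state(rng)
    n = n_per_cond
    x = rng.standard_normal((n_sims, n))
    y = rng.standard_normal((n_sims, n)) + delta
    sp2 = (x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2.0
    t = (y.mean(axis=1) - x.mean(axis=1)) / np.sqrt(sp2 * 2.0 / n)
    p = stats.t.cdf(t, 2 * n - 2)
    with np.errstate(divide="ignore"):
        bf = np.where(p >= 1.0, np.inf, p / (1.0 - p))
    power = float(np.mean(bf >= bf_threshold))
    return PowerResult(power=power, n_per_condition=n_per_cond,
                       n_sims=n_sims, bf_threshold=bf_threshold, delta=delta)


def closed_form_power(n_per_cond: int, delta: float,
                      alpha: float = 0.05) -> float:
    """Normal-approximation one-sided power Phi(delta sqrt(n/2) - z_(1-a))."""
    z = stats.norm.ppf(1 - alpha)
    return float(stats.norm.cdf(delta * np.sqrt(n_per_cond / 2.0) - z))


def cohen_l(n_predictors: int, power: float = 0.80,
            alpha: float = 0.05) -> float:
    """Cohen's L: the noncentrality a chi-square test with ``n_predictors``
    degrees of freedom needs to reach ``power`` at level ``alpha`` (the
    large-denominator-df limit of the noncentral F used in his tables)."""
    crit = stats.chi2.ppf(1 - alpha, n_predictors)
    return float(optimize.brentq(
        lambda lam: 1 - stats.ncx2.cdf(crit, n_predictors, lam) - power,
        1e-6, 1e3))


def regression_sample_size(
    n_predictors: int = 3,
    effect="medium",
    alpha: float = 0.05,
    power: float = 0.80,
    convention: str = "ceil",
) -> int:
    """Required total n for a multiple regression per Cohen's rule.

    Parameters
    ----------
    n_predictors : int
        Number of independent variables (u).
    effect : {"small", "medium", "large"} or float
        Cohen's f-squared benchmark name or an explicit f-squared.
    convention : {"ceil", "plus-one"}
        ``"ceil"`` computes ceil(L / f^2 + u); ``"plus-one"`` uses the
        textbook n = L / f^2 + u + 1 rounded up. Both floor at u + 2, the
        smallest n with any residual degree of freedom.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if power <= alpha:
        raise ValueError("power must exceed alpha")
    f2 = EFFECT_SIZES[effect] if isinstance(effect, str) else float(effect)
    if f2 <= 0:
        raise ValueError("effect size f^2 must be positive")
    L = cohen_l(n_predictors, power=power, alpha=alpha)
    if convention == "ceil":
        n = int(np.ceil(L / f2 + n_predictors))
    elif convention == "plus-one":
        n = int(np.ceil(L / f2 + n_predictors + 1))
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return max(n, n_predictors + 2)


def scale_by_actions(n: int, n_actions: int = N_ACTIONS) -> int:
    """Scale a per-action sample size by the number of actions."""
    return n * n_actions


@dataclass(frozen=True)
class L1Study:
    """Mean L1 errors of Q estimation as a function of sample size.

    ``mean_l1_q[k]`` is the mean absolute difference between subsample and
    reference Q-values over all 40 (state, action) cells at ``sizes[k]``;
    ``mean_l1_action[k]`` is the mean (over states) reference-Q gap between
    the subsample's greedy action and the reference-optimal action.
    """

    sizes: np.ndarray
    mean_l1_q: np.ndarray
    mean_l1_action: np.ndarray
    reps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "size": self.sizes,
            "mean_l1_q": self.mean_l1_q,
            "mean_l1_action": self.mean_l1_action,
        })


def q_error_study(
    states,
    actions,
    rewards,
    next_states,
    sizes,
    reps: int = 100,
    gamma: float = 0.85,
    rng=None,
) -> L1Study:
    """How Q-estimates degrade as the training subsample shrinks.

    Reference Q-values and the reference-optimal policy come from the full
    transition set; each repetition draws a uniform subsample without
    replacement of the requested size and re-estimates Q.
    """
    states = np.asarray(states, dtype=np.intp)
    actions = np.asarray(actions, dtype=np.intp)
    rewards = np.asarray(rewards, dtype=float)
    next_states = np.asarray(next_states, dtype=np.intp)
    sizes = np.asarray(sizes, dtype=int)
    n = states.shape[0]
    if reps < 1:
        raise ValueError("reps must be positive")
    if np.any(sizes < 1) or np.any(sizes > n):
        raise ValueError("sizes must lie in [1, n_samples]")
    rng = check_random_state(rng)

    ref_model = estimate_models(states, actions, rewards, next_states)
    ref_q = value_iteration(ref_model, gamma=gamma)
    ref_best = ref_q.max(axis=1)

    mean_q_err = np.empty(sizes.shape[0])
    mean_act_err = np.empty(sizes.shape[0])
    for k, size in enumerate(sizes):
        q_errs = np.empty(reps)
        act_errs = np.empty(reps)
        for rep in range(reps):
            take = rng.choice(n, size=size, replace=False)
            model = estimate_models(states[take], actions[take],
                                    rewards[take], next_states[take])
            q_hat = value_iteration(model, gamma=gamma)
            q_errs[rep] = np.abs(q_hat - ref_q).mean()
            greedy = q_hat.argmax(axis=1)
            act_errs[rep] = (ref_best
                             - ref_q[np.arange(N_STATES), greedy]).mean()
        mean_q_err[k] = q_errs.mean()
        mean_act_err[k] = act_errs.mean()
    return L1Study(sizes=sizes, mean_l1_q=mean_q_err,
                   mean_l1_action=mean_act_err, reps=reps)
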