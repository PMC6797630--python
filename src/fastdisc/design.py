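"""Adaptive measurement protocol for inter-temporal choice sessions.

The emulated protocol fixes the delayed reward B per commodity (20 for
money and music, 10 for food, on the exchange scale 20 money = 20 song
downloads = 10 chocolate bars), restricts the delay D_B to a grid of 19
geometrically spaced values between one hour and one year, and picks each
trial's immediate amount A and delay D_B adaptively.

The trial selector maximizes the myopic expected Shannon information gain
about the session parameters: for a candidate design d and posterior
draws theta_i, the mutual information between the next response and the
parameters is

    EIG(d) = H( mean_i P_i ) - mean_i H( P_i )

with P_i = P(choose delayed | theta_i, d) and H the binary entropy.  This
is maximized where the draws disagree about the choice, i.e. near the
posterior's indifference region, and is zero for designs every draw calls
the same way.  Between trials the session runner updates a particle
approximation of the posterior by importance reweighting with systematic
resampling and a shrinkage jitter move; the final reported fit always
comes from a full MCMC run (:func:`fastdisc.inference.fit_posterior`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .choices import ChoiceDataset, ChoiceParams, Trial
from .discounting import DiscountFunction
from .inference import Posterior, PriorSpec, choice_probability_matrix

TRIALS_PER_SESSION = 35
N_DELAYS = 19
MIN_DELAY_DAYS = 1.0 / 24.0  # one hour
MAX_DELAY_DAYS = 365.0  # one year

#: Fixed delayed-reward magnitude per commodity (exchange-rate scale).
DELAYED_REWARD = {"money": 20.0, "music": 20.0, "food": 10.0}


def build_delay_grid() -> np.ndarray:
    """The 19 candidate delays in days, geometrically spaced 1 h .. 1 year."""
    return np.geomspace(MIN_DELAY_DAYS, MAX_DELAY_DAYS, N_DELAYS)


def _default_amounts(b: float) -> np.ndarray:
    # percent granularity: A in {B/100, ..., 99B/100}
    return b * np.arange(1, 100) / 100.0


@dataclass
class DesignSpace:
    """Candidate designs for one commodity's sessions."""

    delayed_reward_B: float
    delays: np.ndarray = field(default_factory=build_delay_grid)
    immediate_amounts: np.ndarray | None = None
    trials_per_session: int = TRIALS_PER_SESSION

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, float)
        if len(self.delays) != N_DELAYS or np.any(np.diff(self.delays) <= 0):
            raise ValueError(f"delay grid must be {N_DELAYS} strictly increasing values")
        if not self.delayed_reward_B > 0:
            raise ValueError("delayed reward B must be positive")
        if self.immediate_amounts is None:
            self.immediate_amounts = _default_amounts(self.delayed_reward_B)
        self.immediate_amounts = np.asarray(self.immediate_amounts, float)
        if self.immediate_amounts.size == 0:
            raise ValueError("candidate immediate-amount set is empty")
        if np.any((self.immediate_amounts <= 0) | (self.immediate_amounts > self.delayed_reward_B)):
            raise ValueError("every candidate A must satisfy 0 < A <= B")

    @classmethod
    def for_commodity(cls, commodity: str) -> "DesignSpace":
        return cls(delayed_reward_B=DELAYED_REWARD[commodity])

    def candidate_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """All (A, D_B) candidate pairs, flattened."""
        A, D = np.meshgrid(self.immediate_amounts, self.delays, indexing="ij")
        return A.ravel(), D.ravel()


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -(p * np.log(p) + (1.0 - p) * np.log1p(-p))


def expected_information_gain(
    theta: np.ndarray,
    weights: np.ndarray | None,
    space: DesignSpace,
    spec: DiscountFunction | None = None,
) -> np.ndarray:
    """EIG of every candidate design under (optionally weighted) draws."""
    A, D = space.candidate_grid()
    family = spec.family if spec is not None else "hyperbolic"
    s = spec.s if spec is not None else None
    B = np.full_like(A, space.delayed_reward_B)
    p = choice_probability_matrix(theta[:, 0], theta[:, 1], theta[:, 2], A, B, D, family, s)
    if weights is None:
        weights = np.full(theta.shape[0], 1.0 / theta.shape[0])
    p_bar = weights @ p
    return _binary_entropy(p_bar) - weights @ _binary_entropy(p)


def select_next_trial(
    posterior: Posterior,
    space: DesignSpace,
    history: list[Trial] | None = None,
    rng_seed: int = 0,
    spec: DiscountFunction | None = None,
    max_draws: int = 512,
) -> Trial:
    """Pick the (A, D_B) pair maximizing expected information gain.

    Deterministic for a fixed posterior and seed (the seed only thins the
    draw set when it exceeds ``max_draws``).  ``history`` is accepted for
    protocol symmetry; repeats of an earlier design are allowed, as a
    repeated question still carries information under response noise.
    """
    theta = posterior.theta()
    if theta.shape[0] > max_draws:
        idx = np.random.default_rng(rng_seed).choice(theta.shape[0], max_draws, replace=False)
        theta = theta[idx]
    gain = expected_information_gain(theta, None, space, spec)
    A, D = space.candidate_grid()
    best = int(np.argmax(gain))  # ties: first (lowest A, shortest delay)
    return Trial(A=float(A[best]), B=float(space.delayed_reward_B), D_B=float(D[best]))


# ---------------------------------------------------------------------------
# particle filter for interim posterior updates


class _ParticleFilter:
    """Sequential importance resampling over (log_k, alpha, epsilon).

    Cheap interim updater for design selection only; resamples with a
    Liu-West style shrinkage jitter when the effective sample size drops
    below half the particle count.
    """

    def __init__(self, priors: PriorSpec, n: int, rng: np.random.Generator, shrink: float = 0.98):
        self.theta = priors.sample(rng, n)
        self.theta[:, 2] = np.clip(self.theta[:, 2], 1e-6, 0.5 - 1e-6)
        self.logw = np.zeros(n)
        self.rng = rng
        self.shrink = shrink

    @property
    def weights(self) -> np.ndarray:
        w = np.exp(self.logw - self.logw.max())
        return w / w.sum()

    def update(self, trial: Trial, response: int, spec: DiscountFunction | None) -> None:
        family = spec.family if spec is not None else "hyperbolic"
        s = spec.s if spec is not None else None
        p = choice_probability_matrix(
            self.theta[:, 0],
            self.theta[:, 1],
            self.theta[:, 2],
            np.array([trial.A]),
            np.array([trial.B]),
            np.array([trial.D_B]),
            family,
            s,
        )[:, 0]
        p = np.clip(p, 1e-12, 1 - 1e-12)
        self.logw += np.log(p if response == 1 else 1.0 - p)
        w = self.weights
        if 1.0 / np.sum(w**2) < 0.5 * len(w):
            self._resample(w)

    def _resample(self, w: np.ndarray) -> None:
        n = len(w)
        # systematic resampling
        u = (self.rng.random() + np.arange(n)) / n
        idx = np.searchsorted(np.cumsum(w), u)
        theta = self.theta[np.clip(idx, 0, n - 1)]
        mean = w @ self.theta
        cov = np.cov(self.theta.T, aweights=w) + 1e-10 * np.eye(3)
        a = self.shrink
        center = a * theta + (1 - a) * mean
        jitter = self.rng.multivariate_normal(np.zeros(3), (1 - a**2) * cov, n)
        theta = center + jitter
        theta[:, 1] = np.maximum(theta[:, 1], 1e-4)
        theta[:, 2] = np.clip(theta[:, 2], 1e-6, 0.5 - 1e-6)
        self.theta = theta
        self.logw = np.zeros(n)


def run_simulated_session(
    true_params: ChoiceParams,
    space: DesignSpace,
    priors: PriorSpec | None = None,
    spec: DiscountFunction | None = None,
    rng_seed: int = 0,
    participant: str = "sim",
    condition: str = "control",
    commodity: str = "money",
    n_particles: int = 500,
    adaptive: bool = True,
) -> ChoiceDataset:
    """Simulate a full adaptive session for a known responder.

    Alternates design selection (EIG over the current particle posterior),
    response simulation from ``true_params``, and particle reweighting,
    for ``space.trials_per_session`` trials.  With ``adaptive=False``
    designs are drawn uniformly from the candidate grid (baseline).
    Reproducible for a fixed seed.
    """
    priors = priors or PriorSpec()
    rng = np.random.default_rng(rng_seed)
    pf = _ParticleFilter(priors, n_particles, rng)
    A_cand, D_cand = space.candidate_grid()
    trials: list[Trial] = []
    for _ in range(space.trials_per_session):
        if adaptive:
            gain = expected_information_gain(pf.theta, pf.weights, space, spec)
            best = int(np.argmax(gain))
        else:
            best = int(rng.integers(len(A_cand)))
        trial = Trial(
            A=float(A_cand[best]), B=float(space.delayed_reward_B), D_B=float(D_cand[best])
        )
        p = choice_probability_matrix(
            np.array([true_params.log_k]),
            np.array([true_params.alpha]),
            np.array([true_params.epsilon]),
            np.array([trial.A]),
            np.array([trial.B]),
            np.array([trial.D_B]),
            spec.family if spec is not None else "hyperbolic",
            spec.s if spec is not None else None,
        )[0, 0]
        r = int(rng.random() < p)
        trial = trial.with_response(r)
        pf.update(trial, r, spec)
        trials.append(trial)
    return ChoiceDataset(participant, condition, commodity, trials)
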