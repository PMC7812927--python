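"""Bayesian calibration of the nine guild maximum growth rates.

A Metropolis-Hastings random walk with reflection at the uniform prior
bounds.  The likelihood is independent Gaussian around pool-stability
observations (each pool observed once a year at mid-year, with the stated
standard deviation), computed from a deterministic forward run per proposal.
The posterior sample used for scenario work is the last N accepted parameter
vectors after burn-in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_state import GUILDS, POOLS, ValidationError
from .engine import SimulationResult, run

__all__ = [
    "CalibrationProblem",
    "Chain",
    "observation_days",
    "log_likelihood",
    "propose_reflect",
    "metropolis_run",
    "posterior_sample",
    "make_objective",
    "calibrate",
]


def observation_days(n_days: int, first: int = 180, spacing: int = 365) -> np.ndarray:
    """Yearly observation days: ``first + spacing*k`` for all k within the run.

    A fixed 365-day spacing (leap days ignored), matching mid-year sampling
    of pools assumed stable year over year.
    """
    days = np.arange(first, n_days, spacing, dtype=np.int64)
    if days.size == 0:
        raise ValidationError(f"run of {n_days} days has no observation day >= {first}")
    return days


@dataclass
class CalibrationProblem:
    """Priors, observations and sampler settings for one calibration.

    ``observations`` is a DataFrame with columns pool, value, sd (g C m^-3);
    each pool is observed at every day in ``obs_days``.  ``proposal_scale``
    is the random-walk step standard deviation as a fraction of each prior
    range.
    """

    bounds: np.ndarray  # (9, 2) lower/upper per guild, in GUILDS order
    observations: pd.DataFrame
    obs_days: np.ndarray
    names: tuple = GUILDS
    proposal_scale: float = 0.05
    n_iterations: int = 10_000
    burn_in: float = 0.5
    posterior_size: int = 100
    seed: int = 0

    def __post_init__(self):
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.shape != (len(self.names), 2):
            raise ValidationError("bounds must be (n_params, 2)")
        if (self.bounds[:, 0] > self.bounds[:, 1]).any():
            raise ValidationError("lower bounds must not exceed upper bounds")
        if (np.asarray(self.observations["sd"], dtype=float) <= 0).any():
            raise ValidationError("observation sds must be > 0")
        if not 0.0 <= self.burn_in < 1.0:
            raise ValidationError("burn_in fraction must be in [0,1)")
        self.obs_days = np.asarray(self.obs_days, dtype=np.int64)

    @property
    def step_scales(self) -> np.ndarray:
        return self.proposal_scale * (self.bounds[:, 1] - self.bounds[:, 0])

    @property
    def n_data(self) -> int:
        return len(self.observations) * len(self.obs_days)


@dataclass
class Chain:
    """One MCMC chain: the state at every iteration plus acceptance flags."""

    params: np.ndarray  # (n_iter, n_params), current state per iteration
    loglik: np.ndarray
    accepted: np.ndarray  # True where the proposal of this iteration was accepted
    names: tuple = GUILDS
    burn_in: float = 0.5

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean())

    def posterior(self) -> np.ndarray:
        """Accepted states after burn-in, in chain order."""
        start = int(len(self.params) * self.burn_in)
        acc = self.accepted.copy()
        acc[:start] = False
        return self.params[acc]

    def summary(self) -> pd.DataFrame:
        """Posterior mean +/- sd per parameter from the last accepted sample."""
        post = self.posterior()
        return pd.DataFrame(
            {"mean": post.mean(axis=0), "sd": post.std(axis=0, ddof=1)},
            index=list(self.names),
        )


def log_likelihood(result: SimulationResult, observations: pd.DataFrame, obs_days) -> float:
    """Independent-Gaussian log-likelihood of a run against the observations.

    Each (pool, day) pair contributes a normal log-density with the stated
    sd; the run must cover every observation day.
    """
    obs_days = np.asarray(obs_days, dtype=np.int64)
    if obs_days.max() >= result.n_days:
        raise ValidationError(
            f"run of {result.n_days} days misses observation day {obs_days.max()}"
        )
    ll = 0.0
    for _, row in observations.iterrows():
        sim = result.pool(row["pool"])[obs_days]
        sd = float(row["sd"])
        resid = (sim - float(row["value"])) / sd
        ll += float(-0.5 * np.sum(resid**2) - obs_days.size * math.log(sd * math.sqrt(2.0 * math.pi)))
    return ll


def propose_reflect(theta: np.ndarray, step_scales, bounds, rng) -> np.ndarray:
    """Gaussian random-walk proposal reflected at the prior bounds.

    Coordinates bounce off the bounds until inside, preserving proposal
    symmetry; a zero step returns theta unchanged.
    """
    theta = np.asarray(theta, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    if (theta < bounds[:, 0]).any() or (theta > bounds[:, 1]).any():
        raise ValidationError("theta outside prior bounds")
    prop = theta + rng.normal(0.0, 1.0, theta.shape) * np.asarray(step_scales, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    width = hi - lo
    for i in range(len(prop)):
        if width[i] <= 0.0:
            prop[i] = lo[i]
            continue
        x = prop[i]
        while x < lo[i] or x > hi[i]:
            if x < lo[i]:
                x = 2.0 * lo[i] - x
            if x > hi[i]:
                x = 2.0 * hi[i] - x
        prop[i] = x
    return prop


def metropolis_run(
    problem: CalibrationProblem, objective, theta0=None, init_screen: int = 0
) -> Chain:
    """Metropolis-Hastings random walk with reflection.

    ``objective(theta) -> log-likelihood``; with the uniform prior and the
    symmetric reflected proposal, the acceptance ratio reduces to the
    likelihood ratio.  A failing objective rejects the proposal with a
    warning.  Reproducible given ``problem.seed``.

    ``init_screen > 0`` draws that many prior samples first and starts the
    walk from the best of them (a burn-in accelerator; the kernel itself is
    unchanged).  Otherwise the start is a single prior draw.
    """
    rng = np.random.default_rng(problem.seed)
    n_p = len(problem.names)
    if theta0 is None:
        if init_screen > 0:
            cand = rng.uniform(
                problem.bounds[:, 0], problem.bounds[:, 1], size=(init_screen, n_p)
            )
            lls = np.full(init_screen, -np.inf)
            for k in range(init_screen):
                try:
                    lls[k] = objective(cand[k])
                except Exception:
                    pass
            theta0 = cand[int(np.argmax(lls))]
        else:
            theta0 = rng.uniform(problem.bounds[:, 0], problem.bounds[:, 1])
    theta = np.asarray(theta0, dtype=float)
    ll = objective(theta)

    params = np.empty((problem.n_iterations, n_p))
    logliks = np.empty(problem.n_iterations)
    accepted = np.zeros(problem.n_iterations, dtype=bool)
    scales = problem.step_scales
    for i in range(problem.n_iterations):
        prop = propose_reflect(theta, scales, problem.bounds, rng)
        try:
            ll_prop = objective(prop)
        except Exception as exc:  # failed forward run: reject
            warnings.warn(f"model run failed at iteration {i}: {exc}", stacklevel=2)
            ll_prop = -np.inf
        if math.log(rng.random()) < ll_prop - ll:
            theta, ll = prop, ll_prop
            accepted[i] = True
        params[i] = theta
        logliks[i] = ll
    return Chain(params, logliks, accepted, problem.names, problem.burn_in)


def posterior_sample(chain: Chain, n: int = 100) -> np.ndarray:
    """The last ``n`` accepted parameter vectors after burn-in, in order."""
    post = chain.posterior()
    if len(post) < n:
        raise ValidationError(
            f"only {len(post)} accepted states after burn-in; need {n} - "
            "increase n_iterations"
        )
    return post[-n:]


def make_objective(config, climate, problem: CalibrationProblem, n_days: int, fast: bool = True):
    """Objective closure: set the nine g_max values, run, score.

    The forward model is deterministic, so the likelihood surface is fixed
    given config and climate.
    """
    def objective(theta: np.ndarray) -> float:
        cfg = config.copy()
        for name, value in zip(problem.names, theta):
            cfg.guilds[name].g_max = float(value)
        result = run(cfg, climate, n_days, fast=fast)
        return log_likelihood(result, problem.observations, problem.obs_days)

    return objective


def calibrate(
    config,
    climate,
    observations: pd.DataFrame,
    priors: dict,
    n_days: int,
    n_iterations: int = 10_000,
    seed: int = 0,
    proposal_scale: float = 0.05,
    posterior_size: int = 100,
    fast: bool = True,
    init_screen: int = 500,
    max_extensions: int = 2,
) -> tuple:
    """Convenience wrapper: build the problem, run the chain, draw the sample.

    Returns ``(chain, sample)`` where ``sample`` is the (posterior_size, 9)
    array of the last accepted g_max vectors.  If too few states are accepted
    after burn-in (the walk entered the mode late), the chain is extended
    from its last state up to ``max_extensions`` times before giving up.
    """
    bounds = np.array([priors[g] for g in GUILDS], dtype=float)
    problem = CalibrationProblem(
        bounds=bounds,
        observations=observations,
        obs_days=observation_days(n_days),
        n_iterations=n_iterations,
        seed=seed,
        proposal_scale=proposal_scale,
        posterior_size=posterior_size,
    )
    objective = make_objective(config, climate, problem, n_days, fast=fast)
    chain = metropolis_run(problem, objective, init_screen=init_screen)
    for ext in range(max_extensions + 1):
        try:
            sample = posterior_sample(chain, posterior_size)
            return chain, sample
        except ValidationError:
            if ext == max_extensions:
                raise
            problem.seed = problem.seed + 100_003
            more = metropolis_run(problem, objective, theta0=chain.params[-1])
            chain = Chain(
                params=np.vstack([chain.params, more.params]),
                loglik=np.concatenate([chain.loglik, more.loglik]),
                accepted=np.concatenate([chain.accepted, more.accepted]),
                names=chain.names,
                burn_in=chain.burn_in,
            )
    raise AssertionError("unreachable")
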