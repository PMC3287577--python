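"""Metropolis-Hastings sampling with an analytically marginalized noise
variance.

Observations are modeled as ``y_i = x_i + eps_i`` with i.i.d. Gaussian
measurement noise ``eps ~ N(0, sigma^2)``; the likelihood of a parameter
vector theta is evaluated through one-step-ahead RK4 predictions.  With the
model error

    M.E.(theta) = sum_i (y_i^s - y_i)^2

and a conjugate Inverse-Gamma prior ``sigma^2 ~ IG(eta2, beta2)``, the noise
variance integrates out in closed form, leaving

    p(y | theta)  ∝  (M.E. + 2*beta2)^(-(m + 2*eta2)/2),

so the sampler never has to carry sigma^2 as a chain dimension.  Parameters
are strictly positive, so both priors and proposals are Gamma distributions;
the proposal for a parameter at value theta_i is multiplicative,
``Gamma(shape eta1, scale beta1*theta_i)``.  All density arithmetic is done
in the log domain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import DynamicsModel, ObservedSeries, OneStepPredictor

__all__ = [
    "GammaPrior",
    "NoiseVariancePrior",
    "ProposalSpec",
    "MCMCConfig",
    "Chain",
    "PosteriorSummary",
    "model_error",
    "log_marginal_likelihood",
    "log_prior",
    "propose",
    "log_proposal_ratio",
    "log_acceptance",
    "run_chain",
    "mmse",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape eta, scale beta) prior for a positive parameter.

    Density: ``p(theta) = theta^(eta-1) exp(-theta/beta) / (beta^eta Gamma(eta))``.
    Flat (weakly informative) priors are obtained with small shape and a
    scale spanning the plausible parameter range.
    """

    eta: float
    beta: float

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.beta <= 0:
            raise ValueError("Gamma prior requires eta > 0 and beta > 0")

    @property
    def mean(self) -> float:
        return self.eta * self.beta

    @property
    def variance(self) -> float:
        return self.eta * self.beta**2


@dataclass(frozen=True)
class NoiseVariancePrior:
    """Inverse-Gamma prior IG(eta2, beta2) on the measurement-noise variance."""

    eta2: float = 2.0
    beta2: float = 10.0

    def __post_init__(self) -> None:
        if self.eta2 <= 0 or self.beta2 <= 0:
            raise ValueError("IG prior requires eta2 > 0 and beta2 > 0")


@dataclass(frozen=True)
class ProposalSpec:
    """Multiplicative Gamma proposal: theta* ~ Gamma(eta1, beta1 * theta_i).

    The proposal mean is ``eta1*beta1*theta_i``; the default ``eta1=2,
    beta1=0.5`` makes the walk mean-unbiased (proposal mean equals the
    current value) with relative standard deviation ``1/sqrt(eta1)``.
    """

    eta1: float = 2.0
    beta1: float = 0.5

    def __post_init__(self) -> None:
        if self.eta1 <= 0 or self.beta1 <= 0:
            raise ValueError("proposal requires eta1 > 0 and beta1 > 0")


@dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = 2000
    burn_in: int = 1500
    seed: int = 0
    update_scheme: str = "componentwise"

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.update_scheme not in ("componentwise", "joint"):
            raise ValueError("update_scheme must be 'componentwise' or 'joint'")


def model_error(y, y_s) -> float:
    """Sum of squared prediction residuals, M.E. = sum (y_i^s - y_i)^2."""
    y = np.asarray(y, dtype=float)
    y_s = np.asarray(y_s, dtype=float)
    if y.shape != y_s.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_s.shape}")
    r = y_s - y
    return float(r @ r)


def log_marginal_likelihood(me: float, m: int, prior: NoiseVariancePrior) -> float:
    """Log of the noise-variance-marginalized Gaussian likelihood.

    Integrating sigma^2 out of the product-Gaussian likelihood against
    IG(eta2, beta2) gives

        p(y|theta) = (2*pi)^(-m/2) * beta2^eta2 / Gamma(eta2)
                     * Gamma(m/2 + eta2) * (M.E./2 + beta2)^(-(m/2 + eta2))

    evaluated entirely in the log domain; ``m`` is the number of residuals
    entering M.E.
    """
    if me < 0:
        raise ValueError("model error must be nonnegative")
    if m < 1:
        raise ValueError("need at least one residual")
    e2, b2 = prior.eta2, prior.beta2
    const = (
        -0.5 * m * math.log(2.0 * math.pi)
        + e2 * math.log(b2)
        - math.lgamma(e2)
        + math.lgamma(0.5 * m + e2)
    )
    return const - (0.5 * m + e2) * math.log(0.5 * me + b2)


def log_prior(theta: float, prior: GammaPrior) -> float:
    """Log Gamma density at theta (shape eta, scale beta)."""
    if theta <= 0:
        raise ValueError("parameters are strictly positive")
    eta, beta = prior.eta, prior.beta
    return (eta - 1.0) * math.log(theta) - theta / beta - eta * math.log(beta) - math.lgamma(eta)


def propose(theta_i: float, spec: ProposalSpec, rng: np.random.Generator) -> float:
    """Draw theta* from Gamma(shape eta1, scale beta1*theta_i)."""
    if theta_i <= 0:
        raise ValueError("current parameter value must be positive")
    return float(rng.gamma(shape=spec.eta1, scale=spec.beta1 * theta_i))


def log_proposal_ratio(theta_i: float, theta_star: float, spec: ProposalSpec) -> float:
    """log q(theta_i | theta*) - log q(theta* | theta_i).

    For the multiplicative Gamma proposal this reduces to
    ``(2*eta1 - 1)*log(theta_i/theta*) + (theta*/theta_i - theta_i/theta*)/beta1``.
    """
    if theta_i <= 0 or theta_star <= 0:
        raise ValueError("proposal ratio needs strictly positive values")
    r = theta_i / theta_star
    return (2.0 * spec.eta1 - 1.0) * math.log(r) + (1.0 / r - r) / spec.beta1


def log_acceptance(
    me_star: float,
    me_i: float,
    m: int,
    theta_star: float,
    theta_i: float,
    prior: GammaPrior,
    noise_prior: NoiseVariancePrior,
    spec: ProposalSpec,
) -> float:
    """Log of the MH ratio alpha for a scalar update.

    log alpha = -((m + 2*eta2)/2) * log((M.E.* + 2*beta2)/(M.E.^i + 2*beta2))
                + log p(theta*) - log p(theta^i)
                + log q(theta^i|theta*) - log q(theta*|theta^i)

    The move is accepted with probability min(1, exp(log alpha)).
    """
    e2, b2 = noise_prior.eta2, noise_prior.beta2
    loglik = -(0.5 * m + e2) * (math.log(me_star + 2.0 * b2) - math.log(me_i + 2.0 * b2))
    return (
        loglik
        + log_prior(theta_star, prior)
        - log_prior(theta_i, prior)
        + log_proposal_ratio(theta_i, theta_star, spec)
    )


@dataclass
class Chain:
    """An MH chain: one column of samples per estimable parameter, with
    per-parameter acceptance bookkeeping."""

    param_names: tuple[str, ...]
    samples: np.ndarray          # (n_iter, n_params)
    accepted: np.ndarray         # (n_iter, n_params) bool
    config: MCMCConfig
    n_nonfinite: int = 0

    @property
    def n_iter(self) -> int:
        return self.samples.shape[0]

    @property
    def accept_count(self) -> dict[str, int]:
        return dict(zip(self.param_names, self.accepted.sum(axis=0).tolist()))

    @property
    def accept_rate(self) -> dict[str, float]:
        return {k: v / self.n_iter for k, v in self.accept_count.items()}

    def retained(self, burn_in: int | None = None) -> np.ndarray:
        b = self.config.burn_in if burn_in is None else burn_in
        if not 0 <= b < self.n_iter:
            raise ValueError("burn-in must leave at least one retained sample")
        return self.samples[b:]

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy frame: one row per iteration, sample and accepted-flag
        columns per parameter, plus a retained (post burn-in) flag."""
        df = pd.DataFrame(self.samples, columns=list(self.param_names))
        df.insert(0, "iteration", np.arange(self.n_iter))
        for j, name in enumerate(self.param_names):
            df[f"accepted_{name}"] = self.accepted[:, j].astype(int)
        df["retained"] = (df["iteration"] >= self.config.burn_in).astype(int)
        return df


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior means (MMSE estimates) and credible-interval endpoints
    computed from the retained (post burn-in) samples."""

    mmse: dict[str, float]
    quantiles: dict[str, tuple[float, float]]
    n_retained: int
    q_levels: tuple[float, float] = (0.025, 0.975)

    def to_dataframe(self) -> pd.DataFrame:
        lo, hi = self.q_levels
        return pd.DataFrame(
            {
                "parameter": list(self.mmse),
                "mmse": [self.mmse[k] for k in self.mmse],
                f"q{100 * lo:g}": [self.quantiles[k][0] for k in self.mmse],
                f"q{100 * hi:g}": [self.quantiles[k][1] for k in self.mmse],
                "n_retained": self.n_retained,
            }
        )


def _as_prior_map(priors, param_names) -> dict[str, GammaPrior]:
    if isinstance(priors, GammaPrior):
        return {name: priors for name in param_names}
    missing = set(param_names) - set(priors)
    if missing:
        raise ValueError(f"no prior given for parameter(s): {sorted(missing)}")
    return {name: priors[name] for name in param_names}


def run_chain(
    model: DynamicsModel,
    data: ObservedSeries,
    inputs,
    priors: Mapping[str, GammaPrior] | GammaPrior,
    noise_prior: NoiseVariancePrior = NoiseVariancePrior(),
    proposal: ProposalSpec = ProposalSpec(),
    config: MCMCConfig = MCMCConfig(),
    *,
    init: Sequence[float] | None = None,
    log_likelihood: Callable[[np.ndarray], float] | None = None,
) -> Chain:
    """Run the Metropolis-Hastings sampler and return the full chain.

    Each iteration recomputes one-step-ahead predictions at the proposed
    parameters, evaluates the marginalized likelihood and accepts with
    probability min(1, alpha).  The componentwise scheme (default) proposes
    and accepts each parameter separately, in declared order, holding the
    others at their current values; the joint scheme proposes all
    components at once under a single accept.

    The chain is initialized from one prior draw per parameter (or ``init``)
    and is bitwise-reproducible for a fixed config seed.  ``log_likelihood``
    overrides the data-based marginal likelihood (used for sampler
    validation, e.g. prior recovery); proposals with a non-finite
    acceptance ratio are rejected and counted in ``Chain.n_nonfinite``.
    """
    names = model.param_names
    if not names:
        raise ValueError("model has no estimable parameters")
    prior_map = _as_prior_map(priors, names)
    rng = np.random.default_rng(config.seed)

    if log_likelihood is None:
        predictor = OneStepPredictor(model, data.grid, inputs)
        y_next = data.values[1:]
        m = y_next.size
        e2, b2 = noise_prior.eta2, noise_prior.beta2
        coef = 0.5 * m + e2

        def loglik(theta: np.ndarray) -> float:
            # only the theta-dependent part of log p(y|theta) is needed
            me = model_error(y_next, predictor.predict(theta, data.values))
            return -coef * math.log(me + 2.0 * b2)

    else:
        loglik = log_likelihood

    if init is None:
        theta = np.array([rng.gamma(prior_map[n].eta, prior_map[n].beta) for n in names])
    else:
        theta = np.asarray(init, dtype=float).copy()
        if theta.shape != (len(names),):
            raise ValueError("init must give one value per estimable parameter")
        if np.any(theta <= 0):
            raise ValueError("initial values must be strictly positive")

    p = len(names)
    samples = np.empty((config.n_iter, p))
    accepted = np.zeros((config.n_iter, p), dtype=bool)
    n_nonfinite = 0
    ll_cur = loglik(theta)

    def scalar_step(j: int, theta, ll_cur):
        nonlocal n_nonfinite
        cur = theta[j]
        star = propose(cur, proposal, rng)
        cand = theta.copy()
        cand[j] = star
        try:
            ll_star = loglik(cand)
            log_alpha = (
                ll_star
                - ll_cur
                + log_prior(star, prior_map[names[j]])
                - log_prior(cur, prior_map[names[j]])
                + log_proposal_ratio(cur, star, proposal)
            )
        except FloatingPointError:
            log_alpha = -math.inf
        if not math.isfinite(log_alpha):
            if log_alpha != -math.inf:
                n_nonfinite += 1
                logger.warning("non-finite MH log ratio at %s=%g; rejecting", names[j], star)
            return theta, ll_cur, False
        if math.log(rng.uniform()) <= log_alpha:
            return cand, ll_star, True
        return theta, ll_cur, False

    def joint_step(theta, ll_cur):
        nonlocal n_nonfinite
        cand = np.array([propose(theta[j], proposal, rng) for j in range(p)])
        try:
            ll_star = loglik(cand)
            log_alpha = ll_star - ll_cur
            for j, n in enumerate(names):
                log_alpha += (
                    log_prior(cand[j], prior_map[n])
                    - log_prior(theta[j], prior_map[n])
                    + log_proposal_ratio(theta[j], cand[j], proposal)
                )
        except FloatingPointError:
            log_alpha = -math.inf
        if not math.isfinite(log_alpha):
            if log_alpha != -math.inf:
                n_nonfinite += 1
                logger.warning("non-finite MH log ratio (joint move); rejecting")
            return theta, ll_cur, False
        if math.log(rng.uniform()) <= log_alpha:
            return cand, ll_star, True
        return theta, ll_cur, False

    for it in range(config.n_iter):
        if config.update_scheme == "componentwise":
            for j in range(p):
                theta, ll_cur, ok = scalar_step(j, theta, ll_cur)
                accepted[it, j] = ok
        else:
            theta, ll_cur, ok = joint_step(theta, ll_cur)
            accepted[it, :] = ok
        samples[it] = theta

    chain = Chain(
        param_names=names,
        samples=samples,
        accepted=accepted,
        config=config,
        n_nonfinite=n_nonfinite,
    )
    if not chain.accepted.any():
        logger.warning("chain accepted no proposals; estimates reflect the initial state")
    return chain


def mmse(
    chain: Chain,
    burn_in: int | None = None,
    q_levels: tuple[float, float] = (0.025, 0.975),
) -> PosteriorSummary:
    """Posterior mean (the MMSE estimate) and quantiles of the retained
    samples, per parameter."""
    kept = chain.retained(burn_in)
    means = kept.mean(axis=0)
    lo = np.quantile(kept, q_levels[0], axis=0)
    hi = np.quantile(kept, q_levels[1], axis=0)
    return PosteriorSummary(
        mmse=dict(zip(chain.param_names, means.tolist())),
        quantiles={n: (float(a), float(b)) for n, a, b in zip(chain.param_names, lo, hi)},
        n_retained=kept.shape[0],
        q_levels=q_levels,
    )
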