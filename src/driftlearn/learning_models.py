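"""Trial-level learning models and softmax decision rules.

Four models of how an agent updates its expectation of a noisy outcome:

* constant-rate delta rule (Rescorla-Wagner),
* asymmetric delta rule with separate rates for positive/negative
  prediction errors,
* Kalman filter, where the learning rate is the Bayesian gain implied by
  the agent's assumed drift variance (volatility), noise variance and
  prior uncertainty,
* RL/Pearce-Hall hybrid, where the learning rate is scaled by a dynamic
  associability term tracking recent absolute prediction errors.

Plus the softmax choice rule with either a constant inverse temperature
or one that follows a power function of the trial number.

All update functions are pure: they take a :class:`LearnerState` and
return a new one, touching only the observed option.  Trial indices are
1-based throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "RLParams",
    "AsymRLParams",
    "KalmanParams",
    "HybridParams",
    "SoftmaxParams",
    "DynamicSoftmaxParams",
    "LearnerState",
    "rl_update",
    "asym_rl_update",
    "kalman_gain",
    "kalman_update",
    "hybrid_update",
    "softmax_prob",
    "dynamic_beta",
    "transform_c",
    "steady_state_gain",
]


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class RLParams:
    """Constant learning rate ``alpha`` (unitless fraction)."""

    alpha: float

    def __post_init__(self) -> None:
        _check_unit("alpha", self.alpha)


@dataclass(frozen=True)
class AsymRLParams:
    """Separate learning rates after positive/negative prediction errors."""

    alpha_plus: float
    alpha_minus: float

    def __post_init__(self) -> None:
        _check_unit("alpha_plus", self.alpha_plus)
        _check_unit("alpha_minus", self.alpha_minus)


@dataclass(frozen=True)
class KalmanParams:
    """Kalman-filter learner parameters.

    ``drift_var`` (assumed random-walk variance of the latent mean) and
    ``init_prior_var`` (uncertainty before the first outcome) are
    expressed relative to the assumed outcome noise variance
    ``noise_var``, which is fixed at 1: only the ratios between the
    three variances are identifiable.
    """

    drift_var: float
    init_prior_var: float
    noise_var: float = 1.0

    def __post_init__(self) -> None:
        if self.drift_var < 0:
            raise ValueError("drift_var must be >= 0")
        if self.init_prior_var < 0:
            raise ValueError("init_prior_var must be >= 0")
        if self.noise_var != 1.0:
            raise ValueError("noise_var is fixed at 1 (only ratios matter)")


@dataclass(frozen=True)
class HybridParams:
    """RL/Pearce-Hall hybrid: initial associability, decay, rate scale."""

    assoc_init: float
    decay: float
    kappa: float

    def __post_init__(self) -> None:
        _check_unit("assoc_init", self.assoc_init)
        _check_unit("decay", self.decay)
        _check_unit("kappa", self.kappa)


@dataclass(frozen=True)
class SoftmaxParams:
    beta: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class DynamicSoftmaxParams:
    """Power-law inverse temperature: beta_t = theta * (t/10)**c.

    ``theta`` is the inverse temperature on trial 10; ``c`` in [-2, 2]
    sets the direction and speed of change over trials.
    """

    theta: float
    c: float

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not (-2.0 <= self.c <= 2.0):
            raise ValueError("c must lie in [-2, 2]")


@dataclass(frozen=True)
class LearnerState:
    """Per-option learner state.

    ``expectation`` holds E (delta-rule family) or the posterior mean mu
    (Kalman).  ``posterior_var`` is the Kalman prior variance for the
    *next* trial; ``associability`` is the Pearce-Hall alpha_t;
    ``last_pe`` is the most recent prediction error per option.
    """

    expectation: Mapping[str, float]
    posterior_var: Mapping[str, float] = field(default_factory=dict)
    associability: Mapping[str, float] = field(default_factory=dict)
    last_pe: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.posterior_var.values():
            if v < 0:
                raise ValueError("posterior_var must be >= 0")
        for v in self.associability.values():
            if v < 0:
                raise ValueError("associability must be >= 0")

    def _require(self, option: str) -> None:
        if option not in self.expectation:
            raise KeyError(f"unknown option {option!r}")


def _with(mapping: Mapping[str, float], key: str, value: float) -> dict:
    out = dict(mapping)
    out[key] = value
    return out


def rl_update(
    state: LearnerState, option: str, outcome: float, params: RLParams
) -> LearnerState:
    """Delta-rule update: E' = E + alpha * (outcome - E)."""
    state._require(option)
    pe = outcome - state.expectation[option]
    new_e = state.expectation[option] + params.alpha * pe
    return replace(
        state,
        expectation=_with(state.expectation, option, new_e),
        last_pe=_with(state.last_pe, option, pe),
    )


def asym_rl_update(
    state: LearnerState, option: str, outcome: float, params: AsymRLParams
) -> LearnerState:
    """Asymmetric delta rule: alpha+ for pe > 0, alpha- for pe < 0.

    A zero prediction error leaves the expectation unchanged under either
    branch; the positive branch is taken by convention.
    """
    state._require(option)
    pe = outcome - state.expectation[option]
    alpha = params.alpha_plus if pe >= 0 else params.alpha_minus
    new_e = state.expectation[option] + alpha * pe
    return replace(
        state,
        expectation=_with(state.expectation, option, new_e),
        last_pe=_with(state.last_pe, option, pe),
    )


def kalman_gain(posterior_var: float, noise_var: float = 1.0) -> float:
    """Bayesian learning rate s^2 / (noise_var + s^2), in [0, 1)."""
    if posterior_var < 0:
        raise ValueError("posterior_var must be >= 0")
    if noise_var <= 0:
        raise ValueError("noise_var must be > 0")
    return posterior_var / (noise_var + posterior_var)


def kalman_update(
    state: LearnerState, option: str, outcome: float, params: KalmanParams
) -> LearnerState:
    """Kalman-filter update of the posterior mean and variance.

    Ordering: gain from the current prior variance; mean moves by
    gain * pe; the variance contracts to s^2 * noise / (noise + s^2) and
    the drift variance is then added, so the stored variance is always
    the next trial's prior.
    """
    state._require(option)
    if option not in state.posterior_var:
        raise KeyError(f"no posterior variance tracked for option {option!r}")
    s2 = state.posterior_var[option]
    gain = kalman_gain(s2, params.noise_var)
    pe = outcome - state.expectation[option]
    new_mu = state.expectation[option] + gain * pe
    new_s2 = params.noise_var * s2 / (params.noise_var + s2) + params.drift_var
    return replace(
        state,
        expectation=_with(state.expectation, option, new_mu),
        posterior_var=_with(state.posterior_var, option, new_s2),
        last_pe=_with(state.last_pe, option, pe),
    )


def hybrid_update(
    state: LearnerState,
    option: str,
    outcome: float,
    params: HybridParams,
    pe_scale: float = 1.0,
) -> LearnerState:
    """RL/Pearce-Hall hybrid update.

    The effective learning rate is kappa * alpha_t, clipped to 1 to keep
    the update contractive (associability tracks |pe| in raw outcome
    points, so the product can exceed 1).  After the expectation update
    the associability decays toward |pe|:
    alpha_{t+1} = decay * |pe| / pe_scale + (1 - decay) * alpha_t.

    ``pe_scale`` (default 1: raw points) optionally normalizes the
    prediction error inside the associability update for sensitivity
    checks.
    """
    state._require(option)
    if option not in state.associability:
        raise KeyError(f"no associability tracked for option {option!r}")
    assoc = state.associability[option]
    pe = outcome - state.expectation[option]
    lr = min(1.0, params.kappa * assoc)
    new_e = state.expectation[option] + lr * pe
    new_assoc = params.decay * abs(pe) / pe_scale + (1.0 - params.decay) * assoc
    return replace(
        state,
        expectation=_with(state.expectation, option, new_e),
        associability=_with(state.associability, option, new_assoc),
        last_pe=_with(state.last_pe, option, pe),
    )


def softmax_prob(expectations: np.ndarray, beta: float) -> np.ndarray:
    """Softmax choice probabilities P_s = exp(beta*E_s) / sum exp(beta*E).

    Computed with max-subtraction so large beta * E never overflows.
    """
    e = np.asarray(expectations, dtype=float)
    if e.size < 2:
        raise ValueError("softmax needs at least two options")
    if not np.all(np.isfinite(e)):
        raise ValueError("expectations must be finite")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    z = beta * e
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def dynamic_beta(t: int, params: DynamicSoftmaxParams) -> float:
    """Inverse temperature on (1-based) trial t: theta * (t/10)**c."""
    if t < 1:
        raise ValueError("trial index is 1-based; t must be >= 1")
    return params.theta * (t / 10.0) ** params.c


def transform_c(c_raw: float) -> float:
    """Map the unit-interval consistency parameter to [-2, 2]: 4*c' - 2."""
    if not (0.0 <= c_raw <= 1.0):
        raise ValueError("c_raw must lie in [0, 1]")
    return 4.0 * c_raw - 2.0


def steady_state_gain(drift_var: float, noise_var: float = 1.0) -> float:
    """Asymptotic Kalman gain for given drift and noise variances.

    The variance recursion s' = noise*s/(noise+s) + drift has a unique
    nonnegative fixed point s* solving s^2 - drift*s - drift*noise = 0;
    the asymptotic gain is s*/(noise + s*).
    """
    if drift_var < 0:
        raise ValueError("drift_var must be >= 0")
    if noise_var <= 0:
        raise ValueError("noise_var must be > 0")
    s_star = 0.5 * (drift_var + math.sqrt(drift_var**2 + 4.0 * drift_var * noise_var))
    return s_star / (noise_var + s_star)
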