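"""Core game definitions for the iterated ultimatum game (IUG).

The IUG consists of ``T`` repetitions of a one-shot ultimatum: a *sender*
proposes a split of a unit endowment (the receiver would get ``a_S``, the
sender keeps ``1 - a_S``) and a *receiver* accepts (``a_R = 1``) or rejects
(``a_R = 0``) it; rejection yields zero to both.  Both agents carry a
threshold (``eta``), the minimal share they are willing to end up with, which
enters their utilities linearly:

    u_S = (1 - a_S - eta_S) * a_R
    u_R = (a_S - eta_R) * a_R

Offers live on a discrete, evenly spaced grid in [0, 1].  All agents choose
actions through a softmax policy with a shared, commonly known temperature.
This module holds the configuration object, the utility functions,
discounting, the softmax machinery (including the marginal policy of an agent
whose long-horizon Q-values are evaluated with noise), and the agent
specification used by the experiment runner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ACCEPT",
    "REJECT",
    "GameConfig",
    "AgentSpec",
    "sender_utility",
    "receiver_utility",
    "discounted_return",
    "softmax_probs",
    "softmax_policy",
    "softmax_sample",
    "noisy_softmax_probs",
    "greedy_action",
]

ACCEPT: int = 1
REJECT: int = 0

# Fixed standard-normal draws used to average the noisy-evaluation policy.
# A fixed seed keeps the marginal policy a deterministic function of the
# Q-vector (and therefore of history), which is what keeps nested beliefs
# common knowledge.
_NOISE_SEED = 173208
_noise_cache: dict[tuple[int, int], np.ndarray] = {}


def _noise_draws(n_samples: int, n_actions: int) -> np.ndarray:
    key = (n_samples, n_actions)
    if key not in _noise_cache:
        rng = np.random.default_rng(_NOISE_SEED)
        _noise_cache[key] = rng.standard_normal((n_samples, n_actions))
    return _noise_cache[key]


@dataclass(frozen=True)
class GameConfig:
    """Parameters of the iterated ultimatum game and of the agents' planners.

    Parameters
    ----------
    horizon
        Number of trials ``T`` (>= 1).
    discount
        Discount factor ``gamma`` in (0, 1] applied per trial.
    temperature
        Softmax temperature shared by every agent (> 0).
    grid_step
        Spacing of the offer grid; must divide 1 evenly.  The grid always
        contains 0.0 and 1.0.
    endowment
        Size of the endowment split each trial (fixed to 1.0).
    likelihood_floor
        Per-action floor applied to every policy likelihood before a Bayesian
        belief update, keeping posteriors proper when softmax probabilities
        underflow at low temperature.
    convergence_threshold
        Posterior mass that must be reached and sustained for a belief to
        count as converged on a type.
    branch_tol
        Probability below which opponent-action branches are pruned (and the
        remainder renormalised) inside planners.
    plan_noise
        Scale of the Gaussian Q-evaluation noise of the Monte-Carlo-tier
        planners (DoM(1) and DoM(2)); the per-trial standard deviation is
        ``plan_noise * horizon_weight(t) * (1 - eta)``, shrinking with the
        remaining horizon and with the agent's own reward scale.  Set to 0
        for exact planning.
    noise_samples
        Number of fixed normal draws used to average the noisy policy.
    belief_key_decimals
        Decimals used when quantising belief vectors for memoisation keys.
    state_abstraction_tol
        Posterior mass below which a type's nested simulation state is
        replaced by a placeholder in memoisation keys.
    """

    horizon: int = 12
    discount: float = 0.99
    temperature: float = 0.01
    grid_step: float = 0.1
    endowment: float = 1.0
    likelihood_floor: float = 1e-6
    convergence_threshold: float = 0.95
    branch_tol: float = 1e-4
    plan_noise: float = 0.02
    noise_samples: int = 256
    belief_key_decimals: int = 4
    state_abstraction_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if not 0.0 < self.discount <= 1.0:
            raise ValueError("discount must be in (0, 1]")
        if self.temperature <= 0.0:
            raise ValueError("temperature must be > 0")
        if self.endowment != 1.0:
            raise ValueError("only a unit endowment is supported")
        n = 1.0 / self.grid_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid_step must divide 1 evenly")
        if self.plan_noise < 0.0:
            raise ValueError("plan_noise must be >= 0")

    @cached_property
    def offers(self) -> tuple[float, ...]:
        """The offer grid: evenly spaced values from 0.0 to 1.0 inclusive."""
        n = round(1.0 / self.grid_step)
        return tuple(round(i * self.grid_step, 10) for i in range(n + 1))

    @property
    def n_offers(self) -> int:
        return len(self.offers)

    def value(self, idx: int) -> float:
        return self.offers[idx]

    def index(self, value: float) -> int:
        idx = round(value / self.grid_step)
        if not 0 <= idx < self.n_offers or abs(self.offers[idx] - value) > 1e-9:
            raise ValueError(f"offer {value!r} is not on the grid")
        return idx

    def cap_index(self, eta: float) -> int:
        """Largest grid index whose value does not exceed ``1 - eta``."""
        cap = min(1.0, max(0.0, 1.0 - eta))
        return min(self.n_offers - 1, int(math.floor(cap / self.grid_step + 1e-9)))

    def horizon_weight(self, t: int) -> float:
        """Discounted length of the lookahead remaining after trial ``t``.

        ``sum_{k=1}^{T-t} gamma^k`` — the scale of the continuation value a
        planner has to estimate at trial ``t``; used to scale plan noise.
        """
        g = self.discount
        m = max(0, self.horizon - t)
        if g == 1.0:
            return float(m)
        return g * (1.0 - g**m) / (1.0 - g)


@dataclass(frozen=True)
class AgentSpec:
    """Role, depth of mentalization and threshold of one agent.

    Senders occupy odd DoM levels (or the sub-intentional -1), receivers even
    ones.  ``is_random`` marks the uniform-random DoM(-1) sender, whose
    threshold is ignored.
    """

    role: str
    dom_level: int
    threshold: float = 0.0
    is_random: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("sender", "receiver"):
            raise ValueError("role must be 'sender' or 'receiver'")
        if self.role == "sender" and self.dom_level not in (-1, 1):
            raise ValueError("senders must have DoM level -1 or 1")
        if self.role == "receiver" and self.dom_level not in (0, 2):
            raise ValueError("receivers must have DoM level 0 or 2")
        if self.is_random and (self.role != "sender" or self.dom_level != -1):
            raise ValueError("only DoM(-1) senders can be random")
        if self.threshold < 0.0:
            raise ValueError("threshold must be >= 0")

    @classmethod
    def from_label(cls, role: str, label: str) -> "AgentSpec":
        """Parse labels like ``random``, ``thresh-0.5``, ``dom1-0.1``, ``dom0-0.35``."""
        if label == "random":
            return cls(role, -1, 0.0, is_random=True)
        try:
            kind, thr = label.rsplit("-", 1)
            threshold = float(thr)
        except ValueError as exc:
            raise ValueError(f"cannot parse agent label {label!r}") from exc
        levels = {"thresh": -1, "threshold": -1, "dom1": 1, "dom0": 0, "dom2": 2}
        if kind not in levels:
            raise ValueError(f"unknown agent kind {kind!r}")
        return cls(role, levels[kind], threshold)

    @property
    def label(self) -> str:
        if self.is_random:
            return "random"
        names = {-1: "thresh", 0: "dom0", 1: "dom1", 2: "dom2"}
        return f"{names[self.dom_level]}-{self.threshold}"


def sender_utility(offer: float, response: int, eta_s: float) -> float:
    """``(1 - a_S - eta_S) * a_R`` — the sender's per-trial reward."""
    return (1.0 - offer - eta_s) * response


def receiver_utility(offer: float, response: int, eta_r: float) -> float:
    """``(a_S - eta_R) * a_R`` — may be negative if an under-threshold offer
    is accepted."""
    return (offer - eta_r) * response


def discounted_return(rewards: Sequence[float], gamma: float) -> float:
    """``sum_t rewards[t] * gamma**(t-1)`` with rewards indexed from trial 1."""
    return float(sum(r * gamma**i for i, r in enumerate(rewards)))


def softmax_probs(q: np.ndarray, temperature: float) -> np.ndarray:
    """Softmax probabilities ``P(a) ∝ exp(Q(a)/T)``, computed in log space."""
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise ValueError("empty Q-vector")
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite Q-values: planner failure")
    z = q / temperature
    z = z - z.max()
    p = np.exp(z)
    return p / p.sum()


def noisy_softmax_probs(
    q: np.ndarray, temperature: float, sigma: float, n_samples: int = 256
) -> np.ndarray:
    """Marginal policy of an agent whose Q-values are evaluated with noise.

    The agent draws a private perturbation ``eps ~ N(0, sigma^2)`` per action
    and plays softmax on ``Q + eps``; the marginal over that perturbation,
    ``E_eps[softmax((Q + eps)/T)]``, is what an observer who cannot see the
    perturbation must invert.  Averaged over a fixed set of normal draws so
    the result is a deterministic function of ``Q``.
    """
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite Q-values: planner failure")
    if sigma == 0.0:
        return softmax_probs(q, temperature)
    noise = _noise_draws(n_samples, q.size)
    z = (q[None, :] + sigma * noise) / temperature
    z = z - z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    return p.mean(axis=0)


def softmax_policy(q_values: Mapping, temperature: float) -> dict:
    """Softmax policy over a Q-value mapping, keyed and ordered like it."""
    keys = sorted(q_values)
    qs = [q_values[k] for k in keys]
    if not qs:
        raise ValueError("empty Q-vector")
    if not all(math.isfinite(q) for q in qs):
        raise ValueError("non-finite Q-values: planner failure")
    m = max(qs)
    exps = [math.exp((q - m) / temperature) for q in qs]
    total = sum(exps)
    return {k: e / total for k, e in zip(keys, exps)}

def softmax_sample(q_values: Mapping, temperature: float, rng: np.random.Generator):
    """Sample an action from the softmax policy over ``q_values``."""
    policy = softmax_policy(q_values, temperature)
    keys = list(policy)
    return keys[rng.choice(len(keys), p=np.array(list(policy.values())))]


def greedy_action(q_values: Mapping):
    """Deterministic argmax with lowest-key tie-breaking (for reporting)."""
    keys = sorted(q_values)
    best = max(q_values[k] for k in keys)
    for k in keys:
        if q_values[k] == best:
            return k
    raise AssertionError("unreachable")
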