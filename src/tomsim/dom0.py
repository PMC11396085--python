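"""DoM(0) receiver: infers the DoM(-1) sender's type and plans by ExpectiMax.

The receiver models the sender as sub-intentional, with type space
{Random, threshold 0.1, threshold 0.5}.  Observing an offer it re-weights a
belief over those types by each type's policy likelihood (inverse RL), then
chooses accept/reject by finite-horizon ExpectiMax: the value of a response
is its immediate utility plus the discounted expectation, over the
belief-weighted predictive distribution of the sender's next offer, of the
best next response.  Rejection steers the reactive threshold senders' bounds
upward; the random sender is unaffected by responses, so against it the
policy collapses to the myopic threshold rule.

All planning works on immutable ``Dom0State`` values so the same planner
serves both the actual DoM(0) agent and the replicas nested inside DoM(1)
and DoM(2).
"""

from __future__ import annotations

import math
from typing import NamedTuple, Optional

import numpy as np

from .beliefs import bayes_update
from .game import (
    ACCEPT,
    REJECT,
    GameConfig,
    receiver_utility,
    softmax_probs,
)
from .subintentional import (
    BoundsState,
    initial_bounds,
    threshold_offer_policy,
    update_bounds,
)

__all__ = ["Dom0State", "Dom0Planner", "Dom0Receiver"]


class Dom0State(NamedTuple):
    """Belief over sender types plus the per-type simulated sender state.

    ``belief`` is ordered (random, threshold_1, threshold_2); ``bounds``
    holds the simulated :class:`BoundsState` of each threshold type,
    advanced along the realised history.
    """

    belief: tuple[float, ...]
    bounds: tuple[BoundsState, ...]


_PLACEHOLDER = BoundsState(-1, -1, False)


class Dom0Planner:
    """Exact finite-horizon ExpectiMax planner for the DoM(0) receiver.

    Stateless apart from its memo table: one instance per parameterisation
    (see :meth:`shared`) can back any number of agents and games.
    """

    _shared: dict = {}

    @classmethod
    def shared(
        cls,
        config: GameConfig,
        eta_r: float,
        sender_thresholds: tuple[float, ...] = (0.1, 0.5),
        plan_depth: Optional[int] = None,
    ) -> "Dom0Planner":
        key = (config, eta_r, sender_thresholds, plan_depth)
        if key not in cls._shared:
            cls._shared[key] = cls(config, eta_r, sender_thresholds, plan_depth)
        return cls._shared[key]

    def __init__(
        self,
        config: GameConfig,
        eta_r: float,
        sender_thresholds: tuple[float, ...] = (0.1, 0.5),
        plan_depth: Optional[int] = None,
    ):
        self.config = config
        self.eta_r = eta_r
        self.sender_thresholds = sender_thresholds
        self.plan_depth = plan_depth
        self.type_labels = ("random",) + tuple(
            f"thresh-{eta}" for eta in sender_thresholds
        )
        self._memo: dict = {}

    # -- state mechanics ---------------------------------------------------

    def initial_state(self) -> Dom0State:
        n = 1 + len(self.sender_thresholds)
        return Dom0State(
            belief=tuple(1.0 / n for _ in range(n)),
            bounds=tuple(initial_bounds(self.config) for _ in self.sender_thresholds),
        )

    def offer_likelihoods(self, state: Dom0State, offer: int) -> tuple[float, ...]:
        """Probability each sender type assigns to ``offer`` given history."""
        liks = [1.0 / self.config.n_offers]
        for eta, bounds in zip(self.sender_thresholds, state.bounds):
            policy = threshold_offer_policy(bounds, eta, self.config)
            liks.append(policy.get(offer, 0.0))
        return tuple(liks)

    def posterior_state(self, state: Dom0State, offer: int) -> Dom0State:
        """Belief updated with the likelihood of the just-observed offer."""
        post = bayes_update(
            state.belief,
            self.offer_likelihoods(state, offer),
            self.config.likelihood_floor,
        )
        return Dom0State(post, state.bounds)

    def advance(self, state: Dom0State, offer: int, response: int) -> Dom0State:
        """Advance the simulated sender bounds with a realised trial."""
        return Dom0State(
            state.belief,
            tuple(update_bounds(b, offer, response) for b in state.bounds),
        )

    def predictive_offers(self, state: Dom0State) -> dict[int, float]:
        """Belief-weighted next-offer distribution, pruned at ``branch_tol``."""
        mix: dict[int, float] = {}
        p_random = state.belief[0] / self.config.n_offers
        if p_random > 0.0:
            for a in range(self.config.n_offers):
                mix[a] = mix.get(a, 0.0) + p_random
        for w, eta, bounds in zip(
            state.belief[1:], self.sender_thresholds, state.bounds
        ):
            if w <= 0.0:
                continue
            for a, p in threshold_offer_policy(bounds, eta, self.config).items():
                mix[a] = mix.get(a, 0.0) + w * p
        tol = self.config.branch_tol
        kept = {a: p for a, p in mix.items() if p > tol}
        if not kept:
            kept = mix
        total = sum(kept.values())
        return {a: p / total for a, p in kept.items()}

    # -- planning ----------------------------------------------------------

    def _key(self, state: Dom0State, offer: int, t: int, depth: int):
        scale = 10.0**self.config.belief_key_decimals
        tol = self.config.state_abstraction_tol
        belief = tuple(int(b * scale + 0.5) for b in state.belief)
        bounds = tuple(
            b if w > tol else _PLACEHOLDER
            for w, b in zip(state.belief[1:], state.bounds)
        )
        return (belief, bounds, offer, t, depth)

    def q_values(
        self, state: Dom0State, offer: int, t: int, depth: Optional[int] = None
    ) -> tuple[float, float]:
        """(Q_reject, Q_accept) for the offer observed at trial ``t``.

        ``state`` must already incorporate the offer's belief update.
        ``depth`` limits the lookahead (receding horizon); by default the
        planner expands the exact remaining horizon.
        """
        remaining = self.config.horizon - t
        if remaining < 0:
            raise ValueError("trial index beyond the game horizon")
        if depth is None:
            depth = self.plan_depth
        depth = remaining if depth is None else min(depth, remaining)
        return self._q(state, offer, t, depth)

    def _q(self, state: Dom0State, offer: int, t: int, depth: int) -> tuple[float, float]:
        key = self._key(state, offer, t, depth)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        u_accept = receiver_utility(self.config.value(offer), ACCEPT, self.eta_r)
        if depth == 0:
            result = (0.0, u_accept)
        else:
            gamma = self.config.discount
            q = []
            for response in (REJECT, ACCEPT):
                nxt = self.advance(state, offer, response)
                cont = 0.0
                for next_offer, p in self.predictive_offers(nxt).items():
                    post = self.posterior_state(nxt, next_offer)
                    cont += p * max(self._q(post, next_offer, t + 1, depth - 1))
                q.append(u_accept * response + gamma * cont)
            result = (q[0], q[1])
        self._memo[key] = result
        return result

    def response_policy(
        self, state: Dom0State, offer: int, t: int, depth: Optional[int] = None
    ) -> tuple[float, float]:
        """(P_reject, P_accept): softmax over the ExpectiMax Q-values."""
        q_reject, q_accept = self.q_values(state, offer, t, depth)
        z = (q_reject - q_accept) / self.config.temperature
        if z > 700.0:
            return (1.0, 0.0)
        if z < -700.0:
            return (0.0, 1.0)
        e = math.exp(z)
        return (e / (1.0 + e), 1.0 / (1.0 + e))


class Dom0Receiver:
    """Stateful DoM(0) agent wrapping :class:`Dom0Planner` for game play."""

    role = "receiver"
    dom_level = 0

    def __init__(
        self,
        config: GameConfig,
        eta_r: float,
        sender_thresholds: tuple[float, ...] = (0.1, 0.5),
        plan_depth: Optional[int] = None,
    ):
        self.config = config
        self.eta_r = eta_r
        self.planner = Dom0Planner.shared(config, eta_r, sender_thresholds, plan_depth)
        self.state = self.planner.initial_state()

    def reset(self) -> None:
        self.state = self.planner.initial_state()

    @property
    def type_labels(self) -> tuple[str, ...]:
        return self.planner.type_labels

    def respond(self, offer: int, t: int, rng: np.random.Generator) -> int:
        self.state = self.planner.posterior_state(self.state, offer)
        q = self.planner.q_values(self.state, offer, t)
        p = softmax_probs(np.array(q), self.config.temperature)
        return int(rng.choice(2, p=p))

    def observe_outcome(self, offer: int, response: int, t: int) -> None:
        self.state = self.planner.advance(self.state, offer, response)

    def belief_snapshot(self) -> dict[str, float]:
        return dict(zip(self.planner.type_labels, self.state.belief))
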