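"""DoM(1) sender: manipulates the DoM(0) receiver's inference process.

The DoM(1) sender holds a belief over the receiver's threshold and — because
priors are flat and common knowledge and all actions are observed — an exact
replica of the DoM(0) receiver's own belief about the sender's type.  Its
Q-values plan *through* that nested belief: each candidate offer is
evaluated by simulating the belief update it would trigger in the receiver,
the receiver's induced response policy, and the game that follows.  Out of
this planning the hallmark deception emerges: early offers that a reactive
threshold sender would never make push the nested belief onto the Random
type, after which the receiver accepts anything clearing its threshold and
the sender defects to minimal offers.

Planning backends.  The exact backend expands the full belief tree
(memoised, with opponent branches pruned below ``branch_tol``).  On top of
it, action selection models a Monte-Carlo planner of the IPOMCP family: the
agent softmax-samples from Q-values corrupted by Gaussian evaluation noise
whose scale shrinks with the remaining horizon (``plan_noise`` in
:class:`~tomsim.game.GameConfig`).  Observers invert the *marginal* policy,
averaged over that noise, which is again a deterministic function of
history.  With ``plan_noise = 0`` the policy is the exact softmax.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np

from .beliefs import bayes_update
from .dom0 import Dom0Planner, Dom0State, _PLACEHOLDER
from .game import (
    ACCEPT,
    REJECT,
    GameConfig,
    noisy_softmax_probs,
    sender_utility,
)

__all__ = ["Dom1State", "Dom1Planner", "Dom1Sender"]


class Dom1State(NamedTuple):
    """Belief over receiver thresholds plus the shared DoM(0) replica."""

    belief_r: tuple[float, ...]
    dom0: Dom0State


class Dom1Planner:
    """Belief-tree planner for the DoM(1) sender.

    Planners are pure functions of immutable states plus a memo table, so a
    single instance can safely back any number of agents and games;
    :meth:`shared` hands out one memoised instance per parameterisation.
    """

    _shared: dict = {}

    @classmethod
    def shared(
        cls,
        config: GameConfig,
        eta_s: float,
        receiver_thresholds: tuple[float, ...] = (0.0, 0.35),
        plan_depth: Optional[int] = None,
        dom0_depth: Optional[int] = None,
    ) -> "Dom1Planner":
        key = (config, eta_s, receiver_thresholds, plan_depth, dom0_depth)
        if key not in cls._shared:
            cls._shared[key] = cls(
                config, eta_s, receiver_thresholds, plan_depth, dom0_depth
            )
        return cls._shared[key]

    def __init__(
        self,
        config: GameConfig,
        eta_s: float,
        receiver_thresholds: tuple[float, ...] = (0.0, 0.35),
        plan_depth: Optional[int] = None,
        dom0_depth: Optional[int] = None,
    ):
        self.config = config
        self.eta_s = eta_s
        self.receiver_thresholds = receiver_thresholds
        self.plan_depth = plan_depth
        self.dom0_depth = dom0_depth
        # One nested DoM(0) model per hypothesised receiver threshold; they
        # share a single Dom0State since the receiver's belief is a
        # deterministic function of the observed history.
        self.dom0 = tuple(
            Dom0Planner.shared(config, eta_r) for eta_r in receiver_thresholds
        )
        self._memo: dict = {}

    # -- state mechanics ---------------------------------------------------

    def initial_state(self) -> Dom1State:
        n = len(self.receiver_thresholds)
        return Dom1State(
            belief_r=tuple(1.0 / n for _ in range(n)),
            dom0=self.dom0[0].initial_state(),
        )

    def response_likelihoods(
        self, state: Dom1State, offer: int, response: int, t: int,
        dom0_depth: Optional[int] = None,
    ) -> tuple[float, ...]:
        """P(response | offer, eta_R) under each simulated DoM(0) receiver."""
        if dom0_depth is None:
            dom0_depth = self.dom0_depth
        post0 = self.dom0[0].posterior_state(state.dom0, offer)
        return tuple(
            planner.response_policy(post0, offer, t, dom0_depth)[response]
            for planner in self.dom0
        )

    def advance(
        self, state: Dom1State, offer: int, response: int, t: int,
        dom0_depth: Optional[int] = None,
    ) -> Dom1State:
        """Advance both belief levels with a realised trial."""
        liks = self.response_likelihoods(state, offer, response, t, dom0_depth)
        belief_r = bayes_update(state.belief_r, liks, self.config.likelihood_floor)
        post0 = self.dom0[0].posterior_state(state.dom0, offer)
        return Dom1State(belief_r, self.dom0[0].advance(post0, offer, response))

    # -- planning ----------------------------------------------------------

    def _key(self, state: Dom1State, t: int, depth: int):
        scale = 10.0**self.config.belief_key_decimals
        tol = self.config.state_abstraction_tol
        belief_r = tuple(int(b * scale + 0.5) for b in state.belief_r)
        belief0 = tuple(int(b * scale + 0.5) for b in state.dom0.belief)
        bounds = tuple(
            b if w > tol else _PLACEHOLDER
            for w, b in zip(state.dom0.belief[1:], state.dom0.bounds)
        )
        return (belief_r, belief0, bounds, t, depth)

    def q_values(
        self, state: Dom1State, t: int, depth: Optional[int] = None
    ) -> np.ndarray:
        """Q-vector over the full offer grid at trial ``t``.

        ``state`` is the sender's interactive state *before* making the
        trial-``t`` offer.  Each offer's value combines the expected
        immediate utility under the belief-weighted receiver response and
        the discounted value of the best next offer, planning through the
        receiver's belief dynamics.
        """
        remaining = self.config.horizon - t
        if remaining < 0:
            raise ValueError("trial index beyond the game horizon")
        if depth is None:
            depth = self.plan_depth
        depth = remaining if depth is None else min(depth, remaining)
        return self._q(state, t, depth)

    def _q(self, state: Dom1State, t: int, depth: int) -> np.ndarray:
        key = self._key(state, t, depth)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        gamma = self.config.discount
        tol = self.config.branch_tol
        q = np.empty(self.config.n_offers)
        for offer in range(self.config.n_offers):
            value = self.config.value(offer)
            post0 = self.dom0[0].posterior_state(state.dom0, offer)
            # Belief-weighted receiver response distribution.
            p_accept = 0.0
            per_type = []
            for w, planner in zip(state.belief_r, self.dom0):
                pol = planner.response_policy(post0, offer, t, self.dom0_depth)
                per_type.append(pol)
                p_accept += w * pol[ACCEPT]
            branches = [(REJECT, 1.0 - p_accept), (ACCEPT, p_accept)]
            branches = [(r, p) for r, p in branches if p > tol]
            total = sum(p for _, p in branches)
            q_offer = 0.0
            for response, p in branches:
                p /= total
                u = sender_utility(value, response, self.eta_s)
                if depth <= 0:
                    q_offer += p * u
                    continue
                # Posterior over receiver types given this response.
                liks = [pol[response] for pol in per_type]
                belief_r = bayes_update(
                    state.belief_r, liks, self.config.likelihood_floor
                )
                nxt = Dom1State(
                    belief_r, self.dom0[0].advance(post0, offer, response)
                )
                q_offer += p * (u + gamma * np.max(self._q(nxt, t + 1, depth - 1)))
            q[offer] = q_offer
        self._memo[key] = q
        return q

    def offer_policy(
        self, state: Dom1State, t: int, depth: Optional[int] = None
    ) -> np.ndarray:
        """Marginal offer distribution (noise-averaged softmax over Q).

        The evaluation-noise scale tracks the agent's own reward magnitude:
        a sender with threshold eta_S earns at most ``1 - eta_S`` per trial,
        and Monte-Carlo return noise scales with the returns themselves.
        """
        q = self.q_values(state, t, depth)
        sigma = (
            self.config.plan_noise
            * self.config.horizon_weight(t)
            * (1.0 - self.eta_s)
        )
        return noisy_softmax_probs(
            q, self.config.temperature, sigma, self.config.noise_samples
        )


class Dom1Sender:
    """Stateful DoM(1) agent wrapping :class:`Dom1Planner` for game play."""

    role = "sender"
    dom_level = 1

    def __init__(
        self,
        config: GameConfig,
        eta_s: float,
        receiver_thresholds: tuple[float, ...] = (0.0, 0.35),
        plan_depth: Optional[int] = None,
        dom0_depth: Optional[int] = None,
    ):
        self.config = config
        self.eta_s = eta_s
        self.planner = Dom1Planner.shared(
            config, eta_s, receiver_thresholds, plan_depth, dom0_depth
        )
        self.state = self.planner.initial_state()

    def reset(self) -> None:
        self.state = self.planner.initial_state()

    def act(self, t: int, rng: np.random.Generator) -> int:
        probs = self.planner.offer_policy(self.state, t)
        return int(rng.choice(self.config.n_offers, p=probs))

    def observe_outcome(self, offer: int, response: int, t: int) -> None:
        self.state = self.planner.advance(self.state, offer, response, t)

    def belief_snapshot(self) -> dict[str, float]:
        snap = {
            f"eta_r-{eta}": p
            for eta, p in zip(self.planner.receiver_thresholds, self.state.belief_r)
        }
        for label, p in zip(self.planner.dom0[0].type_labels, self.state.dom0.belief):
            snap[f"nested-dom0:{label}"] = p
        return snap
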