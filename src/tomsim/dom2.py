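"""DoM(2) receiver: counter-deception, and over-mentalizing against simpler
senders.

The DoM(2) receiver models the sender either as the uniform Random sender or
as a DoM(1) sender (threshold 0.1 or 0.5) complete with all of the DoM(1)'s
nested beliefs — its belief about the receiver's threshold and its replica
of the DoM(0) belief it thinks it is manipulating.  Reactive DoM(-1)
threshold senders are deliberately *absent* from this type space: the strict
cognitive hierarchy models the partner exactly one level below, and that
mis-specification is what produces the over-mentalizing phenotype.  Against
a true DoM(1) the same machinery supports counter-deception: a low-threshold
DoM(2) can reject low offers, masquerading as the high-threshold receiver
inside the DoM(1)'s inference, and so pressure the sender into better
offers.

Belief updates invert the marginal DoM(1) offer policy (see
:mod:`tomsim.dom1`) — the exact policy of the hypothesised noisy planner —
alongside the uniform Random policy.  Response planning expands a belief
tree like the DoM(0)'s, but the predictive offer distribution and the
belief dynamics inside the tree come from the nested DoM(1) models.  Nested
planning at every tree node is priced by two depth knobs: ``plan_depth``
(own receding planning horizon) and ``dom1_sim_depth`` (lookahead of the
DoM(1) models simulated inside the tree); the belief update against the
*realised* offer uses the deeper ``dom1_like_depth``.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np

from .beliefs import bayes_update
from .dom0 import _PLACEHOLDER
from .dom1 import Dom1Planner, Dom1State
from .game import (
    ACCEPT,
    REJECT,
    GameConfig,
    noisy_softmax_probs,
    receiver_utility,
)

__all__ = ["Dom2State", "Dom2Planner", "Dom2Receiver"]


class Dom2State(NamedTuple):
    """Belief over sender types plus the shared nested DoM(1) replica.

    ``belief_s`` is ordered (random, dom1_low, dom1_high).  A single
    :class:`Dom1State` serves every DoM(1) hypothesis: the nested belief
    about the receiver's threshold and the DoM(0) replica are deterministic
    functions of the observed history and do not depend on the DoM(1)'s own
    threshold.
    """

    belief_s: tuple[float, ...]
    dom1: Dom1State


class Dom2Planner:
    """Belief-tree planner for the DoM(2) receiver.

    Stateless apart from its memo table; :meth:`shared` hands out one
    memoised instance per parameterisation so repeated games reuse planning
    work.
    """

    _shared: dict = {}

    @classmethod
    def shared(cls, *args, **kwargs) -> "Dom2Planner":
        planner = cls(*args, **kwargs)
        key = (
            planner.config,
            planner.eta_r,
            planner.sender_thresholds,
            planner.dom1[0].receiver_thresholds,
            planner.plan_depth,
            planner.dom1_sim_depth,
            planner.dom1_like_depth,
            planner.dom0_depth,
        )
        if key not in cls._shared:
            cls._shared[key] = planner
        return cls._shared[key]

    def __init__(
        self,
        config: GameConfig,
        eta_r: float,
        sender_thresholds: tuple[float, ...] = (0.1, 0.5),
        receiver_thresholds: tuple[float, ...] = (0.0, 0.35),
        plan_depth: Optional[int] = 3,
        dom1_sim_depth: Optional[int] = 2,
        dom1_like_depth: Optional[int] = 6,
        dom0_depth: Optional[int] = None,
    ):
        self.config = config
        self.eta_r = eta_r
        self.sender_thresholds = sender_thresholds
        self.plan_depth = plan_depth
        self.dom1_sim_depth = dom1_sim_depth
        self.dom1_like_depth = dom1_like_depth
        self.dom0_depth = dom0_depth
        self.dom1 = tuple(
            Dom1Planner.shared(
                config, eta_s, receiver_thresholds, dom0_depth=dom0_depth
            )
            for eta_s in sender_thresholds
        )
        self.type_labels = ("random",) + tuple(
            f"dom1-{eta}" for eta in sender_thresholds
        )
        self._memo: dict = {}

    # -- state mechanics ---------------------------------------------------

    def initial_state(self) -> Dom2State:
        n = 1 + len(self.sender_thresholds)
        return Dom2State(
            belief_s=tuple(1.0 / n for _ in range(n)),
            dom1=self.dom1[0].initial_state(),
        )

    def offer_likelihoods(
        self, state: Dom2State, offer: int, t: int, dom1_depth: Optional[int] = None
    ) -> tuple[float, ...]:
        """Probability each sender type assigns to ``offer`` given history."""
        if dom1_depth is None:
            dom1_depth = self.dom1_like_depth
        liks = [1.0 / self.config.n_offers]
        for planner in self.dom1:
            policy = planner.offer_policy(state.dom1, t, dom1_depth)
            liks.append(float(policy[offer]))
        return tuple(liks)

    def posterior_state(
        self, state: Dom2State, offer: int, t: int, dom1_depth: Optional[int] = None
    ) -> Dom2State:
        post = bayes_update(
            state.belief_s,
            self.offer_likelihoods(state, offer, t, dom1_depth),
            self.config.likelihood_floor,
        )
        return Dom2State(post, state.dom1)

    def advance(
        self, state: Dom2State, offer: int, response: int, t: int,
        dom0_depth: Optional[int] = None,
    ) -> Dom2State:
        """Advance the nested DoM(1) replica with a realised trial."""
        nxt = self.dom1[0].advance(state.dom1, offer, response, t, dom0_depth)
        return Dom2State(state.belief_s, nxt)

    # -- planning ----------------------------------------------------------

    def _key(self, state: Dom2State, offer: int, t: int, depth: int):
        scale = 10.0**self.config.belief_key_decimals
        tol = self.config.state_abstraction_tol
        belief_s = tuple(int(b * scale + 0.5) for b in state.belief_s)
        if sum(state.belief_s[1:]) > tol:
            d1 = state.dom1
            belief_r = tuple(int(b * scale + 0.5) for b in d1.belief_r)
            belief0 = tuple(int(b * scale + 0.5) for b in d1.dom0.belief)
            bounds = tuple(
                b if w > tol else _PLACEHOLDER
                for w, b in zip(d1.dom0.belief[1:], d1.dom0.bounds)
            )
            nested = (belief_r, belief0, bounds)
        else:
            nested = None
        return (belief_s, nested, offer, t, depth)

    def _predictive_offers(self, state: Dom2State, t: int) -> dict[int, float]:
        """Belief-weighted next-offer mixture (Random + DoM(1) models)."""
        mix = np.full(
            self.config.n_offers, state.belief_s[0] / self.config.n_offers
        )
        for w, planner in zip(state.belief_s[1:], self.dom1):
            if w <= self.config.state_abstraction_tol:
                continue
            mix += w * planner.offer_policy(state.dom1, t, self.dom1_sim_depth)
        tol = self.config.branch_tol
        kept = {a: float(p) for a, p in enumerate(mix) if p > tol}
        if not kept:
            kept = {a: float(p) for a, p in enumerate(mix)}
        total = sum(kept.values())
        return {a: p / total for a, p in kept.items()}

    def q_values(
        self, state: Dom2State, offer: int, t: int, depth: Optional[int] = None
    ) -> tuple[float, float]:
        """(Q_reject, Q_accept) for the offer observed at trial ``t``.

        ``state`` must already incorporate the offer's belief update.
        Planning inside the tree simulates the DoM(1) models at
        ``dom1_sim_depth`` for both their future offers and the belief
        updates those offers would trigger.
        """
        remaining = self.config.horizon - t
        if remaining < 0:
            raise ValueError("trial index beyond the game horizon")
        if depth is None:
            depth = self.plan_depth
        depth = remaining if depth is None else min(depth, remaining)
        return self._q(state, offer, t, depth)

    def _q(self, state: Dom2State, offer: int, t: int, depth: int) -> tuple[float, float]:
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
                nxt = self.advance(state, offer, response, t, self.dom1_sim_depth)
                cont = 0.0
                for next_offer, p in self._predictive_offers(nxt, t + 1).items():
                    post = self.posterior_state(
                        nxt, next_offer, t + 1, self.dom1_sim_depth
                    )
                    cont += p * max(self._q(post, next_offer, t + 1, depth - 1))
                q.append(u_accept * response + gamma * cont)
            result = (q[0], q[1])
        self._memo[key] = result
        return result

    def response_policy(
        self, state: Dom2State, offer: int, t: int, depth: Optional[int] = None
    ) -> tuple[float, float]:
        """(P_reject, P_accept): marginal noisy-softmax over the Q-values."""
        q = self.q_values(state, offer, t, depth)
        sigma = (
            self.config.plan_noise
            * self.config.horizon_weight(t)
            * (1.0 - self.eta_r)
        )
        p = noisy_softmax_probs(
            np.array(q), self.config.temperature, sigma, self.config.noise_samples
        )
        return (float(p[0]), float(p[1]))


class Dom2Receiver:
    """Stateful DoM(2) agent wrapping :class:`Dom2Planner` for game play."""

    role = "receiver"
    dom_level = 2

    def __init__(
        self,
        config: GameConfig,
        eta_r: float,
        sender_thresholds: tuple[float, ...] = (0.1, 0.5),
        receiver_thresholds: tuple[float, ...] = (0.0, 0.35),
        plan_depth: Optional[int] = 3,
        dom1_sim_depth: Optional[int] = 2,
        dom1_like_depth: Optional[int] = 6,
        dom0_depth: Optional[int] = None,
    ):
        self.config = config
        self.eta_r = eta_r
        self.planner = Dom2Planner.shared(
            config,
            eta_r,
            sender_thresholds,
            receiver_thresholds,
            plan_depth,
            dom1_sim_depth,
            dom1_like_depth,
            dom0_depth,
        )
        self.state = self.planner.initial_state()

    def reset(self) -> None:
        self.state = self.planner.initial_state()

    @property
    def type_labels(self) -> tuple[str, ...]:
        return self.planner.type_labels

    def respond(self, offer: int, t: int, rng: np.random.Generator) -> int:
        self.state = self.planner.posterior_state(self.state, offer, t)
        p = self.planner.response_policy(self.state, offer, t)
        return int(rng.choice(2, p=np.array(p)))

    def observe_outcome(self, offer: int, response: int, t: int) -> None:
        self.state = self.planner.advance(self.state, offer, response, t)

    def belief_snapshot(self) -> dict[str, float]:
        snap = dict(zip(self.planner.type_labels, self.state.belief_s))
        d1 = self.state.dom1
        for eta, p in zip(self.planner.dom1[0].receiver_thresholds, d1.belief_r):
            snap[f"nested-dom1:eta_r-{eta}"] = p
        for label, p in zip(self.planner.dom1[0].dom0[0].type_labels, d1.dom0.belief):
            snap[f"nested-dom0:{label}"] = p
        return snap
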