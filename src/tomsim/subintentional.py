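"""Sub-intentional DoM(-1) senders: uniform-random and reactive threshold.

The threshold sender has no opponent model.  It keeps a lower and an upper
bound on the offers worth considering and updates them mechanically from the
last trial:

    L_t = L_{t-1} * a_R + a_S * (1 - a_R)        (a rejected offer becomes L)
    U_t = U_{t-1} * (1 - a_R) + a_S * a_R        (an accepted offer becomes U)

with L_0 = 0, U_0 = 1.  Its Q-value for a feasible offer is just the utility
it would collect if the offer were accepted, Q(a) = 1 - a - eta_S, so under a
low softmax temperature it greedily makes the smallest feasible offer.  Once
any offer has been rejected the lower bound is itself a rejected offer and is
excluded (the interval is half-open, (L, U]); offers are capped at
1 - eta_S, above which the sender's utility would be negative.  The combined
rule yields the characteristic one-grid-step-per-rejection ladder that
plateaus at 1 - eta_S.
"""

from __future__ import annotations

from functools import lru_cache
from typing import NamedTuple, Optional

import numpy as np

from .game import ACCEPT, REJECT, GameConfig, softmax_policy, softmax_sample

__all__ = [
    "BoundsState",
    "initial_bounds",
    "update_bounds",
    "feasible_offers",
    "threshold_sender_q",
    "threshold_offer_policy",
    "random_offer_policy",
    "RandomSender",
    "ThresholdSender",
]


class BoundsState(NamedTuple):
    """Offer bounds of the reactive threshold sender, as grid indices.

    ``rejected`` records whether any offer has been rejected yet, i.e.
    whether ``lower`` is itself a rejected offer (and hence excluded).
    """

    lower: int
    upper: int
    rejected: bool = False


def initial_bounds(config: GameConfig) -> BoundsState:
    return BoundsState(0, config.n_offers - 1, False)


def update_bounds(bounds: BoundsState, offer: int, response: int) -> BoundsState:
    """Advance the bounds with the realised (offer, response) of one trial."""
    if response == ACCEPT:
        return BoundsState(bounds.lower, offer, bounds.rejected)
    return BoundsState(offer, bounds.upper, True)


def feasible_offers(bounds: BoundsState, eta_s: float, config: GameConfig) -> tuple[int, ...]:
    """Grid indices the threshold sender considers.

    The intersection of (L, U] (or [L, U] before any rejection) with
    [0, 1 - eta_S].  Never empty: if the rule empties the set the nearest
    feasible grid point is returned alone, so the sender always has a move.
    """
    cap = config.cap_index(eta_s)
    lo = bounds.lower + 1 if bounds.rejected else bounds.lower
    hi = min(bounds.upper, cap)
    if lo > hi:
        return (min(bounds.lower, cap),)
    return tuple(range(lo, hi + 1))


def threshold_sender_q(offers: tuple[int, ...], eta_s: float, config: GameConfig) -> dict[int, float]:
    """Q(a) = 1 - a - eta_S: the utility if the offer were accepted."""
    return {a: 1.0 - config.value(a) - eta_s for a in offers}


@lru_cache(maxsize=None)
def _cached_threshold_policy(
    bounds: BoundsState, eta_s: float, config: GameConfig
) -> dict[int, float]:
    q = threshold_sender_q(feasible_offers(bounds, eta_s, config), eta_s, config)
    return softmax_policy(q, config.temperature)


def threshold_offer_policy(bounds: BoundsState, eta_s: float, config: GameConfig) -> dict[int, float]:
    """Softmax policy of the threshold sender given its bounds.

    Cached — the distinct (bounds, threshold) pairs of a game are few and
    the planners query them millions of times.  Treat the returned mapping
    as read-only.
    """
    return _cached_threshold_policy(bounds, eta_s, config)


def random_offer_policy(config: GameConfig) -> dict[int, float]:
    """Uniform policy over the full grid; independent of history."""
    p = 1.0 / config.n_offers
    return {a: p for a in range(config.n_offers)}


class RandomSender:
    """DoM(-1) sender making uniformly random offers, ignoring all history."""

    role = "sender"

    def __init__(self, config: GameConfig):
        self.config = config

    def reset(self) -> None:
        pass

    def act(self, t: int, rng: np.random.Generator) -> int:
        return int(rng.integers(self.config.n_offers))

    def observe_outcome(self, offer: int, response: int, t: int) -> None:
        pass

    def belief_snapshot(self) -> Optional[dict[str, float]]:
        return None


class ThresholdSender:
    """Reactive, myopic DoM(-1) sender with moving offer bounds."""

    role = "sender"

    def __init__(self, config: GameConfig, eta_s: float):
        self.config = config
        self.eta_s = eta_s
        self.bounds = initial_bounds(config)

    def reset(self) -> None:
        self.bounds = initial_bounds(self.config)

    def act(self, t: int, rng: np.random.Generator) -> int:
        q = threshold_sender_q(
            feasible_offers(self.bounds, self.eta_s, self.config), self.eta_s, self.config
        )
        return softmax_sample(q, self.config.temperature, rng)

    def observe_outcome(self, offer: int, response: int, t: int) -> None:
        self.bounds = update_bounds(self.bounds, offer, response)

    def belief_snapshot(self) -> Optional[dict[str, float]]:
        return None
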