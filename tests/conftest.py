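"""Shared fixtures and independent brute-force oracles.

The oracles re-derive the planners' quantities from first principles —
explicit enumeration of every offer/response path with inline Bayes rule and
inline threshold-sender simulation — so they share no planning code with the
implementation they check.
"""

from __future__ import annotations

import math

import pytest

from tomsim import GameConfig

ACCEPT, REJECT = 1, 0


@pytest.fixture(scope="session")
def config() -> GameConfig:
    """The study configuration: T=12, gamma=0.99, temperature=0.01."""
    return GameConfig()


@pytest.fixture(scope="session")
def exact_tiny_config() -> GameConfig:
    """Tiny exact-planning setup for oracle equivalence: T=3, 3-point grid."""
    return GameConfig(
        horizon=3,
        grid_step=0.5,
        plan_noise=0.0,
        belief_key_decimals=12,
        state_abstraction_tol=0.0,
        branch_tol=0.0,
    )


# ---------------------------------------------------------------------------
# Independent re-implementations used as oracles.


def oracle_softmax(qs: list[float], temperature: float) -> list[float]:
    m = max(qs)
    es = [math.exp((q - m) / temperature) for q in qs]
    s = sum(es)
    return [e / s for e in es]


def oracle_threshold_policy(
    lower: int, upper: int, rejected: bool, eta: float, cfg: GameConfig
) -> dict[int, float]:
    """Threshold-sender softmax policy derived directly from the rules."""
    grid = cfg.offers
    cap = max(i for i, v in enumerate(grid) if v <= 1.0 - eta + 1e-9)
    lo = lower + 1 if rejected else lower
    hi = min(upper, cap)
    feasible = list(range(lo, hi + 1)) if lo <= hi else [min(lower, cap)]
    qs = [1.0 - grid[a] - eta for a in feasible]
    probs = oracle_softmax(qs, cfg.temperature)
    return dict(zip(feasible, probs))


def oracle_bounds_step(state: tuple, offer: int, response: int) -> tuple:
    lower, upper, rejected = state
    if response == ACCEPT:
        return (lower, offer, rejected)
    return (offer, upper, True)


def oracle_dom0_posterior(
    belief: list[float], bounds: list[tuple], offer: int, eta_s: tuple, cfg: GameConfig
) -> list[float]:
    liks = [1.0 / cfg.n_offers]
    for eta, b in zip(eta_s, bounds):
        liks.append(oracle_threshold_policy(*b, eta, cfg).get(offer, 0.0))
    post = [p * max(l, cfg.likelihood_floor) for p, l in zip(belief, liks)]
    s = sum(post)
    return [x / s for x in post]


def oracle_dom0_q(
    belief: list[float],
    bounds: list[tuple],
    offer: int,
    t: int,
    eta_r: float,
    eta_s: tuple,
    cfg: GameConfig,
) -> tuple[float, float]:
    """Exhaustive ExpectiMax over every future offer/response path.

    ``belief`` must already be the posterior given ``offer``.
    """
    u_accept = cfg.value(offer) - eta_r
    if t == cfg.horizon:
        return (0.0, u_accept)
    out = []
    for response in (REJECT, ACCEPT):
        nxt_bounds = [oracle_bounds_step(b, offer, response) for b in bounds]
        cont = 0.0
        for next_offer in range(cfg.n_offers):
            # predictive probability of the next offer
            p = belief[0] / cfg.n_offers
            for w, eta, b in zip(belief[1:], eta_s, nxt_bounds):
                p += w * oracle_threshold_policy(*b, eta, cfg).get(next_offer, 0.0)
            if p == 0.0:
                continue
            post = oracle_dom0_posterior(belief, nxt_bounds, next_offer, eta_s, cfg)
            cont += p * max(
                oracle_dom0_q(post, nxt_bounds, next_offer, t + 1, eta_r, eta_s, cfg)
            )
        out.append(u_accept * response + cfg.discount * cont)
    return (out[0], out[1])


def oracle_dom1_q(
    belief_r: list[float],
    dom0_belief: list[float],
    bounds: list[tuple],
    t: int,
    eta_s_self: float,
    eta_r_space: tuple,
    eta_s_space: tuple,
    cfg: GameConfig,
) -> list[float]:
    """Exhaustive DoM(1) Q-values, planning through the DoM(0) belief update."""
    qs = []
    for offer in range(cfg.n_offers):
        value = cfg.value(offer)
        post0 = oracle_dom0_posterior(dom0_belief, bounds, offer, eta_s_space, cfg)
        pol = [
            oracle_softmax(
                list(oracle_dom0_q(post0, bounds, offer, t, eta_r, eta_s_space, cfg)),
                cfg.temperature,
            )
            for eta_r in eta_r_space
        ]
        q = 0.0
        for response in (REJECT, ACCEPT):
            p_r = sum(w * pol[i][response] for i, w in enumerate(belief_r))
            if p_r == 0.0:
                continue
            u = (1.0 - value - eta_s_self) * response
            if t == cfg.horizon:
                q += p_r * u
                continue
            liks = [pol[i][response] for i in range(len(eta_r_space))]
            floored = [max(l, cfg.likelihood_floor) for l in liks]
            tot = sum(w * f for w, f in zip(belief_r, floored))
            belief_r_next = [w * f / tot for w, f in zip(belief_r, floored)]
            bounds_next = [oracle_bounds_step(b, offer, response) for b in bounds]
            cont = max(
                oracle_dom1_q(
                    belief_r_next,
                    post0,
                    bounds_next,
                    t + 1,
                    eta_s_self,
                    eta_r_space,
                    eta_s_space,
                    cfg,
                )
            )
            q += p_r * (u + cfg.discount * cont)
        qs.append(q)
    return qs
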