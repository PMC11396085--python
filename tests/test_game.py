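"""Core game machinery: utilities, discounting, softmax, configuration."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tomsim import (
    ACCEPT,
    REJECT,
    AgentSpec,
    GameConfig,
    discounted_return,
    noisy_softmax_probs,
    receiver_utility,
    sender_utility,
    softmax_policy,
    softmax_probs,
    softmax_sample,
)


@pytest.mark.parametrize(
    "offer, response, eta, expected",
    [
        (0.3, ACCEPT, 0.1, 0.6),
        (0.9, REJECT, 0.5, 0.0),
        (0.5, ACCEPT, 0.5, 0.0),
    ],
)
def test_sender_utility(offer, response, eta, expected):
    assert sender_utility(offer, response, eta) == pytest.approx(expected)


@pytest.mark.parametrize(
    "offer, response, eta, expected",
    [
        (0.3, ACCEPT, 0.0, 0.3),
        (0.3, REJECT, 0.0, 0.0),
        (0.35, ACCEPT, 0.35, 0.0),
    ],
)
def test_receiver_utility(offer, response, eta, expected):
    assert receiver_utility(offer, response, eta) == pytest.approx(expected)


@given(
    offer=st.floats(0, 1),
    eta=st.floats(0, 0.9),
)
def test_rejection_zeroes_both_utilities(offer, eta):
    assert sender_utility(offer, REJECT, eta) == 0.0
    assert receiver_utility(offer, REJECT, eta) == 0.0


@pytest.mark.parametrize(
    "rewards, gamma, expected",
    [
        ([1, 1], 1.0, 2.0),
        ([5], 0.3, 5.0),
        ([1, 1], 0.99, 1.99),
        ([], 0.99, 0.0),
    ],
)
def test_discounted_return_examples(rewards, gamma, expected):
    assert discounted_return(rewards, gamma) == pytest.approx(expected)


@given(st.lists(st.floats(-1, 1), max_size=12))
def test_discounted_return_gamma_one_is_plain_sum(rewards):
    assert discounted_return(rewards, 1.0) == pytest.approx(sum(rewards))


def test_discounting_weighs_early_rewards_more():
    """Moving a reward to a later trial cannot increase the return."""
    assert discounted_return([1, 0, 0], 0.9) > discounted_return([0, 0, 1], 0.9)


def test_softmax_uniform_for_equal_q():
    p = softmax_probs(np.zeros(7), 0.01)
    assert np.allclose(p, 1 / 7)


def test_softmax_logistic_value():
    """Q = [0, 0.1] at temperature 0.01: P(second) = 1/(1+exp(-10))."""
    p = softmax_probs(np.array([0.0, 0.1]), 0.01)
    assert p[1] == pytest.approx(1.0 / (1.0 + math.exp(-10.0)))


def test_softmax_low_temperature_limit_selects_argmax():
    p = softmax_probs(np.array([0.0, 0.1, 0.05]), 1e-5)
    assert p[1] == pytest.approx(1.0, abs=1e-12)


@given(
    st.lists(st.floats(-50, 50), min_size=1, max_size=11),
    st.sampled_from([0.01, 0.1, 1.0]),
)
@settings(max_examples=200)
def test_softmax_probabilities_normalise(qs, temperature):
    p = softmax_probs(np.array(qs), temperature)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    assert (p >= 0).all()
    d = softmax_policy(dict(enumerate(qs)), temperature)
    assert sum(d.values()) == pytest.approx(1.0, abs=1e-12)


def test_softmax_rejects_non_finite_q():
    with pytest.raises(ValueError):
        softmax_probs(np.array([0.0, np.nan]), 0.01)
    with pytest.raises(ValueError):
        softmax_policy({0: float("inf"), 1: 0.0}, 0.01)


def test_noisy_softmax_normalises_and_reduces_to_softmax():
    q = np.array([0.1, 0.3, 0.2])
    assert noisy_softmax_probs(q, 0.01, 0.0).tolist() == pytest.approx(
        softmax_probs(q, 0.01).tolist()
    )
    q = np.array([0.0, 0.5, 0.1])
    p = noisy_softmax_probs(q, 0.01, 0.2)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    # noise spreads mass onto near-optimal actions but keeps the ordering
    # of well-separated ones
    assert p.argmax() == 1 and p.min() > 0.0


def test_softmax_sample_is_reproducible():
    q = {0.0: 0.0, 0.1: 0.05, 0.2: 0.02}
    draws1 = [softmax_sample(q, 0.1, np.random.default_rng(5)) for _ in range(3)]
    draws2 = [softmax_sample(q, 0.1, np.random.default_rng(5)) for _ in range(3)]
    assert draws1 == draws2


def test_config_grid_and_validation():
    cfg = GameConfig()
    assert cfg.offers[0] == 0.0 and cfg.offers[-1] == 1.0
    assert len(cfg.offers) == 11
    steps = np.diff(cfg.offers)
    assert np.allclose(steps, 0.1)
    assert cfg.cap_index(0.5) == cfg.index(0.5)
    with pytest.raises(ValueError):
        GameConfig(horizon=0)
    with pytest.raises(ValueError):
        GameConfig(temperature=0.0)
    with pytest.raises(ValueError):
        GameConfig(grid_step=0.3)
    with pytest.raises(ValueError):
        GameConfig(discount=1.5)


def test_horizon_weight_counts_discounted_remaining_trials():
    cfg = GameConfig(horizon=3, discount=0.5)
    assert cfg.horizon_weight(1) == pytest.approx(0.5 + 0.25)
    assert cfg.horizon_weight(3) == 0.0


def test_agent_spec_roles_and_labels():
    assert AgentSpec.from_label("sender", "random").is_random
    spec = AgentSpec.from_label("sender", "thresh-0.5")
    assert spec.dom_level == -1 and spec.threshold == 0.5
    assert AgentSpec.from_label("receiver", "dom2-0.35").dom_level == 2
    with pytest.raises(ValueError):
        AgentSpec("sender", 0)  # senders have odd DoM
    with pytest.raises(ValueError):
        AgentSpec("receiver", 1)  # receivers have even DoM
    with pytest.raises(ValueError):
        AgentSpec("receiver", 0, is_random=True)
    with pytest.raises(ValueError):
        AgentSpec.from_label("sender", "nonsense")
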