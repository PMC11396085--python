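"""DoM(2) receiver: counter-deception and the over-mentalizing trap."""

from __future__ import annotations

import numpy as np
import pytest

from tomsim import REJECT, Dom2Planner, GameConfig, run_game


@pytest.fixture(scope="module")
def cfg():
    return GameConfig()


@pytest.fixture(scope="module")
def vs_threshold(cfg):
    """DoM(2) and DoM(0) receivers vs the same DoM(-1) threshold senders."""
    out = {}
    for eta_s in (0.1, 0.5):
        out[eta_s] = [
            (
                run_game((f"thresh-{eta_s}", "dom2-0.0"), cfg, seed),
                run_game((f"thresh-{eta_s}", "dom0-0.0"), cfg, seed),
            )
            for seed in range(3)
        ]
    return out


@pytest.fixture(scope="module")
def vs_dom1(cfg):
    out = {}
    for eta_s in (0.1, 0.5):
        out[eta_s] = [
            (
                run_game((f"dom1-{eta_s}", "dom2-0.0"), cfg, seed),
                run_game((f"dom1-{eta_s}", "dom0-0.0"), cfg, seed),
            )
            for seed in range(3)
        ]
    return out


def test_certain_random_reduces_to_threshold_rule(cfg):
    """With the belief pinned on Random there is no opponent to manipulate:
    accept exactly the offers clearing the threshold, as DoM(0) would."""
    planner = Dom2Planner(cfg, 0.0)
    state = planner.initial_state()._replace(belief_s=(1.0, 0.0, 0.0))
    for offer in range(cfg.n_offers):
        q_rej, q_acc = planner.q_values(state, offer, t=6)
        margin = cfg.value(offer)
        if margin > 1e-9:
            assert q_acc > q_rej
        else:
            assert q_acc == pytest.approx(q_rej, abs=1e-9)


def test_horizon_one_is_myopic(cfg):
    planner = Dom2Planner(cfg, 0.35)
    state = planner.initial_state()
    q = planner.q_values(state, cfg.index(0.2), t=cfg.horizon)
    assert q == pytest.approx((0.0, 0.2 - 0.35))


def test_threshold_sender_read_as_random(cfg, vs_threshold):
    """Repeated minimal offers lie outside the DoM(1) opponent model, so the
    over-mentalizing receiver attributes them to the Random sender."""
    for eta_s, pairs in vs_threshold.items():
        for dom2_records, _ in pairs:
            assert dom2_records[0].receiver_beliefs["random"] > 0.9


def test_overmentalizing_costs_reward(cfg, vs_threshold):
    """Cumulative reward of DoM(2) is strictly below DoM(0)'s against the
    same DoM(-1) threshold sender and seed."""
    for eta_s, pairs in vs_threshold.items():
        for dom2_records, dom0_records in pairs:
            r2 = sum(r.receiver_reward for r in dom2_records)
            r0 = sum(r.receiver_reward for r in dom0_records)
            assert r2 < r0


def test_self_confirming_beliefs(cfg, vs_threshold):
    """Once the DoM(2) stops rejecting, the reactive sender's offers never
    increase — the receiver never generates disconfirming evidence."""
    for eta_s, pairs in vs_threshold.items():
        for dom2_records, _ in pairs:
            last_reject = max(
                (r.trial for r in dom2_records if r.response == REJECT), default=0
            )
            tail = [r.offer for r in dom2_records if r.trial > last_reject]
            assert all(b <= a + 1e-9 for a, b in zip(tail, tail[1:]))


def test_counter_deception_improves_on_dom0(cfg, vs_dom1):
    """Vs the DoM(1), the DoM(2) receiver lowers the sender's advantage:
    its reward ratio beats the DoM(0)'s on the same seeds."""
    for eta_s, pairs in vs_dom1.items():
        for dom2_records, dom0_records in pairs:
            def ratio(records):
                s = sum(r.sender_reward for r in records)
                return sum(r.receiver_reward for r in records) / s if s else np.inf
            assert ratio(dom2_records) > ratio(dom0_records)


def test_masquerade_raises_offers_of_high_threshold_dom1(cfg, vs_dom1):
    """The low-threshold DoM(2) rejects early low offers, pushing the
    eta_S=0.5 DoM(1)'s belief toward the 0.35 receiver and its offers up."""
    saw_masquerade = False
    for dom2_records, _ in vs_dom1[0.5]:
        early_rejects = [r for r in dom2_records[:4] if r.response == REJECT]
        if early_rejects:
            saw_masquerade = True
            late = [r.offer for r in dom2_records[-4:]]
            assert np.mean(late) >= 0.3
    assert saw_masquerade


def test_nested_dom1_model_is_the_shared_planner(cfg):
    """Single source of truth: the DoM(2)'s likelihood model of the DoM(1)
    is the very planner instance that drives the DoM(1) agent."""
    from tomsim.dom1 import Dom1Sender

    dom2 = Dom2Planner.shared(cfg, 0.0)
    sender = Dom1Sender(cfg, 0.5)
    assert dom2.dom1[1] is sender.planner
    state = sender.planner.initial_state()
    np.testing.assert_allclose(
        dom2.dom1[1].offer_policy(state, 1),
        sender.planner.offer_policy(state, 1),
    )


def test_delayed_random_identification(cfg):
    """Mean convergence onto the Random type is slower for DoM(2) than for
    DoM(0) against the true random sender."""
    from tomsim import convergence_trial

    def mean_conv(receiver):
        trials = []
        for seed in range(6):
            records = run_game(("random", receiver), cfg, seed)
            labels = list(records[0].receiver_beliefs)
            traj = [[r.receiver_beliefs[k] for k in labels] for r in records]
            c = convergence_trial(traj, labels.index("random"), 0.95)
            trials.append(c if c is not None else cfg.horizon + 1)
        return np.mean(trials)

    assert mean_conv("dom2-0.0") > mean_conv("dom0-0.0")
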