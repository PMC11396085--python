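"""Game engine, dyad runner, seeded sweeps, summaries and serialization.

A *dyad* pairs one sender with one receiver.  ``run_game`` plays the full
iterated ultimatum game for a dyad and returns per-trial records (offers,
responses, rewards, belief snapshots); ``run_experiment`` repeats that over
dyads and seeds and tabulates per-run summaries.  Reproducibility contract:
each agent draws from its own RNG stream seeded from (run seed, role), so a
(dyad, seed) pair always reproduces the identical game.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .beliefs import convergence_trial
from .dom0 import Dom0Receiver
from .dom1 import Dom1Sender
from .dom2 import Dom2Receiver
from .game import (
    AgentSpec,
    GameConfig,
    discounted_return,
    receiver_utility,
    sender_utility,
)
from .subintentional import RandomSender, ThresholdSender

__all__ = [
    "TrialRecord",
    "make_agent",
    "run_game",
    "run_experiment",
    "summarize_experiment",
    "reward_ratio",
    "records_to_frame",
    "export_records",
    "STUDY_SENDERS",
    "STUDY_RECEIVERS",
]

#: Sender/receiver labels of the full experimental grid.
STUDY_SENDERS = ("random", "thresh-0.1", "thresh-0.5", "dom1-0.1", "dom1-0.5")
STUDY_RECEIVERS = ("dom0-0.0", "dom0-0.35", "dom2-0.0", "dom2-0.35")


@dataclass
class TrialRecord:
    """One trial of one game: actions, rewards and belief snapshots."""

    trial: int
    offer: float
    response: int
    sender_reward: float
    receiver_reward: float
    sender_beliefs: Optional[dict] = None
    receiver_beliefs: Optional[dict] = None


def make_agent(spec: AgentSpec, config: GameConfig):
    """Instantiate the agent described by ``spec``.

    Under high decision noise (temperature >= 0.5) deep lookahead is
    noise-dominated and the exact belief tree no longer collapses, so the
    intentional agents fall back to a short receding planning horizon.
    """
    high_temp = config.temperature >= 0.5
    depth = 2 if high_temp else None
    if spec.role == "sender":
        if spec.dom_level == -1:
            if spec.is_random:
                return RandomSender(config)
            return ThresholdSender(config, spec.threshold)
        return Dom1Sender(
            config, spec.threshold, plan_depth=depth, dom0_depth=depth
        )
    if spec.dom_level == 0:
        return Dom0Receiver(config, spec.threshold, plan_depth=depth)
    return Dom2Receiver(
        config,
        spec.threshold,
        plan_depth=2 if high_temp else 3,
        dom1_sim_depth=2,
        dom1_like_depth=2 if high_temp else 6,
        dom0_depth=depth,
    )


def _as_spec(agent: Union[AgentSpec, str], role: str) -> AgentSpec:
    if isinstance(agent, AgentSpec):
        return agent
    return AgentSpec.from_label(role, agent)


def run_game(
    dyad: tuple[Union[AgentSpec, str], Union[AgentSpec, str]],
    config: GameConfig,
    seed: int,
) -> list[TrialRecord]:
    """Play one full game of ``config.horizon`` trials and record it."""
    sender_spec = _as_spec(dyad[0], "sender")
    receiver_spec = _as_spec(dyad[1], "receiver")
    if sender_spec.role != "sender" or receiver_spec.role != "receiver":
        raise ValueError("dyad must be (sender, receiver)")
    if (
        not sender_spec.is_random
        and sender_spec.threshold + receiver_spec.threshold >= 1.0
    ):
        raise ValueError("dyad is not viable: eta_S + eta_R must be < 1")
    sender = make_agent(sender_spec, config)
    receiver = make_agent(receiver_spec, config)
    rng_sender = np.random.default_rng([seed, 0])
    rng_receiver = np.random.default_rng([seed, 1])
    records: list[TrialRecord] = []
    for t in range(1, config.horizon + 1):
        offer = sender.act(t, rng_sender)
        response = receiver.respond(offer, t, rng_receiver)
        receiver_beliefs = receiver.belief_snapshot()
        sender.observe_outcome(offer, response, t)
        receiver.observe_outcome(offer, response, t)
        value = config.value(offer)
        records.append(
            TrialRecord(
                trial=t,
                offer=value,
                response=response,
                sender_reward=sender_utility(
                    value, response, 0.0 if sender_spec.is_random else sender_spec.threshold
                ),
                receiver_reward=receiver_utility(value, response, receiver_spec.threshold),
                sender_beliefs=sender.belief_snapshot(),
                receiver_beliefs=receiver_beliefs,
            )
        )
    return records


def reward_ratio(records: Sequence[TrialRecord]) -> float:
    """Receiver total reward / sender total reward (undiscounted).

    Returns NaN (with a warning) when the sender earned nothing, which
    happens e.g. for a threshold-0.5 sender whose accepted offers all equal
    its own threshold.
    """
    sender_total = sum(r.sender_reward for r in records)
    receiver_total = sum(r.receiver_reward for r in records)
    if sender_total == 0.0:
        warnings.warn("sender total reward is zero; reward ratio undefined")
        return float("nan")
    return receiver_total / sender_total


def _true_type_label(sender_spec: AgentSpec, receiver) -> Optional[str]:
    """Label of the true sender type inside the receiver's type space."""
    labels = getattr(receiver, "type_labels", ())
    if sender_spec.is_random:
        return "random" if "random" in labels else None
    candidate = f"{'thresh' if sender_spec.dom_level == -1 else 'dom1'}-{sender_spec.threshold}"
    return candidate if candidate in labels else None


def _summarize_run(
    records: Sequence[TrialRecord],
    sender_spec: AgentSpec,
    receiver_spec: AgentSpec,
    config: GameConfig,
    seed: int,
) -> dict:
    sender_rewards = [r.sender_reward for r in records]
    receiver_rewards = [r.receiver_reward for r in records]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ratio = reward_ratio(records)
    summary = {
        "sender": sender_spec.label,
        "receiver": receiver_spec.label,
        "seed": seed,
        "sender_total": sum(sender_rewards),
        "receiver_total": sum(receiver_rewards),
        "sender_discounted": discounted_return(sender_rewards, config.discount),
        "receiver_discounted": discounted_return(receiver_rewards, config.discount),
        "reward_ratio": ratio,
        "convergence_trial": np.nan,
        "final_true_type_prob": np.nan,
    }
    beliefs = [r.receiver_beliefs for r in records]
    if beliefs[0] is not None:
        labels = list(beliefs[0])
        receiver = type("L", (), {"type_labels": labels})  # labels only
        true_label = _true_type_label(sender_spec, receiver)
        if true_label is not None:
            idx = labels.index(true_label)
            trajectory = [[b[k] for k in labels] for b in beliefs]
            conv = convergence_trial(
                trajectory, idx, config.convergence_threshold
            )
            summary["convergence_trial"] = np.nan if conv is None else conv
            summary["final_true_type_prob"] = trajectory[-1][idx]
    return summary


def run_experiment(
    dyads: Iterable[tuple[Union[AgentSpec, str], Union[AgentSpec, str]]],
    config: GameConfig,
    seeds: Sequence[int],
) -> pd.DataFrame:
    """One summary row per (dyad, seed)."""
    rows = []
    for dyad in dyads:
        sender_spec = _as_spec(dyad[0], "sender")
        receiver_spec = _as_spec(dyad[1], "receiver")
        for seed in seeds:
            records = run_game((sender_spec, receiver_spec), config, seed)
            rows.append(
                _summarize_run(records, sender_spec, receiver_spec, config, seed)
            )
    return pd.DataFrame(rows)


def summarize_experiment(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-dyad means of every numeric summary.

    Convergence trials are averaged only over runs that converged; the
    number of non-converged runs is reported alongside.
    """
    grouped = summaries.groupby(["sender", "receiver"], sort=False)
    out = grouped.agg(
        n_runs=("seed", "size"),
        mean_sender_total=("sender_total", "mean"),
        mean_receiver_total=("receiver_total", "mean"),
        mean_sender_discounted=("sender_discounted", "mean"),
        mean_receiver_discounted=("receiver_discounted", "mean"),
        mean_reward_ratio=("reward_ratio", "mean"),
        mean_convergence_trial=("convergence_trial", "mean"),
        n_nonconverged=("convergence_trial", lambda s: int(s.isna().sum())),
        mean_final_true_type_prob=("final_true_type_prob", "mean"),
    )
    return out.reset_index()


def records_to_frame(
    records: Sequence[TrialRecord], sender: str = "", receiver: str = "", seed: int = 0
) -> pd.DataFrame:
    """Long-format table: one row per trial per recorded quantity."""
    rows = []
    for r in records:
        base = {"sender": sender, "receiver": receiver, "seed": seed, "trial": r.trial}
        rows.append({**base, "agent": "sender", "quantity": "offer", "value": r.offer})
        rows.append(
            {**base, "agent": "receiver", "quantity": "response", "value": float(r.response)}
        )
        rows.append(
            {**base, "agent": "sender", "quantity": "reward", "value": r.sender_reward}
        )
        rows.append(
            {**base, "agent": "receiver", "quantity": "reward", "value": r.receiver_reward}
        )
        for agent, beliefs in (
            ("sender", r.sender_beliefs),
            ("receiver", r.receiver_beliefs),
        ):
            if beliefs:
                for label, prob in beliefs.items():
                    rows.append(
                        {
                            **base,
                            "agent": agent,
                            "quantity": f"belief:{label}",
                            "value": prob,
                        }
                    )
    return pd.DataFrame(rows)


def export_records(
    frame: pd.DataFrame, out_dir: Union[str, Path], config: GameConfig, seeds: Sequence[int]
) -> tuple[Path, Path]:
    """Write a long-format CSV plus a JSON manifest; returns both paths."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        csv_path = out / "records.csv"
        frame.to_csv(csv_path, index=False)
        manifest_path = out / "manifest.json"
        manifest = {
            "package_version": __version__,
            "config": asdict(config),
            "seeds": list(map(int, seeds)),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
    except OSError as exc:
        raise OSError(f"failed to export records under {out}: {exc}") from exc
    return csv_path, manifest_path
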