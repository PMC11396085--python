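"""Bayesian type-inference shared by every mentalizing agent.

Each intentional agent holds a belief — a probability vector over a small
space of opponent types — and updates it by inverse reinforcement learning:
the likelihood of an observed action under each type's (simulated) policy
re-weights the prior.  Likelihoods are floored before the update so that a
low softmax temperature, under which off-policy actions have vanishing
probability, cannot produce an improper posterior: surprising actions are
treated as highly unlikely rather than impossible.
"""

from __future__ import annotations

from typing import Optional, Sequence

__all__ = ["bayes_update", "convergence_trial"]


def bayes_update(
    prior: Sequence[float], likelihoods: Sequence[float], floor: float = 1e-6
) -> tuple[float, ...]:
    """Posterior ∝ max(likelihood, floor) × prior, renormalised.

    Raises if the posterior cannot be normalised (impossible with a positive
    floor and a proper prior).  The floor keeps every term well inside double
    range, so the product form is exact enough without log-space arithmetic.
    """
    if len(prior) != len(likelihoods):
        raise ValueError("prior and likelihood vectors are not aligned")
    post = [p * (lik if lik > floor else floor) for p, lik in zip(prior, likelihoods)]
    total = sum(post)
    if total <= 0.0:
        raise ValueError("all-zero posterior: no type explains the action")
    return tuple(x / total for x in post)


def convergence_trial(
    belief_trajectory: Sequence[Sequence[float]],
    true_type_index: int,
    threshold: float = 0.95,
) -> Optional[int]:
    """First trial from which the true type's mass stays >= ``threshold``.

    ``belief_trajectory[t-1]`` is the belief after the trial-``t`` update;
    the returned index is 1-based.  Returns None if the mass never reaches
    and sustains the threshold through the end of the trajectory.
    """
    if len(belief_trajectory) == 0:
        raise ValueError("empty belief trajectory")
    result: Optional[int] = None
    for t, belief in enumerate(belief_trajectory, start=1):
        if belief[true_type_index] >= threshold:
            if result is None:
                result = t
        else:
            result = None
    return result
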