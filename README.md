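# tomsim

Seeded simulations of recursive theory-of-mind agents in the **iterated
ultimatum game** (IUG), for computational cognitive science and computational
psychiatry: how deep should an agent mentalize about its partner, and what
happens — deception, skepticism, or paranoia-like false beliefs — when the
depths are matched or mismatched?

## The model

The IUG repeats the ultimatum game for `T` trials. Each trial a **sender**
proposes a split of a unit endowment (offer `a_S` on the grid
{0.0, 0.1, …, 1.0}); a **receiver** accepts (`a_R = 1`) or rejects
(`a_R = 0`). Rejection yields zero to both. Agents carry a threshold η, the
minimal share they are willing to take, giving linear utilities

    u_S = (1 − a_S − η_S) · a_R        u_R = (a_S − η_R) · a_R

and maximise the discounted return Σ_t u_t γ^(t−1). All actions are chosen by
softmax with a commonly known temperature 𝒯.

Agents differ in **depth of mentalization** (DoM): a DoM(k) agent models its
partner as DoM(k−1).

- **DoM(−1)** senders are sub-intentional: a *random* sender (uniform offers)
  and a *reactive threshold* sender that keeps bounds L ≤ a_S ≤ U, moving L up
  to each rejected offer and U down to each accepted one, and greedily offers
  the smallest feasible amount (capped at 1 − η_S).
- **DoM(0)** receiver: Bayesian inverse RL over the sender type space
  {Random, η_S = 0.1, η_S = 0.5}, planning accept/reject by finite-horizon
  ExpectiMax through the reactive sender dynamics — it learns to reject until
  the threshold sender's cap is reached, but simply takes what a random sender
  happens to give.
- **DoM(1)** sender: holds beliefs over the receiver's threshold
  (η_R ∈ {0.0, 0.35}) and an exact replica of the DoM(0)'s belief (priors are
  flat and common knowledge; actions are fully observed). Planning through
  the replica, deception *emerges*: open with a random-looking offer so the
  DoM(0) classifies you as Random, then defect to the bare minimum it will
  accept.
- **DoM(2)** receiver: models the sender as Random or DoM(1) (with all nested
  beliefs). Against a real DoM(1) it counter-deceives — rejecting low offers
  to masquerade as the η_R = 0.35 receiver and force offers up. Against the
  humbler DoM(−1) senders, which its type space does not contain, it
  *over-mentalizes*: it reads reactive or random behaviour through the lens
  of possible deception, settles on a docile accept-anything policy, never
  probes the sender, and pays for it in reward — a computational sketch of
  paranoia-like self-confirming beliefs.

DoM(1)/DoM(2) planning follows the Monte-Carlo (IPOMCP) tradition: Q-values
are evaluated with noise that scales with the remaining horizon and the
agent's reward scale, and observers invert the noise-averaged (marginal)
policy. An exact belief-tree backend (`plan_noise = 0`) is used by DoM(0)
and by the oracle-equivalence tests.

## Worked example

```bash
$ tomsim run-dyad --sender thresh-0.5 --receiver dom0-0.0 --seed 1
quantity  offer  response
trial
1           0.0       0.0
2           0.1       0.0
3           0.2       0.0
4           0.3       0.0
5           0.4       0.0
6           0.5       1.0
7           0.5       1.0
...
12          0.5       1.0
```

The reactive η_S = 0.5 sender opens at 0.0; the DoM(0) receiver, having
inferred a threshold sender from that stingy opener, rejects, pushing the
offer up one grid step per trial. After trial 6 the sender hits its cap
1 − η_S = 0.5 and the receiver accepts from then on: the receiver has
manipulated the sender to its own reservation price.

The same machinery from Python:

```python
import tomsim as ts

cfg = ts.GameConfig()                      # T=12, gamma=0.99, temperature=0.01
records = ts.run_game(("dom1-0.5", "dom0-0.0"), cfg, seed=1)
print([r.offer for r in records])
# [0.2, 0.2, 0.1, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
print(records[-1].receiver_beliefs["random"])   # 1.0 — deceived
```

The DoM(1) sender opens with random-plausible offers (never the
self-revealing 0.0), the DoM(0)'s posterior settles on the Random type, and
the sender then extracts the minimum acceptable 0.1 for the rest of the game.
`run_experiment` / `summarize_experiment` tabulate rewards, receiver/sender
reward ratios and belief-convergence trials over dyads × seeds, and the
`sweep` CLI command runs the full grid (5 senders × 4 receivers × 20 seeds)
from a YAML config.

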