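# pvrnn-dyad

Simulation and analysis of dyadic imitative interaction between two
active-inference agents, for researchers studying how leader-follower
relationships and turn-taking emerge from free-energy minimization in
coupled predictive agents.

Two simulated humanoid agents each control a 6-joint body and observe the
mirrored hand positions of the other.  Each runs a PV-RNN — a hierarchical
variational RNN with multiple-timescale deterministic units d and Gaussian
latents z — trained on movement-primitive sequences with conflicting
probabilistic preferences: after every deterministic primitive **A**,
agent 1 continues with **C** 80% of the time, agent 2 with **B**.  Both
learning and perception minimize the normalized variational free energy

    F = Σ_t Σ_l w_l · mean_r δ(l, r, t) + (1/R_X) Σ_t ‖X_t − X̄_t‖²,

a complexity term (KL between approximate posterior and conditional
prior, per layer) weighted by the *meta-prior* w, plus the prediction
error.  During interaction each agent updates only the adaptive posterior
variables A inside a sliding regression window, with the error computed
on the exteroceptive channels (the partner's observed hands).  The
meta-prior then acts as a sensory-attenuation dial: a large w makes an
agent follow its own intention (it leads, or ignores); a small w makes it
track its partner (it follows); comparable intermediate values on both
sides produce spontaneous turn-taking between the preferred movements.
The package implements the whole pipeline: synthetic movement data,
PV-RNN training by BPTT (hand-derived analytic gradients, NumPy), online
error regression, two-agent coupling, meta-prior schedules (constant and
anti-phase sinusoid), an echo-state-network movement classifier, and the
behavioral statistics (movement frequencies, synchronization and its
chance level, turn-taking counts, symbolic transfer entropy, phase-region
maps).

## Worked example

Train a desk-scale network per agent, let them interact, and analyze:

```python
import numpy as np
from pvrnn_dyad.movement import generate_training_set, robot_fsm
from pvrnn_dyad.network import desk_specs
from pvrnn_dyad.training import TrainingConfig, train_network, evaluate_preference
from pvrnn_dyad.classifier import train_default_classifier
from pvrnn_dyad.dyad import AgentHandle, run_interaction
from pvrnn_dyad.inference import InferenceConfig, MetaPriorSchedule
from pvrnn_dyad import analysis

clf = train_default_classifier(seed=0)
models = {}
for robot, seed in ((1, 1), (2, 32)):
    data = generate_training_set(robot_fsm(robot), 8, 200, seed=seed)
    models[robot] = train_network(
        data, desk_specs(),
        TrainingConfig(epochs=1200, lr=0.01, grad_clip=50.0, seed=seed))
    pct = evaluate_preference(models[robot], clf, n_rollouts=5, T=500, seed=robot)
    print(f"robot {robot} prior generation  A/B/C % = {pct.round(1)}")

icfg = InferenceConfig(window_len=16, iterations=15, inner_lr=0.03)
a1 = AgentHandle(models[1].params, icfg, MetaPriorSchedule(value=0.005))
a2 = AgentHandle(models[2].params, icfg, MetaPriorSchedule(value=5.0))
trace = run_interaction(a1, a2, T=400, seed=11)
l1 = clf.label_sequence(trace.proprio[0])
l2 = clf.label_sequence(trace.proprio[1])
print("follower A/B/C:", analysis.movement_frequency(l1).round(2),
      " leader A/B/C:", analysis.movement_frequency(l2).round(2))
print("sync:", round(analysis.synchronization_rate(l1, l2).overall, 2),
      " KL1:", trace.kl_layers[0, :, 0].mean().round(3),
      " KL2:", trace.kl_layers[1, :, 0].mean().round(3))
```

Output (about six minutes on one core):

```
robot 1 prior generation  A/B/C % = [56.4  2.  41.6]
robot 2 prior generation  A/B/C % = [53.2 40.9  5.9]
follower A/B/C: [0.55 0.23 0.22]  leader A/B/C: [0.56 0.44 0.  ]
sync: 0.71  KL1: 0.197  KL2: 0.002
```

Reading it: each trained network's spontaneous (prior-generated) behavior
alternates A at ~50% and reproduces its trained B/C bias.  In the
interaction, agent 2 (meta-prior 5.0) keeps producing its preferred B and
ignores its partner — its posterior stays glued to its prior (KL ≈ 0.002)
— while agent 1 (meta-prior 0.005) largely gives up its preferred C
(41.6% alone, 22% coupled) and imitates B (2% alone, 23% coupled),
paying a large divergence from its own prior (KL ≈ 0.197): a
leader-follower relationship set purely by the interaction meta-priors.

The same machinery drives the command line:

```sh
pvrnn-dyad gen-data --robot 1 --n 20 --T 400 --seed 0 --out data/
pvrnn-dyad train --robot 1 --seed 1 --epochs 1200 --out ckpt1
pvrnn-dyad train --robot 2 --seed 32 --epochs 1200 --out ckpt2
pvrnn-dyad interact --ckpt1 ckpt1 --ckpt2 ckpt2 --w1 0.005 --w2 5.0 \
    --T 400 --window 16 --iterations 15 --out trace.h5
pvrnn-dyad oscillate --ckpt1 ckpt1 --ckpt2 ckpt2 --out osc.h5
```

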