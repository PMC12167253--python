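# mtnav

Safe dual-device reinforcement-learning navigation of cerebral vessels, at
desk scale. The package models the second stage of mechanical thrombectomy:
steering a micro-guidewire and micro-catheter from a stable guide-catheter
platform in the internal carotid artery (ICA) to a target in the middle
cerebral artery (MCA), while avoiding the anterior cerebral artery (ACA)
branch and limiting the force the guidewire tip applies to the vessel wall.

It is intended for researchers studying safe RL for endovascular devices who
need a fully reproducible, CPU-sized testbed: synthetic bifurcating vessel
trees stand in for patient CT-angiography meshes, and a follow-the-leader
kinematic surrogate with a linear tip-force proxy stands in for finite-element
beam mechanics.

## What is in the box

* **`mtnav.vasculature`** — synthetic planar centerline trees (ICA-like trunk,
  MCA-like target branch, ACA-like distractor), target sampling from ten
  equally spaced branch points, 0.7–1.3 anisotropic scaling augmentation,
  along-centerline geodesics, and a diff-friendly `.ctl.tsv` file format.
* **`mtnav.navigation_env`** — the two-device environment: clamped rotation
  (≤180°/s) and translation (≤40 mm/s) commands, 0.135 s steps, observations
  of three tracked points 2 mm apart per device (current and previous), the
  target position and the previous action; success within 5 mm, timeout at
  200 steps (≈27 s).
* **`mtnav.rewards`** — the six reward functions:

  R1 = −0.005 − 0.001·Δpathlength + 1.0·[target reached]
  R2 = the side-matched (RICA/LICA) IRL reward model on the observation
  R3 = R1 + α·R2, α = 0.001
  Rj = R(j−3) − 0.01·(‖P‖ − 0.85) for ‖P‖ > 0.85 N, else R(j−3), j = 4, 5, 6

  where ‖P‖ is the guidewire tip-force magnitude.
* **`mtnav.demonstrations`** — a scripted, privileged centerline-following
  demonstrator (replacing human teleoperation for reproducibility), the demo
  file format, and the per-side split used for IRL.
* **`mtnav.maxent_irl`** — maximum-entropy IRL with a four-layer fully
  connected reward network, sample-based partition estimation, per-step
  length penalty and entropy temperature; one model per vascular side.
* **`mtnav.sac_agent`** — a Soft Actor-Critic controller (optional LSTM
  encoder, squashed-Gaussian policy emitting μ and σ, twin soft Q-networks,
  auto-tuned temperature, episode-structured replay with sequence chunks);
  stochastic actions during training, deterministic μ at evaluation.
* **`mtnav.evaluation`** — success rate, procedure time (steps × dt over
  successful episodes), path ratio (fraction of initial distance covered in
  failed episodes), mean tip force, paired t-tests and one-way ANOVA.

All neural components run on a small self-contained numpy autodiff
(`mtnav.nn`); no GPU or deep-learning framework is required.

## Worked example

```python
from mtnav.vasculature import generate_tree, TreeParams, sample_target
from mtnav.demonstrations import run_oracle_episode

tree = generate_tree(TreeParams(side="right"), seed=7)
target = sample_target(tree, seed=3)
demo = run_oracle_episode(tree, target, seed=0)
```

prints (via the snippet in `docs/methods.md`):

```
case case_right_0007: 360 centerline points, target #8 at (-39.7, 96.6) mm
demonstrator: success in 25 steps (3.4 s), max tip force 0.31 N
```

The demonstrator reaches the MCA-branch target in 25 control steps (3.4 s of
simulated time) and never exceeds 0.31 N at the tip — comfortably below the
1.5 N vessel-rupture threshold discussed in the endovascular-robotics
literature, and below the 0.85 N level at which the force-penalized rewards
R4–R6 begin to subtract reward.

Training a controller on a simple straight vessel:

```python
from mtnav.vasculature import generate_straight_tree
from mtnav.sac_agent import SacConfig, train_rl

vessel = generate_straight_tree(length=100.0, target_fraction=0.5)
cfg = SacConfig(total_steps=20_000, eval_every=5_000, eval_episodes=20,
                warmup_steps=500, hidden=32, use_lstm=False, update_every=2,
                seed=0)
result = train_rl([vessel], cfg, "R1")
```

```
step   5000: success 100.0% | procedure time 1.78 s | mean force 0.015 N
step  10000: success 100.0% | procedure time 1.82 s | mean force 0.032 N
step  15000: success 100.0% | procedure time 1.78 s | mean force 0.026 N
step  20000: success 100.0% | procedure time 1.77 s | mean force 0.021 N
```

Every periodic deterministic evaluation reaches the target in all 20
episodes; the dense reward's pathlength shaping makes this task converge
within a few thousand exploration steps.

The same pipeline is scriptable from a shell:

```sh
mtnav generate-vessels --n-cases 12 --seed 0 --out cases/
mtnav record-demos --cases cases/ --out demos/ --seed 0
mtnav train-irl --demos demos/ --side right --out irl/right.json
mtnav train-irl --demos demos/ --side left  --out irl/left.json
mtnav train-rl --reward R6 --cases cases/ --irl-models irl/ --out run/
mtnav evaluate --checkpoint run/checkpoint.json --cases cases/ --out report.csv
```

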