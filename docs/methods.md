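# Methods

This note documents the models, surrogates and numerical choices behind
`mtnav`, and what its desk-scale validations do and do not establish.

## The navigation task

The task is the second stage of mechanical thrombectomy: from a stable guide
catheter in the cervical ICA, a curved-tip micro-guidewire and an over-the-wire
micro-catheter are advanced to a target in the ipsilateral MCA. The two
navigation challenges are the tortuous distal ICA and branch selection at the
ICA terminus, where the anterior cerebral artery acts as a distractor: the
curved guidewire tip must be rotated so that it engages the MCA branch.

The agent's observation is deliberately fluoroscopy-like: three tracked
points, 2 mm apart in arc length, per device (tip first), at the current and
previous step, plus the target coordinates and the previous action — 30
numbers, all planar. Actions are a 4-vector in [−1, 1] mapping linearly to
guidewire/catheter rotation (≤180°/s) and translation (≤40 mm/s). A step is
dt = 0.135 s, derived from the 200-step ≈ 27 s episode budget. Success is
tip-to-target Euclidean distance ≤ 5 mm, which spans the vessel cross-section.

## Synthetic vasculature

Patient CTA meshes are not available, so the package generates planar
centerline trees: a trunk of default length 80 mm with sinusoidal tortuosity
(amplitude 5 mm, 1.5 periods), bifurcating at ≈70° into a target branch
(45 mm) and a distractor branch (40 mm); lumen radii taper from 2 mm
(trunk) to ≈1 mm (distal branches), approximating adult ICA/M1 calibers. A
seed jitters all shape parameters by ±15% so a cohort of cases varies in
length, tortuosity and branch angles; left/right cases are mirrored
parameterizations. Centerlines are resampled at 0.5 mm, which bounds all
arc-length quantization errors stated in the tests. Scaling augmentation
rescales x and y independently by factors in [0.7, 1.3] about the root, with
radii scaled by the mean factor.

"Pathlength" (the dense-reward shaping quantity) is measured along the tree:
tip and target are projected to their nearest centerline nodes and the unique
tree path between them is measured. This is the only choice that decreases
monotonically along a correct route past a bifurcation; a Euclidean option is
available via `EnvConfig(pathlength_metric="euclidean")`.

What the generator does *not* reproduce: 3-D geometry, Circle-of-Willis
topological variants, vessel-wall elasticity, flow, and the tactile coupling
between devices in tortuous 3-D anatomy. Results on these trees demonstrate
the learning machinery, not clinical performance.

## Device surrogate

The finite-element beam mechanics of the original simulation environment are
replaced by follow-the-leader kinematics: the device body occupies the
centerline route traced by its tip, so insertion/retraction move the tip along
the route, and the catheter rides the guidewire's route (it cannot pass the
wire tip). The curved tip's effective in-plane deflection is
`tip_curve_angle · cos(axial rotation)` (45° curve; 90° axial rotation is the
neutral, out-of-plane pose). At a bifurcation the route extends into the child
branch whose tangent best aligns with the deflected tip heading — rotation is
therefore a real control requirement, as in the clinical task. Catheter
rotation reorients the catheter tip only; it has no other mechanical effect in
the surrogate.

Tip force is a linear penetration proxy: the unconstrained tip (the real tip
advanced one 3 mm probe length along the deflected heading) is compared with
the lumen; `‖P‖ = wall_stiffness × max(0, distance-to-centerline − radius)`,
directed along the inward normal. The proxy is zero for a tip following the
lumen, grows when the deflected tip presses a wall, and is largest when the
tip rams a vessel end. `wall_stiffness` (1.25 N/mm) is calibrated so that the
scripted demonstrator's observed maximum over a 60-episode battery (0.74 N)
approaches but respects the 0.80 N demonstrator-force bound that anchors the
force scale; the 0.85 N penalty threshold then sits just above ordinary
demonstrator contact, as intended.

Because tracked points lie on the traced centerline route, lumen containment
holds by construction; the property test asserts it as a regression guard.

## Rewards

The six reward functions are transcribed exactly (tested to 1e-12):

* R1 (dense): −0.005 per step, −0.001 per mm of Δpathlength (current minus
  previous, so progress is positive reward), +1.0 on the reaching step.
* R2 (IRL): the side-matched learned reward evaluated on the current
  observation. Right-side targets can only be approached from the right ICA,
  so dispatch is by target side.
* R3 = R1 + 0.001·R2.
* R4/R5/R6 add −0.01·(‖P‖ − 0.85) when ‖P‖ > 0.85 N (zero at or below the
  threshold; the magnitude is used on both sides of the condition, the only
  dimensionally coherent reading).

The Δpathlength sign convention is fixed and documented; flipping both the
convention and the coefficient sign is behaviorally identical.

## Demonstrations

A privileged scripted oracle replaces human keyboard teleoperation: it
translates proportionally to the remaining pathlength (saturating, slowing
within 12 mm of the target), pre-rotates the tip within 25 mm of the
bifurcation so the deflection matches the target branch's turn angle,
relaxes to neutral after the bifurcation, and retracts if it ever finds
itself in the distractor branch. The recording protocol is 2 targets per
case × 2 repeats = 4 navigations per case; a 10-case cohort yields 40
demonstrations, split by target side for IRL. Timed-out demonstrations are
flagged and excluded from IRL training. The oracle does not model human
variability or expertise.

## Maximum-entropy IRL

The reward network is four fully connected layers (three hidden layers of 32
ReLU units, scalar output) over the same feature vector the policy sees
(coordinates scaled by 0.01 to O(1)). Under the maximum-entropy trajectory
model, P(τ) ∝ exp(score(τ)/α) with α = 0.1 and
score(τ) = Σ_t r(s_t) − 0.01·T (the per-step length penalty discourages long
trajectories). Training minimizes α·logsumexp(score/α) over sampled
background trajectories minus the mean demonstration score — the
guided-cost-learning estimator of the negative demonstration log-likelihood.
Its gradient is the background-softmax feature expectation minus the
demonstration feature expectation; the test suite verifies this identity
against exhaustive trajectory enumeration on a three-state chain, and
verifies expert-policy recovery on a 5×5 gridworld against exact soft value
iteration.

For the navigation domain the default background sampler perturbs and
time-shuffles demonstration features at matched trajectory length; a length
mismatch between demonstration and background scores makes the objective
unbounded (the optimizer can inflate all rewards), which is why background
trajectories keep the source length. Environment-rollout samplers can be
plugged in via the `sampler` argument. The documented full-scale setting is
1e6 iterations at learning rate 1e-2; the desk-scale configurations used in
tests (a few hundred iterations) converge on these problem sizes.

## Soft Actor-Critic

The policy encodes the observation — optionally through a single LSTM layer
(32 units) for trajectory-dependent state, which is what lets an agent probe
a branch and remember the outcome — and a two-hidden-layer head emits μ and a
clamped log σ (bounds −5, 2) per action dimension; actions are
tanh-squashed. Twin Q-networks regress toward
r + γ·(min twin-target Q − temperature·log π) with Polyak factor τ = 0.005;
the temperature is auto-tuned toward a target entropy of −4 (minus the action
dimension). Exploration samples from the squashed Gaussian; evaluation uses
the squashed mean. Replay stores whole episodes; recurrent updates draw
fixed-length chunks (default 8) that never span episode boundaries, with a
2-step zero-state burn-in. The critics are feedforward on (observation,
action); only the policy carries recurrence — a desk-scale simplification
that keeps backpropagation-through-time confined to the actor.

Hyperparameters not fixed by the task contract (γ = 0.99, learning rates
1e-3, batch 64, replay 2e5) follow common SAC practice and are exposed in
`SacConfig`. The documented full-scale profile is 1e7 exploration steps with
evaluation every 2.5e5 steps for 80 deterministic episodes; the desk-scale
profile used in tests is 1e4–2e4 steps, small networks, evaluation every
5e3 steps for 10–20 episodes. The soft-Bellman fixed point of the update rule
is validated against exact soft value iteration (closed-form action integral)
on a two-state MDP with the recurrence disabled and a fixed temperature, to a
0.05 tolerance.

## Evaluation metrics and statistics

Success rate is the percentage of evaluation episodes reaching the target.
Procedure time is steps × dt over successful episodes only. Path ratio,
reported for failed episodes, is the percentage of the initial tip-to-target
distance covered by episode end, clipped to [0, 100] (end-of-episode, not
best-over-episode; retrograde episodes clip to 0). Mean force averages ‖P‖
over all steps of all episodes, successes and failures alike. Pairwise
comparisons use two-tailed paired t-tests (p = 1 returned for exactly
identical samples, where the statistic degenerates), multi-group comparisons
one-way ANOVA, significance at 0.05.

## Desk-scale validation scope

The test suite establishes: exact transcription of the reward functions;
oracle equivalence of the SAC critic and the IRL gradient on enumerable
problems; the environment's task contract (containment, spacing, caps,
determinism); end-to-end convergence of SAC with the dense reward on a
straight vessel (2e4 steps, ≥90% success in at least 2 of 3 seeds); and the
*direction* of the force-penalty effect — across six matched seeds on a fixed
bifurcating task, R4 training yields a lower mean tip-force proxy over the
exploration phase than R1, assessed by a one-sided paired t-test. The penalty
constants are small by construction (slope 0.01/N above 0.85 N against a step
cost of 0.005), so at these run lengths the paired comparison is expected to
show direction rather than conventional significance; establishing effect
sizes requires runs orders of magnitude longer. None of these results claim
performance on patient anatomy.

## Known limitations

Planar geometry; kinematic (not mechanical) device model; force proxy is a
geometric penetration measure, not a calibrated contact model; the
demonstrator is scripted, so IRL rewards reflect its regularities rather than
human expertise; desk-scale training runs are far below the exploration
budgets at which the full method was designed to operate.
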