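# gradedreach

Computational core of a three-game virtual-reality suite for graded
trunk-flexion rehabilitation in low back pain, where fear of movement
(kinesiophobia) drives avoidance of spine flexion. The suite presents
reaching demands in increasing order of difficulty: **Reachality** (static
targets, self-paced), **Fishality** (catch fish jumping in a high parabolic
arc), and **Dodgeality** (block fast, flat-trajectory dodgeballs). All three
games drive the player toward the same four points in space, scaled to the
player's body, so trunk motion demands are controlled while speed demands
increase.

The package is aimed at movement scientists and rehabilitation-game
developers who need the deterministic, testable parts of such a suite
outside the game engine:

* **Target placement.** From hip height `h`, trunk length `L_t` and arm
  length `L_a`, the target for an isolated trunk-flexion angle θ is the hand
  position after rotating trunk+arm rigidly about the hip pivot:
  `(x, z) = (L_t sinθ + L_a cosθ, h + L_t cosθ − L_a sinθ)`,
  with θ ∈ {15°, 30°, 45°, 60°}.
* **Inverse ballistics.** Dodgeballs fly at constant launch speed `v0`; the
  launch angle α solves `Δz = R tanα − gR²/(2v0²cos²α)` (low-arc root).
  Fish flights are prescribed an apex height `H`:
  `v_z0 = √(2g(H−z0))`, `t = v_z0/g + √(2(H−z_t)/g)`, `v_x0 = R/t`,
  intercepting on the descending limb.
* **Protocol scheduling.** 5 right- then 5 left-hand reaches at each of 4
  heights (highest first) for Reachality; 2 seeded sets of 15 launches,
  exactly 3 per category (4 heights + duck), for each launch game.
* **Synthetic motion.** A planar two-link (trunk + arm) participant model
  reaches with minimum-jerk profiles `s(τ) = 10τ³ − 15τ⁴ + 6τ⁵`; the
  required trunk reorientation is split between a lumbar component and a
  lumped hip/lower-limb remainder, with measurement noise, so the whole
  pipeline can be validated against known ground truth.
* **Outcome pipeline.** 41-point, 4th-order Savitzky–Golay smoothing and
  differentiation; analysis window from movement cue to 200 ms after target
  contact; lumbar flexion excursion, peak lumbar flexion velocity, impact
  location relative to the feet midpoint; automated exclusion of trials
  without lumbar motion; right-hand-only aggregation into a
  participant × game × height table.
* **Statistics.** Two-way repeated-measures ANOVA (game × height) with
  Mauchly sphericity tests, Greenhouse–Geisser correction, partial η²
  (`= F·df1/(F·df1+df2)`), LSD post hocs and per-height simple effects,
  exposed as a statsmodels-style model/results pair.

## Worked example

```python
from gradedreach import SuiteConfig, run_end_to_end

bundle = run_end_to_end(SuiteConfig(), n_participants=6, seed=42)
print(bundle.anova["peak_lumbar_velocity_deg_s"].summary())
```

```
Repeated-measures ANOVA: peak_lumbar_velocity_deg_s
  subjects: 6, within: game × theta
effect          F(df1,df2)                p           eta_p^2   size      GG
game            F(2.0,10.0)=7325.924      <.001       0.999     strong    no
theta           F(3.0,15.0)=166.554       <.001       0.971     strong    no
game*theta      F(6.0,30.0)=1.918         0.110       0.277     moderate  no
```

The six synthetic participants each play the full session (40 reaches, 2×30
launches); trials are reduced to outcomes and averaged per condition. The
game effect is enormous by construction — the dodgeball game forces much
faster trunk flexion than the fish game at every height:

```python
bundle.cohort.data.groupby(["game", "theta"])["peak_lumbar_velocity_deg_s"] \
    .mean().unstack().round(1)
```

```
theta        15.0   30.0   45.0   60.0
game
dodgeality  104.5  127.7  151.1  166.2
fishality    22.0   41.0   60.3   79.3
reachality   18.9   36.4   54.3   72.1
```

Rows are mean peak lumbar flexion velocity (°/s) per game and target angle
(15° is the highest target). At n=6 the game×height interaction is not yet
resolved (p=.110); at the full cohort size of 31 it is (see below).

The same stages are available from a shell:

```sh
gradedreach targets --hip-height 0.95 --trunk-length 0.48 --arm-length 0.72
gradedreach launch --mode fish --target-x 0.8 --target-z 1.0 --apex 2.0
gradedreach plan --game dodgeality --seed 3
gradedreach run --n 31 --seed 1 --outdir out/
```

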