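# nichesim

Stochastic lattice metapopulations with **niche construction** on
**ephemeral landscapes** — an interacting-particle simulator, its
mean-field theory, and the experiment harness for phase diagrams,
critical transitions, range expansion and constructor–exploiter
competition.

## The problem

Classic metapopulation theory (the Levins model, and its spatial
counterpart the contact process) treats habitat as given: populations
colonize vacant patches at rate 1 and go extinct at rate δ, and
persistence requires R₀ = 1/δ > 1 (mean field) or δ < δ_c ≈ 0.6065 on the
2D lattice.  Many real populations — siderophore-secreting *Pseudomonas*,
invertase-secreting yeast, ecosystem engineers generally — must also
*build* the habitat they colonize, while disturbances continually destroy
it.  `nichesim` models this feedback: every patch of an L × L toroidal
lattice is destroyed (−1), vacant (∅) or occupied (+), all non-destroyed
patches are destroyed at rate e, and occupied *niche constructor* patches
renew destroyed patches within construction range r back to vacant at
rate c, paying for it with a colonization discount:

    +            → ∅     at rate δ            (extinction)
    + , ∅        → −     at rate e            (destruction)
    − + +        → ∅ + + at rate c·n₊(Z)/‖Z‖  (construction)
    ∅ + +        → + + + at rate (1−c)^α·n₊(Z*)/‖Z*‖   (colonization)

Z\* and Z are von Neumann balls of radius r\* and r (‖Z‖ = 2r(r+1)).  The
package answers: which allocation c persists in the widest range of
landscapes e?  When is the extinction transition continuous vs
discontinuous?  How does the construction range r change range expansion
and resilience?  And what happens when a non-constructing *exploiter*
strategy (a plain contact process) competes for the constructed niche?

It is aimed at theoretical ecologists and statistical physicists studying
absorbing-state transitions, public goods, and habitat feedbacks.

## Worked example

```python
import numpy as np
from nichesim import ModelParams, init_full, run, mf_ecrit, mf_cstar, mf_equilibria

# mean-field theory at delta = 0.1, alpha = 1
print(round(mf_cstar(0.1, 1.0), 3))          # optimal allocation c**
print(round(mf_ecrit(0.4, 0.1, 1.0), 4))     # critical destruction rate at c = 0.4
eq = [q for q in mf_equilibria(ModelParams(delta=0.1, e=0.03, c=0.4)) if q.stable and q.kind == "interior"]
print(round(eq[0].state.p_plus, 3))          # stable occupied fraction

# one stochastic run at the same parameters on a 128 x 128 torus
tr = run(ModelParams(delta=0.1, e=0.03, c=0.4), init_full(128), t_max=1000.0, seed=1)
print(round(tr.mean_occupancy(t_from=750.0), 3))
```

prints

```
0.434
0.0812
0.685
0.632
```

The mean field says: allocating c\*\* ≈ 0.43 to construction maximizes the
survivable destruction rate; at c = 0.4 the metapopulation tolerates
e up to ≈ 0.081 and, at e = 0.03, settles at occupancy 0.685.  The lattice
simulation at the same parameters equilibrates near 0.63 — lower than the
mean field, because spatial crowding wastes colonization events on
occupied neighbors.  That gap widens toward the extinction threshold, and
what it does to the transition is the scientific heart of the package.

## Command line

Every experiment is a subcommand reading a TOML/YAML config:

```bash
nichesim simulate  --config run.toml --seed 1 --out out/
nichesim sweep     --config run.toml --grid 25 --out out/   # {c,e} phase diagram
nichesim critical  --config run.toml --control delta --bracket 0.55 0.75
nichesim exponent  --config run.toml --k-crit 0.6065
nichesim relax     --config run.toml --k-crit 0.6065
nichesim expand    --config run.toml --r-list 1,5,10
nichesim compete   --config run.toml
nichesim meanfield --out out/                               # MFA matrix + e_crit(c)
nichesim transect  --config run.toml
```

Outputs are CSV series/matrices, PNG snapshots (green = occupied, white =
vacant, black = destroyed, red = exploiter) and a JSON manifest with the
full configuration, seed and output checksums.

Example `run.toml`:

```toml
seed = 1
[model]
delta = 0.1
e = 0.01
c = 0.4
[protocol]
L = 128
t_transient = 1000
t_avg = 250
```

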