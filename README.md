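# foragescan

Scan-path organization analysis for dynamic, non-exhaustive visual
foraging.

## The problem

In a foraging-style visual search task an observer taps targets among
moving distractors on a touch screen and may abandon the current display
("patch") at any moment. How *organized* is the resulting scan-path, how
does organization evolve within a patch as targets get scarce, and how
does it change across development? This package provides the full analysis
pipeline for such data — and a task simulator, so every stage is testable
without any human dataset.

## What it computes

**Four organization indicators** over the ordered sequence of collected
targets (pick-time coordinates, in pixels):

- **best-r** = max(|r(order, x)|, |r(order, y)|): near 1 for reading- or
  scanner-like sweeps; blind to circular/spiral organization.
- **mean ITD**: mean Euclidean distance between consecutive picks; lower
  is more organized.
- **PAO** (percentage above optimal) =
  (actual path length / shortest open Hamiltonian path length − 1) × 100,
  with the optimum from an exact dynamic program (n ≤ 10) or a
  nearest-neighbour + 2-opt heuristic; PAO = 0 means the observed order
  was optimal.
- **intersection rate**: crossings between non-adjacent scan-path
  segments, divided by the number of picks.

**A sampling-without-replacement choice model.** The probability of
picking remaining target *j* is proportional to
w_class · w_stick · w_prox · w_dir, with class preference p_a, class
stickiness p_s, proximity bias w_prox = exp(−ρ_d·d_j/s) and direction
perseverance w_dir = exp(|ρ_Θ|·cos(Δθ_j − μ)); the sign of ρ_Θ encodes
the side of a lateral bias, so only |ρ_Θ| measures strength. Parameters
are estimated by maximum likelihood (optionally MAP with weak priors),
with observed-information standard errors.

**Time-course and model comparison.** Each trial is split into two halves
("bins"), scored per bin, and ten a-priori linear mixed models — fixed
effects of ln(age), condition (feature/conjunction), set size and bin,
plus increasing interaction structure, with a random participant
intercept — are fitted by maximum likelihood and ranked by AICc and
Δᵢ = AICc − min AICc.

**A task simulator**: displays of 60/100/140/180 items on a
1400 × 1050 px screen, 20–30 % targets, items moving at 44 px/s with
pseudo-random direction changes and wall reflection; forager agents
(uniform random, left-right / top-bottom scanners, spiral, FVF-limited
nearest-target, and the generative bias model) with configurable quit
rules; and a lifespan-style cohort generator whose proximity bias grows
with ln(age).

## Worked example

```python
import numpy as np
from foragescan import (gen_display, run_agent, AgentPolicy,
                        score_sequence, split_bins)

rng = np.random.default_rng(11)
display = gen_display(set_size=100, condition="feature", rng=rng)
policy = AgentPolicy(kind="nearest_fvf", n_picks=20)   # proximity forager
trial = run_agent(display, policy, rng)

for label, picks in (("bin1", split_bins(trial).bin1),
                     ("bin2", split_bins(trial).bin2)):
    s = score_sequence(picks, bin_label=label)
    print(label, f"n={s.n_picks} best_r={s.best_r:.2f} "
          f"itd={s.mean_itd:.0f} pao={s.pao:.0f} ir={s.intersection_rate:.2f}")
```

prints (seed 11):

```
bin1 n=10 best_r=0.42 itd=229 pao=51 ir=0.30
bin2 n=10 best_r=0.88 itd=319 pao=22 ir=0.10
```

Each bin's ten picks get all four indicators: here the second half of the
patch shows the longer hops typical of a depleting display (mean ITD 229
→ 319 px), while the other indicators swing the way single trials do —
the systematic second-bin decline in organization (ITD *and* PAO rising
on average) only emerges across many trials, which is exactly what
`analysis/02_score_trials.py` aggregates and the mixed-model comparison
tests.

## The analysis pipeline

Numbered drivers under `analysis/` run the whole study on synthetic data
and write their tables under `results/`:

1. `01_simulate_cohort.py` — simulate a lifespan cohort (trial logs,
   display snapshots, ground-truth parameters)
2. `02_score_trials.py` — per-bin organization scores + exclusion ledger
3. `03_fit_bias.py` — choice-model fits per participant × condition
   (and per set size × bin for the ρ_d time course)
4. `04_compare_models.py` — AICc tables for the ten candidate mixed
   models, per indicator
5. `05_correlations.py` — indicator ↔ bias-parameter correlation report

Each driver takes `--results` (and `01` a `--seed`) and prints a short
summary of what it found.

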