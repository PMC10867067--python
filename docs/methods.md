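# Methods

This note documents the models, numerical choices and limitations behind
`foragescan`. It is the package's own account of its science; every
empirical statement here is something the test suite or the analysis
drivers compute.

## Task and data model

The unit of analysis is a *trial* (one patch visit): an ordered sequence
of picks with pick-time screen coordinates, an item-class label, and a
target/distractor flag. Foraging is non-exhaustive — the observer may
leave a patch at will — so trials have variable length by design, and all
statistics must be comparable across unequal pick counts. Coordinates are
screen pixels (origin top-left, y downward); every metric uses only
distances, segment crossings, and correlations up to sign, so it is
invariant to this convention (asserted by reflection/rotation tests).

Distractor taps are retained in the logs but excluded from all
organization metrics and from the choice-model likelihood: the indicators
are defined over collected targets. The original task penalized distractor
taps (−1 point vs +2 per target), making them rare; how they entered the
original metric computations is not documented, and exclusion is the
conservative choice.

## Organization indicators

**best-r.** Pearson correlations between pick rank and each coordinate;
best-r is the larger absolute value. If one axis is constant the other
axis alone supplies the value (Pearson is undefined on a constant vector;
propagating NaN would discard the informative axis); if both are constant
the score is undefined with a reason code. Note that best-r = 1 requires
the coordinate to be *linear* in rank: a perfect left-to-right sweep over
irregularly spaced targets scores slightly below 1, and per-trial values
around 0.95–0.98 are the practical ceiling at 20–50 picks.

**Mean ITD.** Arithmetic mean of consecutive Euclidean distances
(pixels). Defined from 2 picks.

**PAO.** The shortest *open* Hamiltonian path (free endpoints) through
the pick-time coordinates is found exactly by a Held–Karp dynamic program
over subsets for n ≤ 10 (configurable), and heuristically above that by
taking the best nearest-neighbour construction over all starting points
and refining it to 2-opt local optimality. Because the observed pick
order is itself a Hamiltonian path, a heuristic "optimum" can never
legitimately exceed the observed length; if it does, the observed path
replaces it (PAO = 0). This clamp makes PAO ≥ 0 an invariant under
heuristic solving. All picks coincident (optimal length 0) is undefined
with reason `degenerate_geometry`. The exact solver is verified against
exhaustive permutation enumeration on random instances up to n = 8.

**Intersection rate.** Crossings between non-adjacent scan-path segments
(adjacent segments share an endpoint and never count), each crossing pair
counted once, divided by the number of picks. Degenerate geometry is
handled deterministically: collinear overlap of two non-adjacent segments
counts as one intersection, as does a segment passing exactly through
another's vertex; the orientation test uses an epsilon of 1e−9 × the
bounding-box scale. The counter is verified against an independent
segment-pair tester (shapely) on random and integer-grid polylines.

## Choice model

Sampling without replacement: at each step the probability of picking
remaining target *j* is proportional to

    w_class(j) · w_stick(j) · w_prox(j) · w_dir(j)

- w_class = p_a if j belongs to reference class A (lexicographically
  first target class, recorded in output metadata), else 1 − p_a;
- w_stick = p_s if j's class matches the previous pick's class, else
  1 − p_s;
- w_prox = exp(−ρ_d · d_j / s), d_j the distance from the previous pick,
  s a fixed standardization scale (display diagonal, 1750 px, so ρ_d is
  display-size free);
- w_dir = exp(|ρ_Θ| · cos(Δθ_j − μ)), Δθ_j the signed difference between
  the heading to j and the previous movement direction; μ = 0 when
  ρ_Θ ≥ 0 (straight-ahead perseverance) and a configurable lateral offset
  (default −π/2) when ρ_Θ < 0, so the sign encodes the side of the bias
  and only |ρ_Θ| its strength.

The first pick uses the class weight only; the second adds stickiness
and proximity (no heading exists yet). With ρ_d = ρ_Θ = 0 the model
reduces exactly to the two-parameter bag model. The exponential-distance
and cosine (von-Mises-type) kernels are this package's concrete choices:
smooth, identifiable, and neutral at 0. Fitted ρ_d / ρ_Θ magnitudes are
therefore comparable across datasets analysed with *this* package, but
not directly to values obtained under other kernel conventions — only
signs and orderings transfer.

**Estimation.** Maximum likelihood over (logit p_a, logit p_s, ρ_d, ρ_Θ)
with a small multistart and L-BFGS-B. ρ_d is optimized on the natural
scale, unbounded, rather than log-scale: the neutral value ρ_d = 0 must
be an interior point for neutrality checks (estimate within 2 SE of 0)
to be well posed, and a slightly negative fitted value is interpretable
as sampling noise around neutrality. Standard errors come from the
observed information at the optimum, delta-method-transformed to the
probability scale for p_a and p_s. If all targets share one class, p_a
and p_s are unidentifiable: pinned at 0.5 and flagged. Very small
per-cell fits (a dozen choice steps) can be separated — a handful of
nearest-target choices drives ρ_d → ∞ — so the fitter optionally does
MAP with weak zero-mean Gaussian priors (the binned per-set-size fits in
the analysis drivers use sd 5 on ρ_d, 2 on ρ_Θ); with hundreds of steps
the penalty is negligible.

The likelihood conditions on the remaining-target configuration at each
choice. On static displays this is reconstructed from the pick log; on
moving displays the simulator records per-pick snapshots of the remaining
targets, which serialize to a long CSV (`displays.csv`).

## Time-course binning

Each trial's target picks split into first ⌈n/2⌉ (bin 1) and the rest
(bin 2); the odd middle pick goes to bin 1 (a fixed convention, since no
canonical rule exists). Bins are scored as self-contained sequences — the
hop across the bin boundary belongs to neither bin. Trials whose smaller
bin falls below 4 picks (configurable) are excluded with a reason code;
4 is the smallest count at which all four indicators are defined.
Exclusions are reported in a ledger, never dropped silently.

## Candidate mixed models

Ten a-priori fixed-effect structures over ln(age) (numeric), condition
(feature = 0, conjunction = 1), set size (numeric 60–180) and bin
(0/1), from main effects only (Model 1) up to Model 10, which adds the
age × set size × condition three-way and the four-way product on top of
Model 8's two-way structure. Under this coding every interaction is one
product column and the parameter counts (fixed coefficients + intercept
variance + residual variance) are 7, 8, 8, 9, 8, 8, 9, 11, 12, 13.
Set size enters numerically because search costs scale essentially
linearly with it and because this coding yields exactly those counts;
age enters as ln(years), the standard developmental compression.

Fits are maximum likelihood (never REML — log-likelihoods must be
comparable across fixed-effect structures) with a single random
participant intercept, via statsmodels MixedLM; observations are
trial-bin rows. Design columns are internally rescaled (a diagonal
reparameterization that leaves the ML log-likelihood unchanged) to keep
optimization well conditioned with raw interaction columns ranging into
the hundreds. AIC = −2ℓ + 2k, AICc adds 2k(k+1)/(n−k−1), Δᵢ is relative
to the candidate minimum; AICc ties go to the smaller model. Candidates
fitted on different row sets are refused (non-comparable likelihoods).
A fit whose intercept variance collapses is retained and flagged
singular. AIC magnitudes are data-dependent and are not reproduction
targets; what the pipeline warrants is structural (parameter counts,
nesting monotonicity of the log-likelihood, and recovery of a generating
structure by AICc on simulated data).

## Simulator

Displays: uniform random item positions on 1400 × 1050 px, set sizes
60/100/140/180, target fraction drawn uniformly in [0.20, 0.30], four
feature colors or four color × shape conjunction cells with one target
class (a two-target-class option exists as a harness for the class-bias
parameters, which are degenerate under a single target class). Motion:
constant 44 px/s, headings redrawn at exponentially distributed intervals
(mean 1 s; the memoryless single-parameter choice for "pseudo-random
intervals"), walls reflect position and the normal heading component, so
per-step travelled distance is exactly speed × dt. Boundary reflection
(rather than wrap-around) keeps densities uniform and items visible.

Agents pick one target per decision interval (default 0.7 s) while the
display moves between picks. Scanner agents sweep 50 px bands
left-to-right (or top-to-bottom) in lexicographic band order; the spiral
agent starts at the innermost target and takes the nearest remaining
target in the counterclockwise forward half-turn; `nearest_fvf` is a
proximity-driven forager with a limited functional visual field (radius
300 px, roughly a quarter of the display diagonal): nearest detectable
target, else a uniformly random jump. Task scoring (+2/−1, 200-point
cap) is tracked for fidelity but ignored by all metrics.

The FVF mechanism is what makes organization *decline within a patch*:
as targets are collected, fewer remain inside the field, forcing long
random jumps, so bin-2 mean ITD and PAO rise on average. A pure softmax
proximity bias does not produce this decline — scarcity spreads the
remaining distances apart, which *sharpens* its choices — an instructive
negative result reproduced in the test suite's exploratory history and
documented here so nobody re-derives it the hard way. The lifespan
cohort generator therefore runs bias-model agents gated by the FVF
(configurable off).

The lifespan generator gives every participant choice-model parameters
with ρ_d increasing in ln(age) (slope 1.0 per log-year plus N(0, 0.25)
jitter, spanning roughly 1.4 to 3.2 across ages 4–25), 21 observers per
integer age by default, 2 conditions × 4 set sizes, and non-exhaustive
collection of 80 % of targets per patch. These defaults emulate the
*structure* real cohorts show (organization improving with age,
declining within patch); they do not emulate touch-latency noise, motor
error, strategy switching mid-trial, or distractor taps, so passing
recovery tests demonstrate correctness of the estimators under the
model, not robustness to every human idiosyncrasy.

## Problem sizes used in the checks

The self-checks run at desk scale, chosen so the full suite completes in
minutes: solver-oracle equivalence on 200 random instances (n ≤ 8) and
500 random polylines; regime separation with 50 scanner trials of 50
picks (scanner best-r needs long trials: the order-statistic ceiling of a
perfect sweep only clears 0.95 per-trial reliably around 50 picks) and
500 random trials; parameter recovery from 200 trials × 15 picks;
time-course decline over 200 FVF-forager trials; and AICc structure
recovery over 100 replicates of a 279-participant balanced table. The
analysis drivers default to 3 observers per integer age (66 participants)
purely to keep the narrative runs quick; the generator's scientific
defaults are the full cohort.

## Known limitations

- Heuristic PAO (n > 10) is a lower-bounded approximation; values on
  long trials can differ slightly from other heuristic solvers.
- The choice model is first-order (conditions only on the previous pick
  and heading); no memory of earlier picks, no distractor-choice model.
- ρ_d/ρ_Θ magnitudes are kernel-convention-specific (see above).
- Whether to fit one parameter set per participant, per participant ×
  condition, or pooled is a modelling choice; per participant × condition
  is the default here.
- The mixed models use trial-bin rows with a random intercept only; no
  random slopes, no REML, no p-values.
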