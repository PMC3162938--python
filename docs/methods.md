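# Methods

## Model

Each target gene's transcript level y(t) follows a multi-input
single-output stochastic dynamic regulation model

    dy/dt = Σ_i b_i x_i(t) − β y(t) + k + ε(t)

over the set of candidate regulators delivered by Stage I. `b_i`
(expression units/h per unit activity) is TF i's regulatory ability and its
sign encodes activation or repression; `β` (1/h) is the first-order
degradation rate of the target transcript; `k` (units/h) the basal
production rate; `ε` zero-mean Gaussian noise of unknown variance. The
regulatory activity is a logistic function of the TF's own mRNA level,

    x_i(t) = 1 / (1 + exp(−r (z_i(t) − m_i) / s_i)),

modelling a promoter-binding threshold at the TF's typical expression
`m_i` (its profile mean). We standardise by the profile sd `s_i` so that
the transition rate `r` (default 1) is scale-free and one default works
across genes measured in arbitrary units; the unscaled convention
(`standardize=False`, all s_i = 1) is available. A constant TF profile has
no usable scale; its s_i falls back to 1 and the resulting constant
activity column is caught downstream as collinear with the intercept.

The model is deliberately modest: mRNA stands in for regulator activity
(no protein or post-translational layer), regulation is additive, and each
target is fitted independently given its candidate set.

## Identification

The reference design measures 5 non-uniform time points (0, 0.5, 2, 8,
48 h; roughly geometric) in triplicate. Identification proceeds in three
steps, each with the design choices that mattered spelled out:

1. **Interpolation.** Replicate-averaged profiles are interpolated to a
   uniform grid (default step 0.5 h → 97 points over 48 h). The default
   interpolant is a natural cubic spline *in log-shifted time*
   u = ln(1 + t − t0) ("log-cubic"): the design is near-uniform in u, and
   we measured that a plain cubic spline in t overshoots badly across the
   8→48 h gap (median reconstruction error 0.68 signal-sd on synthetic
   trajectories vs. 0.39 for log-cubic). Plain `cubic`, shape-preserving
   `pchip` and `linear` are config options.

2. **Discretisation.** The forward difference (y[j+1] − y[j])/step is an
   O(step²) estimate of the derivative at the interval midpoint, so the
   design row is evaluated there too: TF activities are the sigmoid of the
   midpoint expression and the degradation term uses the midpoint level
   ("midpoint" collocation). Evaluating at the left endpoint instead
   (explicit-Euler convention, config option "left") carries an O(step)
   bias we measured at 26% median error in b on densely observed data,
   against 3% for midpoint.

3. **ML fit and order selection.** Under i.i.d. Gaussian noise the ML
   coefficient estimates are ordinary least squares; σ̂² = RSS/N and
   log L = −(N/2)(ln 2πσ̂² + 1). Model order is selected by minimising
   AIC = n_obs·ln(max(σ̂², 10⁻¹²)) + 2P with P = L + 2 (the b_i, β, k; σ is
   not counted — only internal consistency matters, additive constants
   cancel). Greedy backward elimination removes, per round, the regulator
   whose deletion lowers AIC most and stops when no deletion improves;
   exhaustive search scans all subsets (capped at L = 12, beyond which
   greedy is forced with a warning). Ties prefer the smaller model, then
   lexicographic regulator ids. β is estimated unconstrained; fits with
   β̂ ≤ 0 are flagged as biologically suspect but kept.

### What the sparse design can and cannot determine

Five time points give only four independent interval-difference equations
per target, while an L-regulator model has L + 2 parameters. For L ≥ 3 the
measured information alone therefore cannot pin down either the parameters
or the regulator subset — any 3-regulator model can interpolate the five
time-point means, which we confirmed empirically with a simulation-based
(output-error) fit whose subset ranking is random even at zero noise. All
discrimination rests on the interpolation prior, i.e. on how faithfully
the spline tracks the trajectory *between* samples. As a consequence:

- **Per-target regulator selection at the 5-point design is essentially
  uninformative.** Under the benchmark's conditions (3 true regulators
  among 8 candidates, 5% noise) exact-set recovery is ≈0%: decoy
  activities are smooth curves that absorb the smooth interpolation
  residual. A control with trajectories observed directly on the 0.5 h
  grid recovers the true subset as the best-fitting one in ≈100% of
  cases and b to ≈3% — the machinery is consistent; the design is the
  binding constraint.
- **The AIC sample-size convention cannot repair this.** The default
  scores AIC at the regression row count (n_obs = 96), which is liberal:
  spline rows are dependent, the penalty is relatively small, and most
  candidates are retained. The conservative alternative `n_eff="design"`
  (score at the 4 measured intervals) prunes harder but — selection being
  structurally uninformative — prunes largely at random, and it degrades
  the greedy/exhaustive agreement (measured ≈70–78% subset identity vs.
  ≈99% under the default). Both conventions are exposed; the default
  errs on the side of retaining candidate regulation.
- **Parameter recovery given the true structure** is accurate when the
  trajectory is temporally resolved (≈3% median error on the 0.5 h grid,
  noise-free) and degrades gracefully with noise (≈11% at 5% triplicate
  noise, dominated by errors-in-variables attenuation); at the 5-point
  design it is bias-dominated and not reliable.

These are statements about any method operating on five time points with
this model class, not about a fixable implementation detail; they match
the common caveat that such designs support network *screening* rather
than per-edge kinetic estimation.

## Stage I choices

Replicates are averaged per time point before correlation and fitting (the
model describes one profile per gene). "Delete the bottom 10%" is applied
to the global |r| ranking of all scored pairs, with a stable
(|r|, TF, target) tie-break; `floor(0.10·n)` pairs are removed, so fewer
than ten pairs lose nothing. Correlation is computed per condition and
each condition gets its own rough and refined network. Self-edges are
excluded by default (the model's β term already captures self-decay).
Unscorable pairs (zero-variance profile) are deleted and logged. Gene
identifiers are matched case-insensitively after whitespace trimming.

## Synthetic studies

The generator emulates the reference experiment: two conditions, 58
targets + 7 TFs (65 measured genes), design times {0, 0.5, 2, 8, 48} h,
3 replicates. Choices and what they emulate:

- **TF trajectories** cycle through three smooth response archetypes —
  saturating relaxation (τ ∈ [1.5, 8] h), an early transient pulse
  (peak ∈ [1, 4] h) and a delayed sigmoidal switch (onset ∈ [0.5, 6] h) —
  plus a slow sinusoidal drift. The archetype mix exists because a bank
  of near-identical drivers would make regulator identity meaningless;
  the early time scales reflect an acclimation response that initiates
  within 0.5–2 h and settles within the sampled window, which is what
  the log-spaced design was built to observe.
- **Target kinetics**: β ∈ [0.2, 0.6]/h (mRNA half-life ≈1–3.5 h, typical
  for regulatory-response transcripts), |b_i| ∈ [0.8, 2] with random
  sign, 1–3 regulators per target. The basal rate is drawn in
  [0.5, 1.5] and shifted by the sum of negative b so production stays
  positive even when every repressor saturates — expression is emitted
  in positive arbitrary units, matching array-intensity-like data.
- **Simulation** is classical fixed-step RK4 at 0.1 h — well above
  inference fidelity, so recovery tests probe the inference, not the
  simulator. Measurement noise is applied at the replicate level with sd
  = 5% of each gene's temporal signal sd.
- **Hubs and decoys.** Each condition plants one hub TF regulating 60% of
  targets (TF001 in the first condition, TF002 in the second), giving
  the differential comparison a known answer. The candidate table is the
  union of both conditions' true edges plus 4 decoys per target — it is
  condition-independent, as sequence-based binding predictions are.
  Truth labels live only in a JSON sidecar, never in pipeline inputs.

What the generator does *not* emulate: array-specific intensity
distributions, probe effects or missing values; TF→TF regulation (TF
profiles are exogenous drivers, mirroring the treatment of TF mRNA as
observed inputs); condition-dependent binding. Passing tests therefore
demonstrate correctness of the pipeline's logic and its behaviour under
the stated noise/design regime — not performance on real hybridisation
data.

## Numerical details

- Interpolation grid: `t0 + step·arange(floor(span/step)+1)`; design-time
  values are reproduced exactly; 2-point profiles fall back to linear.
- Rank-deficient designs raise a named error listing the collinear
  columns (QR with pivoting); per-target failures inside network
  refinement are logged and the target emitted regulator-free.
- σ̂² < 10⁻¹² is floored inside logs and flagged (`sigma2_floored`).
- Seeding: every generator output is a pure function of its arguments
  including the seed (numpy `SeedSequence` spawning per condition/gene).

## Problem sizes

Defaults used throughout the test suite and the acceptance script: studies
of 58 targets + 7 TFs for end-to-end runs (20 seeds), 100 seeded
single-target instances for recovery and parameter error, 200 instances
for greedy-vs-exhaustive (L = 6), 500 random network pairs for the
partition invariants. These sizes make the whole suite reproducible on a
single CPU in a few minutes.

## Known limitations

- Per-edge inference at the 5-point design is screening, not estimation
  (see above); conclusions should rest on aggregate structure and on the
  common/differential decomposition, both of which are exercised by the
  tests.
- The likelihood treats interpolated grid rows as observations;
  uncertainty is therefore optimistic and no standard errors are
  reported.
- No regularised or Bayesian alternatives; no joint multi-target fitting;
  no protein-level modelling.
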