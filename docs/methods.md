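# Methods

## The model

The community is a four-species generalized Lotka–Volterra (gLV) system
over three resident groups of the vaginal microbiome — non-optimal
anaerobic bacteria (nAB, the BV-associated polymicrobial group),
*Lactobacillus iners* (Li), and "optimal" lactobacilli (oLB:
*L. crispatus / gasseri / jensenii*) — plus a probiotic strain P treated as
a fourth species:

    dx_i/dt = x_i * ( g_i + Σ_j α_{j→i} x_j )

with intrinsic growth rates `g_i = k_grow-i` (d⁻¹) and interaction
coefficients `α_{j→i}` (density⁻¹ d⁻¹, stored as `alpha[i, j]`).
Self-interactions are negative and set carrying capacities; cross terms are
free in sign and encode competition, amensalism, commensalism or mutualism.
Two interventions perturb the system:

- **Antibiotic (metronidazole)**: during a treatment window the nAB growth
  rate is replaced by a first-order kill rate `k_kill` (−2.64 d⁻¹ by
  default, the mean reported decay; −3.82 d⁻¹ for the strong variant).
  Lactobacilli and the probiotic are metronidazole-resistant and
  unaffected.
- **Probiotic dose**: an instantaneous additive bolus to P. Dosing as a
  bolus is the simplest semantics consistent with discrete administration;
  the model has no pharmacokinetics.

Abundances are in arbitrary density units; classification uses relative
abundances only. Time is in days; 1 month = 30 d, 12 months = 365 d.

## Virtual patients

A patient is a draw of the 12 resident parameters. Defaults:

| parameter | range | unit | note |
|---|---|---|---|
| growth rates (3) | U[0.1, 1.0] | d⁻¹ | in vitro ranges scaled in vivo |
| self-interactions (3) | U[−0.04, −0.004] | density⁻¹d⁻¹ | mean −0.022 |
| interspecies terms (6) | U[−0.04, 0.04] | density⁻¹d⁻¹ | Li→nAB, oLB→nAB restricted ≤ 0 |

Interspecies terms sit on the same in-vivo-scaled envelope as the
self-interactions. This is a deliberate design choice: if cross terms can
exceed every self term severalfold, (a) competitive exclusion makes almost
every nAB-dominant equilibrium an nAB-*only* state, eliminating the
clinically typical subdominant lactobacilli, and (b) mutualistic pairs
blow up in finite time for 10–25 % of patients under therapy. Both are
artifacts a practitioner would reject. The lactobacilli→nAB sign
constraint encodes lactic-acid/H₂O₂/bacteriocin inhibition; all other
directions, including nAB→lactobacilli (biogenic amines can inhibit
lactobacilli, but facilitation is not excluded), remain free. Ranges are
config-first (`ParameterRanges`, YAML-loadable) so species-resolved values
can be dropped in when available.

**Equilibrium census.** For each draw, all 2³ support subsets of the
resident subsystem are solved analytically (`Σ_{j∈S} α_{j→i} x_j = −k_i`),
feasible solutions (all support abundances > 0) are kept, and linear
stability is decided by the Jacobian spectral abscissa (stable iff
< −10⁻⁹; marginal cases count as unstable). Each stable point is
classified by the CST classifier; the set of stable CSTs yields the *CST
equilibrium behavior* label (`1SS X`, `2SS X/Y`, `other-multistable`).

**BV+ population.** A 30,000-draw pool is resampled (largest-remainder
rounding, without replacement when the stratum suffices) to the clinically
observed distribution of BV-capable behaviors: 60 % `1SS nAB`, 31 %
`2SS nAB/Li`, 9 % `2SS nAB/oLB` — 1200/620/180 patients at n = 2000.

**Initial condition.** Each patient starts at its stable nAB-dominant
fixed point (highest-nAB point if several) with P absent, and residents
below 1 % of the community total raised to that detection-limit floor.
The floor matters: gLV extinction is absorbing, so exact boundary starts
would freeze the species pool and make multistable patients unable to
switch state under any therapy — contradicting both clinical observation
(nAB-dominant communities harbor low-level lactobacilli and vice versa)
and the very point of the 2SS strata. 1 % is a fixed choice on the order
of sequencing detection limits.

**Untreated-baseline screen.** A BV+ candidate must, with no therapy,
remain bounded and classify nAB-dominant at every standard observation
time over a year. This removes (rare) draws whose facilitative loops
diverge once the floor seeds their partners, and marginal patients whose
nAB basin is smaller than the floor perturbation — both unphysical as
"stably BV-positive" patients. Typically a few percent of candidates fail.

## Classification

A nearest-centroid rule over relative abundances stands in for VALENCIA.
Default centroids are the one-hot unit vectors (label = most abundant
group); distances tie-break by the fixed priority nAB > Li > oLB > P, so
ambiguous states conservatively count as treatment failure. Custom
(e.g. VALENCIA-derived) centroids load from CSV. Classification is scale
invariant and permutation equivariant; an empty community is an error.

## Strains and regimens

A probiotic strain is 7 parameters: `k_grow-P`, `α_P→P`, and the six cross
terms with the residents. The null reference strain (k = 0.5 d⁻¹,
α_P→P = −0.022, cross terms 0) neither affects nor is affected by the
community; the library adds the traditional design (α_P→nAB = −0.01), the
1p/2p/3p "best" designs (+0.01 α_nAB→P, −0.01 α_P→nAB, +0.01 growth), the
2p counterfactual (both nAB couplings negative), the oLB-boosting family
(±0.05 modifications), and the Lactin-V benchmark set (traditional/null/
moderate/bad) anchored at α_P→nAB = −0.012 with 3× competition terms
(−0.036) on the Li/oLB↔P couplings. The "3× strength" anchor is read
against the fixed −0.012 reference; the alternative literal reading
(3 × the strain's own α_nAB→P) is available via `competition_reading`.

Regimens:

- `short_term`: 7 once-daily doses; readouts at cessation (day 7) and 1 wk,
  1/3/6/12 months post-cessation.
- `abx_only`: 7-day antibiotic window.
- `abx_then_probiotic`: 7-day antibiotic, then 7 daily doses.
- `lactin_v`: 5-day antibiotic; 4 daily doses (days 5–8); twice-weekly
  doses days 12–78.5 (20 doses); cessation day 82; readouts at trial weeks
  12 and 24 (days 89 and 173 — week 12 is one week after cessation).
  Intermittent-phase frequency variants: bi-weekly, weekly, twice-weekly,
  4×-weekly, daily over the same 70-day span.

**Dose calibration.** The bolus size is one scalar per study. The original
anchor (a clinically observed relative-abundance distribution one day
after a dose) is not recoverable, so the dose is chosen such that the
median probiotic relative abundance one day after a single dose is 0.5
across the population (bisection on the simulator with the null strain).
Typical calibrated doses are ~100–150 density units for the default world.

## Numerics

- Single trajectories (`simulate`): piecewise LSODA with analytic
  Jacobian, rtol 10⁻⁶ / atol 10⁻⁹, restarted at every dose and window
  boundary. Undershoots below −100·atol are an error; smaller ones are
  clipped to 0.
- Population runs (`simulate_batch`): vectorized fixed-step classic RK4 at
  h = 0.01 d across all patients simultaneously, with steps shortened to
  land exactly on events and readouts, and clipping to enforce
  non-negativity. The gLV timescales here (|per-capita rates| ≲ 3 d⁻¹)
  make this step size conservative; agreement with the adaptive path is
  tested (≲10⁻⁴ relative, far below sampling noise) and halving h moves
  results by <10⁻⁶. It is ~100× faster than per-patient adaptive calls,
  which is what makes 2,000-patient × 500-strain studies tractable.
- Divergence: trajectories exceeding 10⁸ or losing finiteness are flagged;
  the affected patient is excluded from the response profile and counted
  in `n_excluded` (reported in every manifest). With default ranges this
  is 0–5 % depending on the strain's facilitative couplings.

## Sensitivity analysis

One-at-a-time sweeps around the null strain, response fractions read at 12
months post-cessation. Default grids: interspecies [−0.10, 0.10] (11
points), growth [0, 1], self-interaction [−0.04, −0.004]. The normalized
metric is `S = ((Y − Y0)/(P − P0)) · (P0/Y0)`. For interspecies terms the
reference is P0 = +0.01 with Y0 the response *at* P0 (the reference point
is inserted into the sweep); for growth and self-interaction the reference
is the null strain's own value. The per-sweep summary S uses the
least-squares slope of Y against P (robust to grid spacing); endpoint-wise
S values are also reported. The four-parameter grid evaluates all 3⁴ = 81
combinations of {−0.01, 0, +0.01} on (α_nAB→P, α_P→nAB, α_P→Li, α_P→oLB),
sorts by failure rate and attaches BH-adjusted chi-square tests against
the all-zero (null) row.

## Screening and statistics

Candidate strains are LHS-sampled over the same numeric ranges as the
population parameters with α_P→nAB constrained negative (a probiotic is
selected to inhibit nAB). Each strain's *modal class* is the response type
it elicits most frequently (final readout; ties toward nAB). PLS-DA is
two-block PLS (z-scored parameters vs centered one-hot classes, NIPALS via
scikit-learn) with 2 latent variables reported and a stratified 10-fold CV
classification rate. Best-fit strains minimize
`|pred₁₂ − 0.346| + |pred₂₄ − 0.484|` against the clinical 12/24-week
recurrence. Frequencies compare by Pearson chi-square without continuity
correction (n ≈ 2000 per arm), numeric data by two-sided Wilcoxon
rank-sum, with Benjamini–Hochberg adjustment where families arise.

## What the synthetic world does and does not establish

The generator reproduces the documented construction *procedure* — LHS
pool, equilibrium-behavior census, HMP-matched strata, calibrated dosing —
with generic text-stated parameter ranges; species-resolved ranges for the
three resident groups are not publicly available, so each group draws from
the same envelope. Relative statements (design orderings, which
parameters drive which response, regimen comparisons) transfer well and
are what the test suite asserts exactly. Absolute population percentages
depend on the distribution of nAB equilibrium abundance relative to the
probiotic carrying capacity (0.5/0.022 ≈ 22.7) and on how often BV+
equilibria are coexistence states; with symmetric per-species ranges the
BV+ conditioning enriches high-nAB patients (a max-order-statistic
effect), so several absolute endpoints sit above the reported values. A
green relative test therefore establishes the mechanism; absolute numbers
should be read as properties of this regenerated world. Host factors
(hormones, behavior), metabolite-mediated interactions and stochastic
demography are out of scope.

## Reproducibility

Every experiment is seeded; one global seed fans out to per-stage child
seeds (`SeedSequence`), all below 2³¹. `run_experiment` writes tidy CSVs
and a JSON manifest with the config hash, stage seeds and excluded-patient
count; identical configs yield byte-identical outputs.
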