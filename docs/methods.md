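# Methods

`esmnet` implements a group-level temporal-network analysis of
experience-sampling (ESM) affect data, together with a synthetic cohort
generator that makes every stage testable against known ground truth.
This note documents the models, the defaults and why they were chosen,
the numerical choices, and the known limitations.

## The scientific setting

Participants rate six momentary affect states — three positive
(*cheerful*, *relaxed*, *energetic*) and three negative (*irritated*,
*down*, *lonely*) — on 1–7 Likert scales, ten times a day for six days at
semi-random prompts ("beeps") between 07:30 and 22:30 with ~90-minute
mean gaps. Persons are nested in twin families. Each person also has a
90-item symptom checklist (SCL-90, sum range 90–450) at baseline and one
year later, and a 4-item childhood-experience screening sum (JTV, range
4–20). The analysis asks whether the lagged dynamics among affect states
at baseline differ between people whose symptoms later stay stable and
people whose symptoms increase — in particular whether the
symptom-increase group shows stronger coupling among negative states and
"vicious cycles" (mutually reinforcing directed cycles).

## Synthetic cohort generator (`esmnet.simulate`)

The latent affect vector follows a group-specific VAR(1) around
person-specific means:

    x_t = mu_p + B_p (x_{t-1} - mu_p) + delta t + e_t,
    e_t = phi e_{t-1} + u_t,   u_t ~ N(0, diag(sigma_u^2) (1 - phi^2))

- `B` (6×6, row = outcome, column = lagged predictor) is the
  ground-truth transition matrix; per-person matrices `B_p` add
  independent N(0, `slope_sd`²) deviations per entry (diagonal
  random-slope covariance, matching the fitted model). Spectral radius
  must be < 1.
- `mu_p` adds family-level and person-level normal intercept deviations
  (`family_sd`, `person_sd` per node) to the group means; twins share the
  family deviation.
- The first beep of each day is drawn from the exact stationary
  distribution of the stacked (state, innovation) process (solved as a
  12-dimensional discrete Lyapunov equation): an *overnight reset*. This
  mirrors the analysis convention that lags never span a night, and makes
  first-beep values independent of the previous evening.
- Observation: latent values are rounded half-up and clipped to 1–7
  (`observe="likert"`), or recorded directly (`observe="continuous"`).
  Missingness is beep-level MCAR and always whole-beep (all six items at
  once), because the analysis uses complete observations only.
- Beep schedules use stratified-interval jitter: the 900-minute day
  window is cut into `beeps_per_day` equal blocks with one uniform draw
  per block, giving strictly increasing times and a 90-minute mean gap
  without collisions.

Default parameter values and rationale:

| parameter | default | rationale |
| --- | --- | --- |
| families × persons | 40 × 2 | emulated group size (~80 persons) |
| days × beeps | 6 × 10 | emulated sampling design |
| `node_means` | group-specific, e.g. Stable (4.76, 5.03, 4.63, 2.24, 1.79, 1.69) | observed group mean levels |
| `innovation_sd` | 0.95 per node | yields within-person SDs ≈ 1.0–1.1 on the Likert scale, the item-selection target |
| `person_sd` / `family_sd` | 0.6 / 0.3 | between-person ICC ≈ 0.3 with a modest twin-shared component |
| `slope_sd` | 0.08 | visible but realistic between-person heterogeneity in dynamics |
| `resid_phi` | 0.0 | see below |
| `missing_rate` | 0.25 | matches the observed ~43/60 filled-in beeps |
| SCL-90 change | Stable N(−5.04, 4.95), Increase N(25.7, 22.5), Decrease N(−41.48, 33.09) | observed group change distributions; draws are rounded and resampled until both scores fit the 90–450 scale |
| SCL-90 baseline | Stable N(126.8, 26.1), Increase N(130.24, 34.0), Decrease N(168.3, 35) | observed group baselines (Decrease SD chosen, none reported) |
| JTV sums | round N(15.3, 2), truncated to [4, 17] | the cohort emulates the screened, below-population-median (≤17) half |

Two defaults deserve explanation:

- **`resid_phi = 0` in the generator.** When the predictors are the
  lagged outcomes themselves, a data-generating residual AR(1) changes
  what the fitted fixed effects converge to: the conditional expectation
  given the observed history is no longer `B(x_{t-1} - mu)` (the
  innovation carries information across beeps), and autoregressive
  estimates shift upward by roughly `phi * var(e)/var(x)` (measured:
  +0.13 at phi = 0.2). A generator with phi > 0 therefore has no
  well-defined "true B" for a recovery study. The default keeps all
  serial dependence in the VAR transition; `resid_phi > 0` remains
  available for sensitivity analyses, and the *estimator* still fits the
  AR(1) residual structure because real data motivate it.
- **Decrease-group change scores.** The prescribed truncation (resample
  until the follow-up score is ≥ 90) interacts with the large negative
  change mean: the realized Decrease mean change is ≈ −34 rather than
  −41.5. Stable and Increase means are unaffected.

Ground-truth transition matrices: both groups share a positive
cheerful–relaxed–energetic cluster with autoregressions of 0.16–0.22 and
one inhibitory edge from the positive cluster to a negative node. The
Increase matrix additionally contains an interconnected negative cluster
with a reciprocal reinforcing pair down → lonely = lonely → down = 0.15
(a 2-cycle), irritated → down = 0.06, lonely → irritated = 0.05, and two
inhibitory negative→positive edges; in the Stable matrix the negative
nodes are mutually unconnected. These magnitudes keep the injected
contrast qualitatively matching the reported group networks while staying
inside the stationarity region.

## Preprocessing (`esmnet.preprocess`)

- A beep is *complete* iff all six items are present. Persons with more
  than 30% missing beeps (denominator: the 60 scheduled beeps,
  configurable) are excluded; the boundary is strictly-more-than (18/60
  kept, 19/60 excluded).
- Items are person-mean centered over each person's complete
  observations. Only the lagged predictors enter centered; outcomes stay
  on the raw scale and person-level intercepts absorb level differences.
- Lag-design rows pair beep t with beep t−1 only when both are complete,
  consecutive in beep number, and on the same day, so no pair spans a
  night. The time covariate is the beep number over the whole period
  (rescaled to [0, 1] internally for conditioning; coefficients are
  reported per beep).
- Item diagnostics reproduce the item-selection criteria: pooled
  within-person SD per item (target band 0.7–1.4 around 1.0, configurable),
  pooled within-person correlations (|r| < 0.5), two-sample tests of
  person-mean levels between groups, and the max/min ratio of group
  within-person SDs (≤ 1.12; the "10–12%" criterion operationalized at
  its permissive end). Cronbach's alpha is provided for the JTV-style
  item sets.

## Group composition (`esmnet.groups`)

Change score = SCL-90 at follow-up minus baseline. The JTV screen keeps
persons strictly below the cohort median (ties excluded; configurable).
`tertile_split` ranks persons by a stable sort on (change, person_id) and
cuts near-equal thirds — Decrease / Stable / Increase — so group sizes
differ by at most one even with tied integer scores; the type-7 empirical
1/3 and 2/3 quantiles are reported as the cutoffs. Explicit cutoff
specifications (quantile pairs or raw values; ties to the lower group)
drive the multiverse grid, defaulting to quantile pairs
(25, 75), (30, 70), (33.3, 66.7), (40, 60). The Decrease tertile is
excluded from analysis by default because its inflated baseline severity
confounds network comparison; `assign_groups` always emits a
baseline-comparability report (pairwise Welch tests of baseline SCL-90)
so that this rationale is checked rather than assumed.

## Network estimation (`esmnet.estimate`)

For each outcome j:

    y_j,t = b_0 + sum_k b_jk x~_k,t-1 + b_time t + a_family + a_person
            + sum_k u_person,k x~_k,t-1 + u_person,time t + e_t

with diagonal random-effects covariance (family intercept; person
intercept plus seven person slopes) and residuals following a continuous
AR(1): corr(e_s, e_t) = phi^|Δt| with Δt in hours along each person's
analysis rows. Estimation is maximum likelihood (not REML) so AIC is
comparable across rungs sharing fixed effects.

Implementation: the marginal likelihood is evaluated exactly per family
block. The AR(1) correlation matrix of a Gaussian Markov chain has a
closed-form tridiagonal inverse and log-determinant; the low-rank
random-effects part enters through the Woodbury identity, and the
residual scale and fixed effects are profiled out. Blocks are padded and
batched, so one evaluation costs ~1 ms at 80 persons and a full fit runs
in about a second. The profiled objective over (9 log-SD ratios,
transformed phi, bounded to [0, 0.95)) is minimized with L-BFGS-B
(relative tolerance 1e-10, ≤ 200 iterations). The implementation is
verified in the test suite against (i) a dense-matrix likelihood oracle,
(ii) `statsmodels` MixedLM on the intercept-only rung, and (iii) an
independent R `nlme::lme` fit with `pdDiag` random effects and `corCAR1`
residuals, which agrees on fixed effects, log-likelihood and phi to
≥ 4 decimals.

Convergence ladder: full model → drop AR(1) → drop random slopes → drop
family intercept → pooled regression with person-cluster-robust errors.
A fit counts as converged when the optimizer succeeds and all standard
errors are finite and positive; otherwise the next rung is tried, and the
rung used is recorded. When the full model converges, the next rung is
also fitted (warm-started) and the lower-AIC model reported, mirroring
the best-fit-by-AIC model-selection rule. P-values use a normal
reference for coefficient/SE; no single degrees-of-freedom convention is
standard for these models. A residual-normality summary (QQ correlation,
skewness, kurtosis) accompanies each fit.

The network `W[j, k]` is the fixed effect of node k at t−1 on node j at
t; `significant_subnetwork` zeroes entries with p ≥ alpha (default 0.05)
while retaining the unfiltered weights. Edge lists are emitted as
(from = k, to = j); DOT export styles positive edges solid and negative
edges dashed.

The **fast (two-stage) tier** fits one OLS per person (outcome on the six
centered lags plus time; persons with fewer than 12 rows are skipped) and
averages the per-person coefficient matrices within a group, with
between-person standard errors and a t reference (n_persons − 1 df). It
targets the same estimand as the multilevel fit (their metric differences
agree within 0.02 on large cohorts without random effects) and its
person-level decomposition is what makes 10,000-permutation tests
affordable: the per-person regressions are label-invariant and are fitted
exactly once.

## Network metrics (`esmnet.metrics`)

- *Negative connectivity*: sum of |W[j, k]| over ordered pairs of
  distinct negative nodes, using all estimated paths.
- *Out-strength*: sum of a node's outgoing |weights| to the other nodes.
  Published analyses are not always explicit about whether such sums are
  signed or absolute, so both modes are provided and the mode used is
  recorded; absolute is the default so inhibitory edges still count as
  influence.
- *Cross-valence sums*: the 9 absolute entries from one valence block to
  the other (PA→NA and NA→PA).
- Self-loops are excluded from all summed metrics by default ("between
  nodes", "to the other nodes"); a flag restores them.
- *Reinforcing cycles*: simple directed cycles of length 2–3 within a
  node subset (default: the negative nodes) of the significance-filtered
  network whose every edge is positive; each cycle reports its weakest
  edge as its strength. "Vicious cycle" is thus operationalized purely
  structurally; no dynamical activation is simulated.

## Group comparison (`esmnet.compare`)

Observed metric differences (B − A, plus B/A ratio) are referenced
against permutation distributions: group labels are shuffled across
permutation units preserving group sizes, and both networks re-estimated
per replicate. The default unit is the family, so twins always carry the
same permuted label, respecting the sampling design; family-level
permutation requires group-homogeneous families and the person unit is
available otherwise. The default estimator inside permutations is the
fast tier (the full tier is supported with a configurable budget,
default ≤ 200 replicates). P-values use the add-one rule
p = (1 + #{|perm| ≥ |obs|}) / (1 + n_perm) — exact under exchangeability,
never zero. No multiple-testing correction is applied across metrics;
the report says so explicitly.

Several permutation schemes circulate for dynamic-network group
comparisons and published descriptions are often brief; the scheme
implemented here — group-label permutation over persons/families with
re-estimation per replicate — is one defensible, fully documented choice
rather than a reproduction of any particular unpublished procedure.
Its calibration is demonstrated empirically: under a null generator the
measured type-I error at alpha = 0.05 falls inside the exact binomial
band (see `simstudy.calibration_study`).

`multiverse_report` maps the pipeline over a list of group assignments
and summarizes, per qualitative feature (signed significant edge, or
reinforcing cycle, per group), the fraction of valid assignments in which
it appears; assignments with an empty analysis group are flagged and
excluded from the denominators.

## Built-in simulation studies (`esmnet.simstudy`)

`scripts/acceptance.py` re-runs these from scratch:

- **Metric enumeration**: 1,000 random networks, exact agreement with
  brute-force double loops and exhaustive cycle search.
- **Recovery**: 20 cohorts × 80 persons (40 families, 6×10 beeps, 25%
  missingness), continuous observation to isolate estimator behaviour
  from Likert coarsening; reports per-entry bias and RMSE. A degenerate
  cohort (all random-effect SDs zero) checks equality with pooled OLS.
- **Calibration**: 200 null experiments (two identical generators, 10
  families each), fast-tier permutation test at n_perm = 199.
- **Power**: 20 replicates of the default Stable-vs-Increase contrast
  (injected negative-connectivity gap 0.41 vs 0) at n_perm = 499.
- **Structure recovery**: 20 replicates of the full Likert pipeline at 80
  persons per group; rates of the down↔lonely cycle appearing in the
  Increase network and of a clean (no significant negative–negative
  edge) Stable network.
- **Composition**: a 239-person cohort at the emulated mixture
  (80/81/78); tertile sizes and baseline comparability behaviour.

These sizes keep the full battery around ten minutes on one CPU.

## Known limitations

- **Centering-induced attenuation.** Person-mean centering with ~45
  complete observations per person induces the classic dynamic-panel
  (Nickell) bias of order −(1 + rho)/T on autoregressive coefficients —
  about −0.03 here. This is a property of the method being modelled, not
  of the implementation: off-diagonal entries recover with |bias| < 0.01,
  but diagonal entries cannot beat the 1/T floor at this series length.
  Consumers comparing autoregressions across groups should note the bias
  is shared by both groups.
- **Multiplicity in qualitative structure checks.** Declaring a network
  "clean" requires all six negative–negative off-diagonal entries to be
  non-significant; with true-zero edges and tests of approximately
  correct size at alpha = 0.05 the expected clean probability is about
  0.95^6 ≈ 0.74 per replicate. The fitted tests run somewhat
  conservative here, so measured clean rates hover between ~0.75 and 1.0
  across simulation seeds; structure-recovery rates near 0.8 should be
  read with this in mind.
- The generator is MCAR and whole-beep; real ESM missingness is likely
  state-dependent. Likert floor effects for low-mean negative items
  (down, lonely) compress their within-person variance, as in real data.
- The generator does not model circadian mean trends, measurement
  reactivity, zygosity beyond a shared family intercept, or the extra
  morning/evening items that inflate observed beep counts above 60 in the
  emulated study; passing tests therefore speak to the statistical
  machinery under these idealized conditions, not to substantive
  conclusions about real cohorts.
- Contemporaneous (residual-correlation) networks, regularized
  estimation, and person-specific idiographic networks are out of scope;
  the analysis is group-level throughout.
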