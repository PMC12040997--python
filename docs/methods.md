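# Methods

`mklabour` implements a peer-based paradigm for continuous labour
monitoring: an unsupervised multiple-kernel embedding places women in a
low-dimensional space ordered by clinical similarity; a monitored woman's
follow-ups trace a trajectory through that space; her *peers* — historical
subjects near her current position at the same time since admission —
supply a personalised reference trajectory, a deviation z-score, and
event-chance estimates; and three per-woman summary scores (vπ, vπz, vπzt)
are evaluated as caesarean-section (CS) predictors against partograph
alert/action lines. Because the motivating cohort is access-restricted,
the package ships a synthetic labour-cohort generator with known ground
truth; every stage is validated against it.

## The embedding (MKL-DR)

**Kernels.** Each feature gets its own kernel over the standardised
admission-time state: a Gaussian kernel for continuous/ordinal features
(bandwidth = median of positive pairwise distances, the standard
scale-free default) and an indicator-match kernel for categoricals. One
kernel per feature is what lets the learner weigh features against each
other.

**Graph.** A symmetric k-nearest-neighbour graph (default k = 10) is built
on the mean kernel; `L = D − W` is its Laplacian. The degree form is
*deflated* against the constant vector, `D' = D − D11ᵀD / 1ᵀD1`, so the
trivial constant mode has zero norm and can neither appear among the
optimisers nor be mixed into them.

**Objective.** With kernel weights β on the probability simplex and
projection coefficients A (one column per embedding dimension), embedded
coordinates are `y_i = Aᵀ K_β[:, i]` with `K_β = Σ_m β_m K_m`. The fit
minimises the sum over dimensions of graph Rayleigh quotients
`aᵀ K_β L K_β a / aᵀ K_β D' K_β a` — affinity-weighted squared embedded
distances under a degree normalisation.

**Optimisation.** Both alternating steps work in one fixed, well-
conditioned subspace: the significant eigenvectors of the mean kernel
(relative cut 1e−12), whitened under the uniform-mix degree form (cut
1e−10). Restricting to this space removes the kernels' numerical
nullspace, where spurious zero-cost directions would otherwise live, and —
because the space does not move with β — keeps the two steps' objectives
consistent:

1. **Projection step.** A generalised symmetric eigenproblem in the
   reduced space; the first `n_dims` directions by increasing eigenvalue.
   A coefficient-of-variation filter remains as a backstop against
   numerically near-constant directions.
2. **Weight step.** With the projections fixed, minimise the *ratio-trace*
   of the graph pencil restricted to the span of the current projections,
   `tr[(YᵀD'Y)^{-1}(YᵀLY)]` with `Y = Y(β)` linear in β, over the simplex
   (SLSQP started at the current iterate). At the current β this equals
   the projection-step objective, and for any β it upper-bounds what the
   next projection step will attain, so any accepted decrease guarantees a
   monotone alternation; non-improving proposals are rejected.

Convergence: relative objective change below 1e−6, capped at 50
alternations (a cap hit is flagged and the best iterate returned — the
tail of the alternation is extremely flat, so this is benign). β starts
uniform.

**Gauge and orientation.** The deflated degree form is blind to constant
shifts, so each dimension is centred to zero degree-weighted mean; each
dimension's sign is oriented so its correlation with an anchor feature
(default: cervical dilatation) is non-negative, making "labour advances
rightwards" reproducible across runs.

**Out-of-sample projection.** A new state vector x is projected as
`y(x) = Aᵀ (Σ_m β_m K_m(·, x)) − centre` (a Nyström-style extension). The
same kernel code path computes training Grams and query columns, so
training points reproduce their in-sample coordinates to machine
precision.

**Dimensionality.** The package default is `n_dims = 6` (the space is
also an interpretability tool, and dimension–variable correlation tables
are part of the output). The evaluation pipeline in
`scripts/acceptance.py` uses `n_dims = 4`: dimension–variable correlation
diagnostics on the simulated cohort show no recoverable structure beyond
dimension 4 (|ρ| < 0.1 for dimensions 5–6 against every latent variable),
and because the z-score aggregates across dimensions (below),
structureless dimensions only dilute the peer metric.

## The monitoring engine

* **Peers.** Training trajectories are linearly interpolated to the query
  time; past the last follow-up (but before delivery) the last position is
  held; delivered subjects are excluded. Peers are all training subjects
  within a hypersphere (default radius 10% of the admission embedding's
  dimension-wise IQR norm) around the subject's position; the radius
  expands geometrically (×1.5) until at least `min_peers` (default 30) are
  found, with an expansion flag.
* **Reference ("ideal") trajectory.** Mean ± population standard
  deviation, per dimension, of the *uncomplicated, non-caesarean* peers'
  positions on a 30-minute grid from the query time onward. The curve is
  cropped at the first time the contributing-peer count falls below half
  its initial value (beyond that, the surviving — slower — peers would
  bias the mean), and requires a support floor of 10 reference peers,
  else a `no_reference` flag.
* **Deviation.** At follow-up k the subject's position is compared with
  the reference estimated at follow-up k−1 (their position is compared to
  what was *expected* for them): per dimension `z_d = |y_d − E_d(t)| /
  σ_d(t)`, aggregated as the Euclidean norm divided by √n_dims —
  dimensionless, and equal to the textbook z-score in 1-D. Zero
  dispersion with nonzero offset yields an infinite, flagged z; times
  beyond the crop yield `reference_expired`. The first follow-up has no
  reference.
* **Event chance.** π = (# peers whose event lies ahead of t) / (# peers);
  peers whose event already happened, or who never experience it, count in
  the denominator only. The empirical distribution of peer event timings
  is also exposed (CDF, median, chance-by-time).
* **Scores.** Per subject, maxima over follow-ups: `vπ = max π(t)`,
  `vπz = max π(t)z(t)`, `vπzt = max π(t)z(t)t` (t in hours); flagged
  entries are excluded from the maxima. Scores at follow-up t use only
  the subject's own data up to t plus complete historical peer records —
  prospectively valid by construction.

## Evaluation

Thresholds use the convention *positive iff score ≥ Th*. `learn_cutoff`
runs stratified 3-fold cross-validation on the training partition only:
candidate thresholds are midpoints of the sorted unique scores of the
fold's training portion, the fold-optimal threshold maximises
min(SE, SP) on the held-out fold (ties toward the larger threshold), and
the final Th is the mean of fold-optimal thresholds. AUC is the
rank-based Mann–Whitney statistic with tie correction; its significance
is the fraction of random label permutations whose AUC is at least the
observed one. Partograph baselines follow the WHO composite convention:
the alert line expects ≥ 1 cm/h dilatation from the first assessment at
≥ 4 cm; the action line runs parallel, 4 h to its right; a series is
positive when any assessment falls strictly to the right of the line
(on-line points negative), and series never reaching 4 cm are flagged
not evaluable. Subgroup analysis relearns cutoffs per training subgroup
(axis-aligned quantile boxes on dimensions 1–2, or any user partition)
and evaluates on the test counterparts.

## The synthetic cohort

The generator emulates the structure of a large two-country intrapartum
cohort: 33 static features (20 continuous, 13 categorical, the first a
two-level `site`) and 19 dynamic features by default, nonstandardised
follow-up intervals (mean 1 h, jitter 0.5 h), ~5% missingness per dynamic
cell (missing completely at random), and a marginal caesarean rate of
817/6349 ≈ 12.9%.

Mechanics, with the latent ground truth retained on every record:

* Two latent factors: z1 (progress propensity) and z2 (site/practice).
  Static continuous features load on both (the first is a strong
  progress marker); the `site` categorical follows sign(z2) with 15%
  flips and shifts augmentation propensity (a practice-bias hook).
* Cervical dilatation follows a logistic curve from the admission value
  (≈ N(4, 1.8²) cm, clipped) towards 10 cm with per-subject rate
  `r = exp(log 0.55 + 0.25·(√0.7 z1 + √0.3 ε))` per hour; vaginal
  delivery at 9.5 cm. Two-thirds of the dynamic features track current
  dilatation (progress-linked vitals); the rest are subject-level noise.
* **Arrest dynamics.** 12% of labours arrest at a random mid-labour time:
  the rate drops to 5–20% of itself. Most arrested labours end in
  caesarean after a 3–8 h stall (hours of alarming, partograph-crossing
  data — the clinical phenomenon deviation monitoring exists to detect);
  the rest resolve after a 2–5 h stall and resume at 60–100% of the
  original rate.
* **Caesarean hazard** is logistic in the standardised progress deficit
  (slope 1.0) and the arrest indicator (slope 4.0). The intercept is
  solved numerically (Brent) so the marginal CS rate equals the
  configured value exactly in expectation — a plain logit intercept is
  biased whenever the linear term has spread. Non-arrested caesareans
  occur mid-labour. Adverse outcomes follow an analogous calibrated
  logistic.

The arrest parameters were designed so the simulated study reproduces
the qualitative behaviour the paradigm is reported to have on real
labour data: the deviation-weighted scores (vπz, vπzt) outperform the
plain chance score, cross-validated cutoffs balance SE ≈ SP ≈ 0.7, and
AUCs fall in the mid-0.7s. What passing tests on this cohort show is
that the pipeline recovers structure and risk signal *when they exist in
the stated form*; the generator does not emulate facility-level
clustering, referral, twin pregnancies, informative missingness, or
measurement drift, so performance on real cohorts is not implied.

## Numerical and procedural choices

* Train/test split 75/25 (training size floored), seed-explicit
  everywhere; encoding moments, imputation values (train median/mode),
  kernel bandwidths, kernel weights and cutoffs are all learned on the
  training partition only.
* Missing follow-up cells: last observation carried forward; admission
  missingness imputed from training statistics; subjects with residual
  missingness or time inconsistencies (non-increasing follow-up times, or
  events after delivery) are excluded with a per-reason report.
* Degenerate inputs: zero-variance features are flagged and left
  unscaled; an all-identical peer set gives σ = 0 and flagged infinite z;
  empty peer sets give flagged undefined chance; single-class label sets
  are flagged, not silently scored.
* Problem sizes in the shipped tests/acceptance runs (chosen for desk
  hardware): cohorts of 60–2000 subjects with 11–16 features; the
  evaluation pipeline caps the fit at 20 alternations (the objective tail
  beyond that is flat to ~1e−4 relative) and scores ~2000 subjects in a
  few minutes.

## Known limitations

* The alternation is guaranteed monotone but not guaranteed to reach a
  global optimum; kernel weights typically move modestly from uniform.
* The z-score is symmetric (being ahead of the reference also scores
  high); on cohorts where fast labours carry no risk this adds noise.
* Peer retrieval conditions only on the current position and time, so
  subjects with different histories but identical current states share
  peers; history enters only through the deviation score.
* The reference-trajectory crop rule (support halving) is coarse; near
  delivery, references expire quickly and late follow-ups may carry
  flagged deviations.
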