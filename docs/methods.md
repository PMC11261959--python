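# Methods

## Model family

The package models two continuous traits, X and Y, measured on MZ and DZ
twin pairs.  Pre-causal trait deviations follow the standard bivariate ACE
decomposition: for twin *j* and trait *t*,

    u_tj = a_t A_tj + c_t C_tj + e_t E_tj ,

where the latent standard-normal factors correlate across co-twins (A: 1
for MZ, 0.5 for DZ; C: 1; E: 0) and, optionally, across traits within the
same component (`r_a`, `r_c`, `r_e`).  Causal regressions between the
phenotypes act within each twin; with the pair vector ordered
(x₁, y₁, x₂, y₂) and B holding the active regressions, the reduced form is

    y = (I − B)⁻¹ (ν + u),
    μ = (I − B)⁻¹ ν,     Σ = (I − B)⁻¹ Ψ (I − B)⁻ᵀ .

Ψ is assembled per component as D·(K_twin ⊗ K_trait)·D with D the loading
diagonal — the cross-twin cross-trait entry of each component is the twin
correlation times `r` times the two loadings, the standard behavior-genetic
convention.

Because the sampling unit is a pair and each member may belong to either
causal subpopulation, a two-direction mixture implies four classes per
zygosity group: concordant X→Y, concordant Y→X, and two discordant
combinations.  Twin ordering within a pair is arbitrary, so the discordant
classes are equated in parameters and in mixing proportion (ω₃ = ω₄).
Class-specific structural intercepts ν (two per trait, shared across twins
and zygosity groups) carry the between-class mean differences that make
the mixture identifiable; covariance differences between classes are
second-order and contribute less information.

Identification: of the five covariance carriers (b_xy, b_yx, r_a, r_c,
r_e) at most three are estimable in one model.  The base mixture fixes
r_a = r_c = r_e = 0 (covariance purely causal); the extended variant frees
r_a, equated across classes (`confound_ra_free=True`).

Six families share one estimator surface: `mix4`, `mix2` (discordant
proportions fixed to zero), `doc_xy`, `doc_yx`, `doc_bidir` (reciprocal
causation, one class), and `cholesky` (saturated bivariate ACE with all
three r's free in factor form; nests the unidirectional DoC models).

Free parameters: 6 loadings + active b's + direction-specific intercepts,
plus mixing proportions (2 free per zygosity group for `mix4`, 1 for
`mix2`, after the simplex and discordant-equality constraints):
16 / 14 / 9 / 9 / 10 / 11 for the six families.  Raw-data (FIML) degrees of
freedom are observed data points minus free parameters, and
`AIC = −2LL + 2k`; the lowest AIC wins, with differences below 0.01
reported as ties.

## Estimation

The −2 log-likelihood sums, over pairs, the log of the ω-weighted class
densities for that pair's zygosity, evaluated with log-sum-exp.  A
reference implementation (`minus2_loglik`) defines the quantity; a
vectorized evaluator (batched 4×4 Cholesky factorizations across classes)
is used inside the optimizer and is tested to agree to machine precision.

Optimization is L-BFGS-B on an unconstrained scale: log for non-negative
loadings and factor diagonals, atanh for correlations, and a multinomial
logit for mixing proportions that hardwires ω₃ = ω₄ (logits are log-ratios
against the discordant class).  Convergence uses a relative −2LL change
below 1e-10 and projected-gradient norm below 1e-5, capped at 500
iterations.

Starting values are method-of-moments: univariate ACE components from the
MZ/DZ cross-twin covariances (floored at 5% of the trait variance and
shrunk by 0.8 to leave room for causal variance), causal effects from the
pooled cross-trait regression, and class means from a 2-means clustering
of the per-pair trait averages.  The default 10 starts comprise the moment
start, a cluster-swapped start (guarding the direction-labeling local
optimum), and Gaussian perturbations (sd 0.25) of the moment start; study
drivers use 3–4 starts, which the perturbation experiments showed is
enough given the strength of the moment start.  The best optimum wins;
exact ties go to the smallest start index, making fits reproducible from
(data, seed).  Class labels are structurally pinned (class 1 *is*
concordant X→Y), so no post-hoc relabeling is needed.  Estimated component
weights below 1e-4 are logged but the fit is kept.  Missing data: pairs
with missing values are dropped by default; `missing="marginalize"`
instead integrates each pair's density over its missing entries.

## Posterior classification and entropy

Posterior class probabilities are Bayes' rule over the fitted class
densities, computed in log space.  The relative entropy index

    Ent = 1 − Σᵢ Σ_c (−p_ic ln p_ic) / (N ln C),   0·ln 0 ≡ 0

pools all pairs with C = 4 by default (the classes align across zygosity
groups; a per-zygosity split is available).  It is 0 for uniform
posteriors and 1 for degenerate ones, invariant to row order and class
permutation, and non-decreasing under sharpening of any row.  Entropy can
be evaluated from a model fitted to the same data (the full procedure,
used for reported numbers) or at the generating parameter values ("oracle"
mode), which isolates the information content of a design and is used in
fast property tests; the two agree closely in the regimes tested.

## Simulation design

Two independent samplers generate twin data and cross-validate each other:
a moment route (draw each pair from its class's expected 4-variate
Gaussian) and a structural route (draw the latent A/C/E scores with their
twin/trait correlations and solve the causal system).  Their agreement in
distribution is a test invariant.  All randomness descends from one root
seed through fixed-offset `SeedSequence` children per zygosity and class.
Class counts are multinomial by default; a fixed-quota mode (largest
remainder) reproduces exact-proportion designs and is used for the
replication studies.

`make_params` builds generating parameters from interpretable quantities:
per-trait (A, C, E) variance components, causal effects, and class means
in structural form — every class shares base intercepts, the X→Y class is
offset by −Δ/2 and the Y→X class by +Δ/2 per trait.  With a nonzero base
intercept the causal path itself displaces the downstream trait's observed
mean (X→Y: E[y] = ν_y + b_xy ν_x), so causal-effect size contributes to
class separation — the mechanism by which opposing causal processes
produce observable mean differences.

### Study conditions and reconstructed constants

The replication experiments hold these conditions (all in
`mixdoc.study.STUDY_DEFAULTS`):

* **Variance shares** — trait X (0.7, 0.1, 0.2), trait Y (0.2, 0.5, 0.3):
  deliberately different modes of inheritance, which is what lets the
  cross-twin cross-trait pattern discriminate causal direction.
* **Model-comparison scenarios** — heterogeneous: equal quarters,
  b = 0.5 both ways, class intercept gap 1.0, unit pre-causal trait
  variance, 1000 pairs per zygosity, 20 replications; homogeneous:
  reciprocal causation with b_xy = b_yx = 0.3, no mean gap.  Reported
  quantities are AIC-win frequencies across replications.
* **Entropy grid** — 5000 pairs split evenly across zygosities and
  classes; defaults between sweeps: pre-causal variance 0.2 per trait,
  b = 0.3, intercept difference 0.3, base intercept 0.5.  Four sweeps vary
  one design axis each: class mean differences, causal effect sizes,
  additive genetic share of trait Y (A trading against C with E fixed,
  trait X pinned at a² share 0.7), and genetic confounding r_a.

The grid constants are *reconstructions*: the reference experiments did
not publish them, so they were chosen once so that oracle-posterior
entropy reproduces the published mean-difference and causal-effect
entropy patterns as closely as possible, and frozen.  The published grid
appears internally inconsistent with any single default set (its
(0.5, 0.5) mean-difference cell exceeds its (1.5, 0.1) cell under every
isotropic design we examined), so two cells remain off by 0.15–0.2 while
the extreme-separation cell (entropy ≈ 0.99 at Δ = 1.5 on both traits) and
all monotone trends reproduce.  Only those robust features are asserted.

### What the generator does and does not emulate

Data are exactly multivariate normal within class, with no measurement
error, no missingness, equal class means across twins and zygosity
groups, and known class structure.  Passing tests therefore demonstrate
correctness of the moment algebra, likelihood, optimizer and
classification machinery under the model's own assumptions — not
robustness to the non-normality, scaling artifacts, assortative mating or
G×E covariance that real phenotypes exhibit.  Departures from within-class
normality in particular can masquerade as spurious mixture components.

## Numerical choices

* Positive-definiteness is enforced where a proper density is required
  (Cholesky factorization failure raises, naming the class); loadings may
  be exactly 0 in the structural simulator (deterministic twins).
* Reciprocal effects with b_xy·b_yx = 1 make (I − B) singular and raise.
* Log-sum-exp stabilizes all mixture sums; the fast path subtracts the
  per-pair max class term.
* Monte-Carlo oracle tests use 10⁵–10⁶ pairs with absolute tolerance 0.01
  on moments; optimizer-level nesting inequalities allow 0.1 on −2LL.
* Replication counts (20 for model comparison, 10 for entropy and
  recovery) and 2000–5000-pair samples are desk-scale choices that keep
  the full study on one core in minutes; the CLI `--full` flag runs the
  1000-replication version.

## Known limitations

* Finite-sample mixture ML is slightly biased (≈0.02 on some intercepts
  at 2000+2000 pairs); recovery is assessed against Monte-Carlo standard
  errors, not asymptotics.
* On homogeneous data the 16-parameter mixture typically gains several
  −2LL units over the generating single-class model by fitting noise; AIC
  (not −2LL) is the appropriate comparison, and with small samples the
  penalty can occasionally fail to overcome that gain.
* No standard errors, bootstrap, or likelihood-ratio tests for the number
  of classes (mixture-order tests violate the usual regularity
  conditions); no dominance variance, sex limitation, ordinal measurement
  models, or more than two traits.
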