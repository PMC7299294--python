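# Methods

`sowlong` implements a complete genetic evaluation of sow longevity for
a multi-breed pig breeding program — two purebred maternal lines (A, B)
and their F1 cross (X) — together with a synthetic-data generator that
reproduces the statistical structure such an evaluation assumes.  This
note records the models, the generator's assumptions, the numerical
choices, and the limits of what the simulation-based tests demonstrate.

## Traits

Three longevity definitions are built from per-parity sow histories:

* **LGY12** — whether the sow was inseminated for a second litter within
  85 d of first farrowing (0/1; the boundary day counts as a success).
* **LGY15** — the number of litters within 570 d of first farrowing,
  capped at 5; the first farrowing counts, so the minimum is 1.
* **Survival** — a per-parity repeatability trait: a sow culled after
  parity *k* contributes records 0, …, 0, 1 for parities 1…*k*; a sow
  still alive contributes only zeros and is censored.

Linear models cannot carry censored records, so sows whose 85-d or
570-d window has not elapsed (and who are still alive and below the
LGY15 cap) are excluded with a logged reason.  A culled sow's LGY15
count is complete regardless of the window, and is kept.  Cohort
filters retain farms with ≥ 50 animals and countries with ≥ 1,000
animals and ≥ 2 breeds (defaults; configurable); because removing a
farm can change country totals, the two rules are iterated to a fixed
point, which also makes the filter idempotent.

## Model

All traits are analysed with the linear mixed model

y = Xb + Zu + Vv + e,   u ~ N(0, K ⊗ G0),  v ~ N(0, I σ_v²),  e ~ N(0, R)

where K is the pedigree relationship matrix **A** (variance-component
estimation) or the single-step matrix **H** (breeding-value
estimation), G0 the genetic covariance over trait slots, and v a common
birth-litter effect.  Survival is a repeatability model — repeated rows
in Z — deliberately **without** a permanent environmental effect: with
a single absorbing outcome per sow, the parity-to-parity covariance
beyond u and v is not estimable, and model fit is best without it.

Fixed effects follow the per-trait convention: dam parity, herd at
first insemination, year of first insemination and country for
LGY12/LGY15; parity, dam parity, herd-year of insemination, country and
season of insemination plus a fixed regression of weaned count for
Survival.  The weaned regression defaults to one slope per herd (the
natural reading of a regression "on herd at farrowing"); a single
global slope is available by passing `covariate_by={"n_weaned": None}`.
In multi-breed "different" mode the response maps to breed-specific
slots; since no animal records two slots, the residual never couples
slots and R stays diagonal (the standard missing-record treatment).
Fixed effects are nested within slot.  One reference level per factor
is dropped deterministically (first in sort order) and remaining linear
dependencies (e.g. herd within country) are detected on the Gram matrix
and dropped with a log message.

## Relationship matrices

* **A** by the tabular method; **A⁻¹** directly from the pedigree with
  Meuwissen–Luo inbreeding coefficients (unknown parents are unrelated
  founders; no unknown-parent groups).
* **G** by VanRaden method 1, centred at pooled allele frequencies of
  the genotyped set (within-breed frequencies are a config switch).
  SNPs are first filtered: segregating in all three populations, then
  within-population MAF ≥ 0.01; removal reasons are counted in that
  fixed order (a SNP passing the MAF rule everywhere is automatically
  segregating, so the reverse order would leave the segregation counter
  empty).
* **A22** for the genotyped subset via the factorisation A = T D T'
  (one sparse triangular solve; full A is never formed).
* **H⁻¹ = A⁻¹ + [0, 0; 0, τ G_w⁻¹ − ω A22⁻¹]** with
  G_w = 0.95 G + 0.05 A22 and τ = ω = 1 by default — standard
  single-step blending; no G-to-A22 tuning is applied by default.
  The default pipeline uses A for REML and H for EBVs.

## REML

Variance components are estimated by average-information REML with EM
fall-back steps, on A-based models only.  The restricted log-likelihood
is always evaluated exactly through the mixed-model-equation
factorisation, −2ℓ = log|G| + log|R| + log|C| + y'Py, using a sparse LU
with the symmetric MMD ordering (dramatically less fill than the
default column ordering on these symmetric systems).

Two trace engines serve the updates:

* **small systems** (≤ 3,000 equations): dense C⁻¹ gives exact EM
  traces and the exact score.
* **large systems**: the AI matrix needs only solves and is always
  exact; the score is obtained by forward finite differences of the
  exact log-likelihood (one extra factorisation per parameter, h = 1e-4
  of the parameter), and the identity tr(P V_y) = n − rank(X) — V_y is
  linear in the parameters — recovers the largest parameter's trace
  from the others, saving one evaluation.  This keeps the large path
  free of stochastic trace estimation; Monte-Carlo probes remain only
  inside the large-path EM update, which is used for warm-up and
  fall-back.

Safeguards: three EM warm-up iterations before AI; each AI step is
capped at a factor 5 change per variance, halved until the parameter
vector is admissible, and halved again (up to six times) if the exact
likelihood would decrease; a singular candidate system evaluates to −∞
and is backed away from.  Variances are floored at 1e-8 of the
phenotypic variance and G0 is projected onto the PSD cone.  Convergence
requires relative parameter change < tol (1e-8 exact path, 1e-4 large
path) and a stable likelihood.  **Non-convergence is a first-class
outcome**: the last iterate, the flag and the full history are
returned, mirroring the fact that multi-breed survival analyses of this
kind are known not to converge.  Standard errors come from the inverse
AI matrix; heritabilities and genetic correlations carry delta-method
SEs.

The heritability of the mean of n survival records is
h_n² = σ_g² / (σ_e²/n + σ_g² + σ_v²); it reduces to h² at n = 1 and
rises to σ_g²/(σ_g² + σ_v²) as n → ∞.  `feasible_litter_variance`
inverts the formula for σ_v² on a unit phenotypic scale.

## Validation

Forward validation masks phenotypes of animals born after breed-specific
cutoff dates (the crossbred cutoff may be later, keeping enough
crossbred training records), selects the n youngest masked animals per
breed with an anchor-trait observation, refits, and scores
cor(CP, EBV)/√h², where CP = y − Xb̂ − Vv̂ from the full-data fit; for
the repeatability trait the per-animal CP is the mean of corrected
per-parity records (sum and first-record variants are available).  The
h² in the denominator defaults to the all-breed estimate.  EBV sets can
be compared by Pearson correlation over common animals, and information
flow over time is summarised as SD(EBV)/σ_u per birth year, optionally
for genotyped animals only.

## Synthetic data

The generator reproduces the study conditions rather than any real herd:

* **Pedigree** — two lines bred for a configurable number of
  generations (the founder generation counts), each dam producing a
  fixed number of litters with Poisson litter sizes; a configurable
  fraction of matings are crosses, 80 % A-sire × B-dam by default
  (crossbreds predominantly have A-line sires); X animals are terminal.
* **Genotypes** — line-specific founder allele frequencies drawn
  uniformly on a MAF range, then gene dropping (fair coin per locus per
  meiosis).  No linkage map: LD arises only from co-ancestry.
* **Breeding values** — each animal carries a 3-slot vector (its trait
  expressed in A, B and X environments) flowing down the pedigree with
  inbreeding-adjusted Mendelian sampling.  Slot variances are the
  per-breed heritabilities; slot correlations r(A,X) and r(B,X) are the
  configured purebred–crossbred correlations and r(A,B) = r(AX)·r(BX),
  which keeps the matrix PSD for any admissible pair.  Defaults follow
  the published single-breed estimates (LGY12 0.074/0.063/0.073, LGY15
  0.096/0.132/0.049 on the observed scale; Survival on the liability
  scale, converted from 0.017/0.026/0.013 at the per-breed culling
  rates) and correlations (LGY12 0.308/0.231, LGY15 0.485/0.614;
  Survival reuses the LGY15 values because no estimate exists — the
  correlation is expected to be of similar size).
* **Lifetime records** — per parity, a culling liability sums the sow's
  Survival breeding value, her birth-litter effect, herd / year /
  country / season / dam-parity effects, a weaned-count term with a
  small negative slope (fewer weaned piglets → higher culling risk, so
  the fixed regression has signal) and an i.i.d. residual; the sow is
  culled when it exceeds a threshold calibrated so the *marginal*
  culling probability equals the configured per-breed, per-parity rate
  (0.22 / 0.12 / 0.07 by default, matching the published means).  Sows
  alive at the observation end are censored.  Calendar defaults: first
  insemination at ~240 d of age, 115 d gestation, ~33 d
  weaning-to-service (≈ 148 d farrowing interval); these distributions
  are declared, not estimated from any source, as only the 85-d and
  570-d windows are documented.  No permanent environmental effect is
  simulated by default (a config switch adds one for sensitivity
  analysis), and there is no selection-on-EBV feedback.
* **Quantitative records** — a second generator emits one continuous
  record per animal with exactly the configured h², litter fraction and
  unit phenotypic variance.  It exists because LGY12/LGY15 are
  *emergent* functions of the culling process (their realized
  heritabilities cannot be set directly), while recovery experiments
  need the generating truth exactly.

**What the tests do and do not show.**  Passing recovery tests show the
estimation machinery is correct under the generating model: REML
recovers a 0.13 heritability within ±0.01 (mean of 20 replicates of
~20,000 recorded sows in paternal half-sib/full-sib families over three
generations) and a 0.614 purebred–crossbred correlation within ±0.1
(20 replicates of ~15,000 records with shared sires across pure and
cross litters).  They do not show that real sow data satisfy the model:
real histories add genotyping error, heterosis, selection on EBV,
time-varying culling policy and G×E, none of which are simulated.  One
structural mismatch is reproduced faithfully and documented rather than
hidden: the liability-to-observed-scale conversion
h²_obs = h²_liab·z²/(p(1−p)) is recovered within ±0.01 on *first-parity*
records, but whole-history repeatability analyses inflate the
per-record h² because a sow's record count depends on her own outcomes
(at most one "1" per sow) — the known price of the repeatability
approximation for sequential survival.

## Problem sizes and runtime choices

The standing test suite runs the recovery experiments at the sizes
stated above (chosen as the smallest populations at which the stated
tolerances are comfortably identified); the acceptance script uses
three replicates per recovery quantity at the same per-replicate sizes.
Direct sparse solves are used up to 20,000 equations and Jacobi-
preconditioned conjugate gradients above (relative tolerance 1e-10,
5,000 iterations, residual history surfaced on failure).

## Known limitations

* No unknown-parent groups, metafounders, APY, dominance, or marker
  effect back-solving.
* REML is A-based only (matching the pipeline's division of labour);
  H-based REML would require the same machinery with K = H and is not
  exposed.
* The delta-method SEs understate uncertainty near parameter
  boundaries, where genetic-correlation estimates pile up at ±1 on
  weakly informative data — visible in the recovery experiments as
  occasional boundary replicates, and the reason the multi-breed binary
  survival configuration legitimately fails to converge.
* The cohort filters count unique animals per farm/country on the trait
  table being filtered, not on an external census.
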