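# Methods

## Model and assumptions

The package models the time evolution of a genotype's phenome as a
time-invariant linear dynamical system on the trait vector
x ∈ ℝᵖ:

    x_{t+1} = A x_t,    A ∈ ℝ^{p×p},

with one step per calendar day. Linearity of the *operator* does not assume
traits change linearly in time — a linear system generates rich
exponential/oscillatory trait curves — but it does assume time-invariance
over the observation window and that genotype differences act through the
operator and the initial state.

Two estimators of A are provided.

**Classical DMD.** A = X₂X₁†, where X₁/X₂ stack all one-day snapshot pairs
and † is the Moore–Penrose pseudoinverse (singular values below
`rcond · σ_max` truncated; default `rcond = max(p, n_pairs) · eps`, the
standard numerically safe cutoff). This is the Frobenius-optimal one-step
operator; with p comparable to the number of snapshot columns it interpolates
noise.

**Schur-reduced DMD.** The operator is projected on the r leading POD modes
of X₁ = UΣVᵀ, giving the reduced operator Ã = UᵣᵀX₂VᵣΣᵣ⁻¹, whose *real*
Schur form Ã = QᵀRQ yields projected modes Φ = X₂VᵣΣᵣ⁻¹Qᵀ and the rank-r
reconstruction Aᵣ = ΦRΦ†. The real (not complex) Schur form is used because
downstream genomic prediction needs real scalars; complex-conjugate
eigenvalue pairs remain as 2×2 diagonal blocks of R. The nonzero spectrum of
Aᵣ equals the spectrum of Ã by construction (proved by the identity
AᵣΦ = ΦR and verified to 1e−8 in the tests).

A note on conventions: with a conventional Schur routine returning
Ã = Z R Zᵀ, we store Q = Zᵀ so that the identity Ã = QᵀRQ holds, and build
the projected modes with the factor Z = Qᵀ. Writing the modes with Q itself
would produce a ΦRΦ† that no longer restricts to Ã on the data subspace;
the exactness and spectrum tests pin the correct algebra down.

## Gap-aware snapshot construction

Phenotyping designs often measure in blocks (here: 5 consecutive days, then
a 2-day gap, five times, starting at day 15 — 25 timepoints over 33 days).
Snapshot pairs are built within blocks only: X₁ takes every within-block
timepoint except each block's last, X₂ every one except the first, so every
column pair spans exactly one calendar day and no pair crosses a gap.
Blocks with a single timepoint contribute nothing (warning); a line errors
only when it yields zero usable pairs.

Forecasting across a gap of g missing days supports two policies:
`unit_step` applies A once per measured step (the library default), `power`
applies A^(g+1), i.e. one application per calendar day. When the underlying
process genuinely advances through the gap days — as the synthetic generator
does, and as any real plant does — only the `power` policy can be exact, and
recursive forecasts inherit any gap error into all later timepoints;
evaluations in the acceptance script therefore use `power`. Both policies
are exposed because with real, imperfectly linear data the single-step
variant can be the more robust extrapolation.

## Canonical form and cross-genotype comparability

The SVD and Schur decompositions are unique only up to column signs and
block ordering, but the method's core assumption — an entry of Φ or R means
the same thing in every genotype — requires a fixed convention. Three
normalizations are applied per model, each an orthogonal sign change or
similarity that leaves Aᵣ untouched (tested to 1e−10):

1. columns of Uᵣ oriented positively, Vᵣ/Ã/Q compensated;
2. diagonal blocks of R reordered by descending eigenvalue modulus
   (LAPACK `trexc` orthogonal swaps; stable selection, first-maximum wins),
   Q and Φ compensated;
3. columns of Φ oriented positively, R and Q compensated.

Orientation uses the continuous functional sign(Σᵢ sign(vᵢ)vᵢ²) — the
difference between positive- and negative-part squared mass — rather than
the sign of the single largest-magnitude element: an argmax anchor switches
identity between two near-tied elements of opposite sign, silently flipping
whole columns between genotypes and destroying entry heritability (we
observed the entry-to-dosage linearity collapse from R² ≈ 1 to ≈ 0.3 in a
noise-free population before adopting the continuous functional).

No per-model convention can be globally continuous, so the entry-extraction
step additionally **harmonizes** orientations across the population: each
line's Uᵣ and Φ columns are sign-aligned to the first line's by inner
product, which in the coherent (shared mode basis) regime is bounded away
from zero. All flips leave every Aᵣ — and the reassembled predicted operator
A_P, which is invariant under Φ→ΦD, R→DRD — unchanged.

## Marker models

**GRM.** VanRaden method-1: K = WWᵀ / (2Σpⱼ(1−pⱼ)) with W the
allele-frequency-centered dosages and monomorphic markers excluded. The
diagonal averages ≈ 1 under this scaling (checked within ±0.2).

**GREML.** The single-GRM animal model y = μ1 + g + e,
g ~ N(0, σ²_g K), e ~ N(0, σ²_e I), is profiled over h² ∈ [0, 1] after
rotating by the eigenvectors of K (each restricted-likelihood evaluation is
then O(n)). Optimization is a 41-point coarse grid followed by bounded
Brent refinement to 1e−8 (the grid guards against flat or boundary-hugging
profiles); boundary optima are reported with a flag, interior estimates
clipped to [1e−6, 1−1e−6]. Unbiasedness at true h² ∈ {0.2, 0.5, 0.8}
(k = 500, m = 2000, 50 replicates) is exercised by the acceptance suite.

**RR-BLUP.** y = μ1 + Mu + e with i.i.d. normal marker effects. Markers are
centered inside the fit and the centering stored, so prediction of new lines
is self-contained. The ridge ratio λ = σ²_e/σ²_u is REML-estimated over
log λ ∈ [−10, 10] on the spectral decomposition of the n×n kernel MMᵀ —
reused across the dozens of entry traits sharing a training fold — and
β = Mᵀ(MMᵀ + λI)⁻¹(y − μ̂1). At fixed λ this equals the primal ridge
solution (MᵀM + λI)⁻¹Mᵀ(y − μ̂1) to 1e−8 (tested), and the REML λ matches a
1000-point grid search within one grid step (tested). The intercept is
handled by GLS projection, not penalized. Markers are centered but not
variance-standardized; entries of structurally constant value (e.g. the
exact-zero subdiagonal of a triangular R) get a constant predictor rather
than an error.

## Trait-panel reduction

Image-derived panels are hugely redundant. For each trait a k×k Euclidean
distance matrix over the full line×time profiles is computed; the Mantel
correlation between two traits is the Pearson correlation of the strict
lower triangles of their distance matrices (this reading makes the Mantel
name literal; a plain flattened-profile correlation is available behind
`method="flat"`). Traits joined by Mantel r above a threshold (default
0.96, signed comparison by default with an absolute-value switch) form an
unweighted graph; deterministic greedy (CNM-style) modularity communities
define clusters, singletons included; each cluster is represented by the
member with the highest mean GREML h² over the timepoints (ties broken
lexicographically and logged). Min–max normalization maps each trait to
[0, 1] over all lines and timepoints jointly — appropriate for
heterogeneous real units, but note that the affine shift makes exactly
linear latent dynamics affine in the observed coordinates, so synthetic
benchmarks that assert exact recovery feed unnormalized (already
commensurate) values instead.

## Rank selection

For candidate ranks (default 2–6) the Ã entries are screened for GREML
heritability and cross-validated RR-BLUP predictability using only the
training–testing lines (any validation slice of the plan is excluded). The
chosen rank is the largest candidate whose mean Ã-entry predictability
exceeds a floor (default 0.1); if none qualifies the smallest candidate is
returned with a no-signal flag. Because the leading sub-block of Ã is
rank-stable, the mean dilutes as r grows and the rule bites once the added
entries carry no marker signal; in strong-signal regimes it deliberately
errs toward larger r.

## The pipeline

Training fits the canonical Schur DMD per line, harmonizes orientations,
extracts the {Φ, R} entries (p·r + r² per line), and fits one RR-BLUP per
entry on a shared kernel eigendecomposition. Lines with unidentifiable
dynamics are dropped with a logged reason; more than 20% drops is an error.
Prediction assembles Φ_P and R_P entry-by-entry and reconstructs
A_P = Φ_P R_P Φ_P† (pseudoinverse fallback with a warning if Φ_P is
rank-deficient). Cross-validated evaluation shares one CVPlan — fold
assignments are a pure function of (seed, iteration, n_lines) — between the
dynamic modes and the snapshot baseline, so comparisons are paired; an
optional validation fraction per iteration is excluded from both training
and testing (it exists for the rank-selection screen). Accuracy is the
Pearson correlation across the test lines per trait × timepoint, averaged
over folds; undefined correlations (constant vectors, < 3 test lines) are
stored as missing and excluded from means, never coerced to zero, which
would bias averages toward the null. MSE is computed on the modelling
scale. Two scenarios: `full_series` (predict timepoints 2..T) and
`holdout_tail` (models trained on the first n timepoints; forecasts start
from the first or the last trained timepoint). The
heritability-consistency analysis correlates each trait's coefficient of
variation of h² across time with its mean accuracy (two-sided
t-distribution p-value), reproducing the observation that temporally stable
heritability predicts forecastability.

## Synthetic data: what it emulates, and what it does not

The generator realizes the model class exactly: independent biallelic
markers (dosages Binomial(2, f), f uniform on a MAF range, realized
MAF ≥ 0.01 enforced), a shared orthonormal mode basis Φ0 (p × r_true), and
per line a reduced operator R(g) = R_base + genetic + residual whose entry
variances are rescaled so the realized genetic fraction equals the target
entry h² exactly. Base eigenvalues are spread over the interior of the
spectral interval with separated moduli, so small perturbations neither
leave the interval (lines that do are rescaled back) nor create spurious
complex pairs. Latent states advance through gap days; observations add
i.i.d. Gaussian noise at measured days only. Initial states are
x₁ = Φ0·c₁ with genotype-dependent coefficients.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| entry effect scale | 0.03 | operator entries vary by a few percent across a population; larger variation leaves the regime where factor entries are comparable across lines |
| leading base eigenvalue | 0.98 (interval 0.70–1.05) | min–max-normalized saturating traits cannot amplify across-line differences exponentially; a leading mode just below 1 keeps differences persistent while letting compounded prediction errors dominate at long horizons |
| initial-coefficient spread | 0.3 (h² = entry h²) | gives across-line trait sd ≈ 0.1 against 0.05 measurement noise, matching moderately heritable normalized phenomics traits and a nonzero snapshot-GP baseline |
| causal markers per entry | 20 | oligogenic architecture |
| measurement noise sd | 0.05 | typical residual on a [0, 1] scale |

Benchmark presets: `perfect` (k=100, m=40, p=10, entry h²=1, no noise,
effect scale 0.005) sits deliberately in the small-perturbation regime
where the genotype → canonical-entry map is effectively linear — i.e.
inside RR-BLUP's hypothesis class — which is what makes near-exact pipeline
recovery a meaningful correctness criterion rather than an accident;
`heritable` (k=300, p=20, m=1000, entry h²=0.5, noise 0.05) is the
qualitative-behaviour benchmark; `null` removes both the marker signal and
the systematic initial-state spread, because a recursive forecast started
from an informative measured state shows persistence accuracy even with
zero genetics — the null control must close every information channel to
measure what the pipeline could manufacture; `maize_like` reproduces the
dimensions of a field-scale panel (k=330, p=50, T=25 in five blocks).

What passing these benchmarks does **not** show about real data: real trait
dynamics are neither linear nor time-invariant (growth stages change the
operator), markers are linked rather than independent, operator entries are
not additively oligogenic, measurement noise is heteroscedastic, and the
shared-mode-basis assumption only holds approximately (a rotation parameter
exists to probe its violation). The synthetic results certify the
machinery and its self-consistency, not field performance.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale by design: exactness
checks at k=50, p=20; GREML recovery at k=500, m=2000 with 50 replicates;
the pipeline benchmarks at k≤300 with 5×5-fold cross-validation (the full
protocol of 20×5 for entry screens and repeated 5-fold with validation for
trajectory CV is configuration, not code). Every random draw flows from an
explicit seed; CLI reruns are byte-identical, and prediction reports are
written with full float precision (`repr`) and read back with round-trip
parsing so that write → read is bit-exact.

## Known limitations

* A single operator per genotype: no environmental covariates, no
  time-varying dynamics.
* Entry-wise independent RR-BLUPs ignore the covariance between factor
  entries; a multi-trait model could share information.
* The Schur-entry ordering convention can still mis-align genotypes whose
  eigenvalue moduli cross (nearly tied blocks), and harmonization assumes a
  coherent population; heritability of the affected entries degrades
  gracefully rather than failing loudly.
* GREML uses one genomic relationship matrix; no GxE, dominance or
  epistatic kernels.
* The baseline is a single-timepoint RR-BLUP; richer longitudinal baselines
  (random-regression models) are out of scope.
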