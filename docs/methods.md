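# Methods

## Model

One calving record is an ordinal score k ∈ {1..4} generated by a latent
liability with unit residual variance:

λ = x'β + hys + u_s(sire) + u_m(maternal) + e, e ~ N(0, 1),
score = k ⇔ t_{k−1} < λ ≤ t_k, with t_0 = −∞, t_K = +∞.

Fixed effects are the observed combinations of year–season, breed×parity
and breed×sex. The contemporary group hys (herd–year–season) is random
with known variance. The genetic pair (u_s, u_m) — sire effect for the
SCE trait and maternal effect for the DCE trait — follows N(0, G₀ ⊗ H),
where H is the pedigree relationship matrix A or its single-step
genomic counterpart. Under SMGS the maternal effect attaches to the
maternal grandsire of the calf; under SMAT, to the dam. Calves carry no
ID: records attach directly to sire and dam/MGS, so the pedigree is an
ordinary animal pedigree over sires, dams/MGS and their ancestors
(flag-and-trace extraction), not an animal–sire–MGS structure.

Thresholds and variance components are treated as known inputs (they are
estimated upstream in national practice). The identifiability restriction
fixes the *last* cutpoint at 0; fixing the first at 0 instead is an
equivalent choice. Defaults are the national liability-scale estimates:

- SMGS: G₀ = [[0.0223, 0.0113], [0.0113, 0.0224]], σ²hys = 0.216,
  t = [−1.14, −0.63, 0.00];
- SMAT: the reparameterization below, which lands on
  [[0.0239, 0.0242], [0.0242, 0.0961]], σ²hys ≈ 0.232,
  t ≈ [−1.22, −0.68, 0.00].

## MGS → dam reparameterization

An MGS transmits half of the dam's additive maternal effect, so on the
dam scale σ²_d = 4σ²_mgs and σ_s,d = 2σ_s,mgs. The MGS parameterization
leaves the untransmitted 3/4 of maternal additive variance in the
residual; removing it gives a residual of 1 − 3σ²_mgs on the old scale,
and restoring a unit residual multiplies every variance by
c = 1/(1 − 3σ²_mgs). With σ²_mgs = 0.0224, c = 1.07204, which reproduces
all published SMAT components to print precision (0.02391, 0.02423,
0.09606, σ²hys 0.23156).

The cutpoints are rescaled by the same factor c. Dimensional reasoning
would suggest √c (cutpoints live on the liability's standard-deviation
scale), but c is what reproduces the published SMAT cutpoints
(−1.14·1.07204 = −1.2221 → printed −1.22; −0.63·1.07204 = −0.6754 →
printed −0.67); this package follows the published convention. A ±0.01
comparison tolerance on cutpoints absorbs the unknown rounding rule.

## Liability-scale primitives

With a = t_{k−1} − η, b = t_k − η:

- category probability p_k(η) = Φ(b) − Φ(a);
- EM imputation: E[λ | k, η] = η + (φ(a) − φ(b)) / p_k — the
  truncated-normal conditional mean used as next-round pseudophenotype;
- NR score v = (φ(a) − φ(b)) / p_k = ∂ log p_k/∂η (identically the
  imputation shift);
- NR weight w(η) = Σ_k (φ(a_k) − φ(b_k))² / p_k, the *expected* (Fisher)
  information. Expected rather than observed curvature guarantees w > 0
  and a positive-definite weighted system.

Numerical guards: interval probabilities use a complementary-CDF branch
(Φ(−a) − Φ(−b)) whenever both bounds are in the upper tail, avoiding
catastrophic cancellation; interval masses below 1e−300 fall back to the
nearer truncation boundary ± 1e−8 with a warning; weights are floored at
1e−12.

## Mixed-model equations and solvers

With T = [X | Z_hys | Z_s→trait-1 | Z_m→trait-2] and
Λ = blockdiag(0, I/σ²hys, G₀⁻¹ ⊗ H⁻¹), one solving round is

(T′WT + Λ) θ = T′Wy.

- EM: W = I, y = imputed liabilities. The coefficient matrix never
  changes; only the right-hand side is refreshed each outer round.
- NR: W = diag w(η_i), y_i = η_i + v_i/w_i. The equations are rebuilt
  every outer round.

Both algorithms share the stationary condition Λθ = T′v(θ), so they
converge to the same solutions; NR is locally quadratic while EM is
linear, which is why EM needs many more outer rounds.

No explicit constraints are imposed on the (rank-deficient) fixed-effect
block: the three factor blocks each sum to an intercept, the system is
singular but consistent, and conjugate gradients started at zero stay in
the range space. GEBV contrasts and all reported correlations are
invariant to the fixed-effect nullspace.

The inner solver is a hand-rolled Jacobi-preconditioned conjugate
gradient (relative-residual stop ‖r‖/‖rhs‖ < inner_tol, default 1e−10,
warm-started from the previous round); owning the loop makes the
iteration accounting exact — reported "inner" counts are cumulative PCG
iterations across outer rounds. Outer convergence is the relative
solution change CD = ‖θ_new − θ_old‖/‖θ_new‖ < outer_tol (default 1e−6);
the inner tolerance is kept four orders tighter so inner error never
masquerades as outer change. Starting values are all-zero. Optional
step-halving damps NR if CD ever increases; five consecutive CD increases
raise a divergence error.

## Pedigree and genomic machinery

Pedigrees are topologically sorted at read time (file order is never
trusted); cycles are reported as errors, unlisted parents become founders
with a warning. Inbreeding uses the Meuwissen–Luo algorithm (exact,
ancestor-list traversal); A⁻¹ uses Henderson's rules with
Mendelian-sampling variances adjusted for parental inbreeding; A₂₂ for
the genotyped subset is computed by the tabular method on the subset's
ancestor closure — an explicitly O(n²) desk-scale contract.

G = ZZ′/(2Σp(1−p)) with Z the dosage matrix centred at 2p and allele
frequencies taken from the genotyped sample unless supplied. Before
inversion G is moment-matched to A₂₂ (a + bG matching mean diagonal and
mean off-diagonal) and blended as G* = 0.95·G_tuned + 0.05·A₂₂ — the
de-facto defaults of single-step practice; positive definiteness is
verified by Cholesky. The single-step contribution is stored as A⁻¹ plus
the dense correction (G*)⁻¹ − (A₂₂)⁻¹ scattered onto genotyped
equations; a zero correction reduces the evaluation exactly to pedigree
BLUP (tested end-to-end). Markers with MAF < 1% are dropped; missing
dosages are mean-imputed to 2p. Unknown parents form the ordinary
(single) genetic base; unknown-parent groups and metafounder-style bases
are out of scope.

## Synthetic data generator

The generator emulates the *structure* of national calving-ease data:
records carrying sire, dam, MGS (= pedigree sire of the dam), hys code
and fixed-effect codes; a three-layer pedigree (founder males/females →
proven bulls → recorded dams); gene-dropped biallelic genotypes on the
male layers. The truth model is the dam-level (SMAT) structure with the
published dam-scale components and unit residual, so the SMAT analysis
is correctly specified and SMGS is its reduced form — matching how the
two models relate on real data.

Defaults define the standard comparison scenario: 300 service sires ×
150 records = 45,000 records, 200 MGS, 20,000 dams, 1,000 founder males,
5,000 founder females, 150 herds × 6 year–seasons (≈900 hys levels,
σ²hys = 0.232), 1,000 SNP on the 1,500 males of the founder and
proven-bull layers. Fixed-effect level values are Uniform(±0.1),
centred — estimable but not dominant. The intercept is calibrated in
closed form, μ₀ = t₁ − Φ⁻¹(0.826)·σ_λ with
σ_λ = √(σ²hys + σ²s + σ²d + 1), so the marginal category shares
reproduce the national distribution (~82.6/9.1/5.7/2.6%). Breeding
values descend as parent average plus Mendelian deviation ~ N(0, G₀/2);
parental inbreeding is ignored in the Mendelian variance (founders are
unrelated and the pedigree is three layers deep, so the error is
negligible). Breeds attach to herds; a dam's records stay in her herd.

What the generator does *not* emulate: two breeds with genuinely
different allele-frequency/LD architecture, national pedigree depth and
size, selection, or non-random mating. Passing tests therefore show
algorithmic correctness and the expected solver/model agreement
structure at desk scale, not predictive accuracy on field data.

## Problem sizes and runtime choices

The default comparison scenario yields ~26,500 pedigree animals under
SMAT (≈54,000 genetic equations) and ~2,000 under SMGS; all four runs
complete in about a minute on one CPU, with NR converging in ~9 outer
rounds and EM in ~50 at outer_tol 1e−6. Unit and property tests use a
2,000-record scenario. These sizes were chosen so that every qualitative
finding (solver equivalence, cross-model correlation ordering, NR ≪ EM
outer rounds) is comfortably resolvable on a laptop.

## Known limitations

- Thresholds and variance components are inputs, never estimated.
- Single categorical trait only; no multiple-trait extension of NR.
- The O(n²) tabular A₂₂ and dense (G*)⁻¹ limit the genotyped set to a
  few thousand animals; large-scale approximations (APY etc.) are out of
  scope.
- PTA publication scaling ("percentage of difficult births") and
  reliability approximation are not implemented.
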