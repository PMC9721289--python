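# Methods

## Model and assumptions

All four evaluation models are linear mixed models y = Xb + Zu + e with
u ~ N(0, K σ²-structured) for some relationship structure K and
e ~ N(0, R).  The package treats incomplete pedigree information in two
ways that share the same group definitions (breed × country × period):

* **Unknown-parent groups (UPG).**  Groups absorb the genetic level of
  animals with missing parents.  They enter through the Quaas–Pollak
  (QP) augmented inverse
  [A⁻¹, −A⁻¹Q; −Q′A⁻¹, Q′A⁻¹Q], where Q holds pedigree-derived gene
  contributions from each group.  No variance ratio is attached to the
  group equations; the augmented structure itself realizes the groups as
  random levels, and the animal solutions of the augmented system are
  group-inclusive breeding values.

* **Metafounders (MF).**  Groups are related, inbred pseudo-founders
  with covariance Γ.  The tabular relationship matrix A^Γ starts the
  recursion from the metafounder block Γ (a metafounder's
  self-relationship is γ_gg, not 1 + γ/2); inbreeding and Mendelian
  sampling variances d_i = 1 − (s_p + s_q)/4 use parental
  self-relationships (1 + F for animals, γ_gg for metafounders).  The
  sparse augmented inverse is Henderson's rules over animals ∪
  metafounders plus Γ⁻¹ on the metafounder block; metafounder equations
  are kept in every system and dropped only at the reporting boundary.

The single-step models add genomic information through
H⁻¹ = A-family-inverse + correction on the genotyped coordinates, with
Gc = (1−w)·G05 + w·A₂₂-family and G05 built at reference allele
frequency 0.5 (Z₁₀₁ coding, scale k = m/2), as the metafounder theory
requires.  Gc⁻¹ is represented as (1/w)·base⁻¹ − T′T via the Woodbury
identity; the binding definition of the factor pair is this inverse
identity (enforced to 1e-8 against dense oracles in the tests), with
T = w^{-1/2} L⁻¹ Z′ base⁻¹ and L L′ = (kw/(1−w))I + Z′ base⁻¹ Z.

## Γ estimation pipeline

1. **Truncation.**  The pedigree is pruned to the genotyped animals plus
   one ancestor generation; cut ancestors are replaced by group codes
   from their own breed/country/birth year.  A genuinely unknown parent
   keeps its code; if it has none it is assigned from the offspring's
   breed/country at birth year minus a configurable gap (default 5
   years — the data do not record the missing parent's own birth year,
   so a typical generation interval stands in).
2. **GLS base allele frequencies** per marker,
   p̂ = ½(Q₂′A₂₂⁻¹Q₂)⁻¹Q₂′A₂₂⁻¹m, with A₂₂ and Q₂ from the truncated
   pedigree.  Estimates are deliberately **not clipped** to [0, 1]
   (clipping would bias Cov(P)); out-of-range counts are reported.
   Groups without genotype linkage are detected and named.
3. **Γ = 8 Cov(P)** with the population divisor m: Γ is a moment over a
   fixed marker panel, and the m vs m−1 difference is below 0.1% at
   panel sizes of interest.
4. **Panel merging and diagonal replacement.**  Per-source Γ diagonals
   (computed on each panel's full marker set) overwrite the joint-panel
   diagonals, since the marker intersection deflates per-group variance.
5. **Covariance function.**  Φ columns: standardized year
   t = 2(y − y_min)/(y_max − y_min) − 1 (y_min = 1950, y_max = 2021 for
   the reference application) plus one indicator per breed class;
   `year_degree = 0` drops the year term for group sets without year
   spread.  K̂ is the printed two-sided estimator
   (Φ′Φ)⁻¹Φ′ΓΦ(Φ′Φ)⁻¹, which equals the OLS solution of the vectorized
   regression of Γ entries on Φ column-pair products (tested to 1e-10
   against that oracle).  The exact column order of the original
   application's Φ is not published, so element-level equality with the
   printed K̂ is not asserted anywhere; its dimensions, definiteness and
   the rank-9 consequence are.
6. **Extrapolation and bending.**  Γ_all = Φ_all K̂ Φ_all′ has rank ≤ q;
   bending (off-diagonals × 0.975, diagonals × 1.025) equals
   (1−δ)Γ + 2δ·diag(Γ) and is therefore positive definite whenever Γ is
   PSD with positive diagonal.  The pipeline never passes a pre-bend Γ
   to an inverse.

## MME assembly and solver

Multi-trait systems use trait-minor ordering within each level; the
genetic block is the relationship operator composed with G0⁻¹, applied
matrix-free.  Records with missing traits are grouped by missingness
pattern with pattern-wise residual inverses.  Fixed effects: the first
categorical factor keeps all levels, later factors drop their first
level; remaining rank deficiency is tolerated because the solver is
residual-criterion based and reported quantities (fitted values,
breeding values) are invariant.  Calving-age covariates α, α², α³
(α centered over all data and divided by 365) are multiplied by
pedigree breed proportions when enabled.

The PCG solver starts from zero, uses Jacobi (diagonal) preconditioning
— the operator exposes exact diagonals including the low-rank genomic
corrections — and stops when ‖rhs − Cx‖/‖rhs‖ < 1e-6 (the criterion is
re-verified with a true residual at acceptance of convergence).
Published iteration counts of production software are not reproducible
targets, since preconditioner and starting values there are unknown.

## Validation

YD = per-cow mean of (y − full-data fixed-effect fits); DYD = ERC-weighted
mean over daughters of (YD − EBV_dam/2), i.e. on the transmitting-ability
scale, and the reported bull slope is doubled.  A dam recorded as an
unknown-parent code contributes the model's estimated group/metafounder
solution; leaving it at zero pushes the base-population mean into the
DYD and inflates the validation slope (observed ~1.4 before this
adjustment, ~1.1 after, on 8 replicate seeds).  ERC is simplified to the
per-trait record count and EDC to the sum of daughter ERC: with
single-record daughters, EDC/(EDC + λ_b), λ_b = (4−h²)/h², is then
exactly the reliability of the DYD (the ¼ signal share of a daughter is
already inside λ_b), keeping the adjusted reliability R²/mean-weight on
the [0, 1] scale.  The combined parity index is 0.30·p1 + 0.25·p2 +
0.45·p3.  Cutoff default: 4 years of records.

## Synthetic data generator

The generator emulates a multi-country dairy population at desk scale:
ancestral allele frequencies uniform on [0.05, 0.95]; per-metafounder
base AF as Beta draws with mean p and variance p(1−p)·F_drift (default
F_drift = 0.08, inside the 0.05–0.15 range typical of between-population
cattle differentiation — this makes Γ_true ≈ 8·Var analytic, the anchor
of the recovery tests); 4 metafounders = 2 breeds × 2 countries; 100
founders per metafounder and 15 sires per cell per generation (a
national AI program's effective sire usage — much narrower choices
bottleneck the estimable base-AF precision); 6 overlapping generations
with 5% crossbreeding, 5% migration, 8% missing parents; 2,000 markers;
~500 genotyped animals in the youngest three generations.

True breeding values are built on the metafounder scale so the
evaluation models are exactly specified for the data: the marker part is
Z₁₀₁a with i.i.d. effect variance (1−w)σ²_u/k (matching the G05-based
covariance analytically), and the polygenic part (share w = 0.30,
matching the default blending) has metafounder group means with
covariance Γ_true and the standard Mendelian recursion — together
w·A^Γ + (1−w)·G05-structured.  On this scale the realized population
variance of u is below σ²_u (the variance-scaling diagnostic quantifies
the gap), so the residual variance is set from the configured h² against
the *realized* Var(u) and stored as `truth.R0_used`; model-consistent
runs use it as R0.  Heritability default 0.40 (305-day yield scale);
herd and season effects N(0, 0.5²) and N(0, 0.2²); one record per cow
per parity trait, parities modeled as correlated traits (default
correlation 0.85).

What the generator does **not** emulate: selection and assortative
mating (validation slopes are interpretable as bias-free baselines only
under random mating), linkage and LD (markers segregate independently),
genotyping errors and imputation artifacts, heterogeneous herd sizes,
and permanent-environment effects for repeated records.  Passing
recovery tests therefore show estimator correctness under the model's
own assumptions, not robustness to these real-data features.

## Problem sizes and numerical choices

Dense tabular relationship matrices and dense A₂₂-inverses are used
throughout; the package targets pedigrees up to ~20k animals (test and
acceptance runs use 1k–3k animals, 400–2,000 markers, chosen so the
entire suite solves dozens of mixed-model systems in a few minutes).
Inbreeding uses the tabular diagonal up to that scale and a
Meuwissen–Luo-style recursion beyond (the two agree to 1e-10).  No
MAF filtering is applied anywhere by default; when a filter is wanted it
must be applied to Γ estimation and G05 alike (the marker sets must stay
consistent).  The variance-scaling factor 1 + tr(Γ)/(2n) − 1′Γ1/n² is
reported as a diagnostic only — it presumes the population is a
homogeneous mixture of all base populations, which real populations are
not, so the solver keeps the user-supplied variances.

## Known limitations

Colleau-style indirect A₂₂ products, APY-type sparse genomic inverses,
iteration-on-data, REML variance-component estimation and exact
effective-daughter-contribution algorithms are out of scope.  The
148-group reference table reconstructs the published scheme's class
counts and year spread deterministically; the original period boundaries
are not published, but only class membership and year spread enter the
model matrix, so rank and scale conclusions are unaffected.
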