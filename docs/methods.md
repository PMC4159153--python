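# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions.

## Synthetic cohorts

**LD model.**  Haplotypes come from a one-parameter left-neighbour copying
kernel: each haplotype carries a latent uniform that is re-drawn at site *j*
with probability `1 − exp(−Δbp / ld_decay_bp)` and otherwise copied from the
previous site; the allele is the indicator `u < p_j`.  Copying the *uniform*
rather than the allele preserves each site's target frequency exactly while
giving comonotone correlation between neighbours, so pairwise r² decays
monotonically with distance, two co-located same-frequency sites are in
complete LD, and `ld_decay_bp → 0` recovers independent sites.  The default
decay length is 50 kb and allele frequencies are uniform on [0.05, 0.5],
which gives adjacent-SNP r² around 0.2–0.5 at typical array spacing — enough
LD structure to exercise every LD-dependent code path.  The kernel is a
stand-in with one auditable parameter, not a demographic model: it has no
recombination hotspots, no allele-frequency spectrum, and no population
substructure beyond optional sibling pairs.

**Relatedness.**  Genotypes are two haplotypes drawn with replacement;
optional sibling pairs share two parental haplotype pairs with one haplotype
per parent inherited at random, so expected kinship is 0.25 and the realised
value per pair ((same-maternal) + (same-paternal))/4 ∈ {0, 0.25, 0.5} is
recorded in `kinship_true`.  All kinship matrices in the package are on the
kinship-coefficient scale (diagonal 0.5); the mixed model multiplies by 2
internally to get the relationship matrix.

**Trait decomposition.**  `y = Σ a·g + d·1[g=1] + Σ M[g₁,g₂] + Σ β·covariate
+ u + e` with `u ~ N(0, σ²_g·2K)`, `e ~ N(0, σ²_e I)` and
`σ²_g = h2_poly/(1−h2_poly)·σ²_e`, so `h2_poly` is exactly the polygenic
heritability σ²_g/(σ²_g+σ²_e) of the non-fixed part — the quantity the REML
fit estimates.  Epistatic 3×3 matrices are double-centred under HWE genotype
frequencies (`center_epistasis`), which removes their marginal content and
makes the planted interaction variance available in closed form
(`interaction_variance`), enabling exact parameter-recovery tests.
Missingness is injected uniformly at random *after* phenotype simulation so
QC and pairwise-complete deletion have real work to do; real missingness is
not uniform, so call-rate-correlated artefacts are outside what these tests
demonstrate.

**Annotation tracks.**  Enhancers are an alternating exponential gap/interval
renewal process whose covered fraction matches the requested density in
expectation (mean interval 2 kb); ChIA-PET interactions are Poisson per Mb
with 2-kb anchors placed uniformly.  Both are geometry-only nulls: they carry
no sequence or chromatin biology, so enrichment tests against them verify the
*statistics*, not biological signal.

## Quality control

Filters run in one pass, in the listed order, and are pure functions of the
inputs and thresholds.  The Hardy–Weinberg test is the 1-df χ² of observed vs
expected genotype counts at the sample allele frequency, without continuity
correction — at a rejection threshold of 1e−10 the difference from an exact
test is immaterial, and the χ² is auditable by hand.  The heterozygosity rule
reads "unacceptably high" as one-sided: per-sample heterozygosity proportions
are z-scored and their upper-tail normal P-values passed to Benjamini–
Hochberg at FDR 0.01 (via statsmodels).  PC outlier removal flags samples
beyond 6 SD (a conventional, conservative default; no published value exists)
on any of the first three kinship PCs and iterates once, since a gross
outlier can mask a second one.

## Polygenic residualisation

The kinship estimator is the centred, frequency-scaled cross-product
(Astle–Balding): `K_ij = mean_snps (g_i−2p)(g_j−2p)/(2p(1−p)) / 2`, with
missing calls contributing zero and excluded from the per-pair SNP count.
Principal components are eigenvectors of this same matrix (scaled by √λ), so
PCs and the polygenic covariance derive from one object.

The trait is pre-corrected for covariates by OLS, rank-inverse-normal
transformed (`Φ⁻¹((rank−0.5)/n)`, ties averaged), then fit with
`PolygenicModel`: after one eigendecomposition of `A = 2K`, the REML
log-likelihood is profiled over σ² and maximised over h² by bounded Brent
search on [0, 1−1e−6] with tolerance 1e−8 — a single variance component
makes the 1-D search exact enough.  `pgresidualY = y − Xβ̂ − BLUP(u)` with
`BLUP(u) = σ̂²_g A V̂⁻¹(y − Xβ̂)` evaluated on the eigenbasis.

Degenerate case: when `A ∝ I` (identity kinship) the profiled likelihood is
exactly flat in h², because σ² absorbs any rescaling.  The fit then prefers
the h² = 0 boundary (tie-break: the optimum must beat the boundary
log-likelihood by more than 1e−6), which makes the residuals equal OLS
residuals — the sensible no-structure limit.

The residualise-then-scan strategy is known to be conservative for additive
single-SNP scans when structure and heritability are high; no deflation
correction is applied here, and the marginal scan should be read with that
in mind.

## Pairwise scan

**Screening.**  For each pair the 9-cell two-locus table is built over
pairwise-complete samples.  Counts come from the bit-plane encoding (one
packed plane per genotype class; an AND of two planes popcounts to a cell
count), and the per-cell trait sums and sums of squares from a fused
single-pass numba kernel — bit planes alone cannot carry trait sums.  The
screening statistic is the pooled-within-cell F comparing the saturated
cell-means model with the best 5-parameter additive+dominance two-locus
main-effect fit, with `df_int = (#non-empty cells) − rank(main design)`;
pairs with `df_int ≤ 0` are skipped and counted.  The batched solver uses a
pseudo-inverse on the cell-level normal equations, so empty cells and
collinear designs degrade df rather than crash.

**Verification.**  Every emitted pair is re-tested with an exact
individual-level least-squares partial F (3-level factor coding for each
SNP, four interaction product columns, rank-aware df), and that `p_full` is
the reported `P_int`; `p_screen` is retained for audit.  On complete data
with no empty cells the two tests coincide identically — the screen is then
the same F test — so the "approximate" screen can never silently disagree
with the exact test on the data that matter.

**Conventions.**  Missing genotypes: pairwise-complete deletion, matching
the contingency construction.  The local-interaction distance boundary is
*inclusive* at exactly 1 Mb ("within 1 Mb").  `dist_kb` rounds half-up to
one decimal; thresholds are reported at two significant figures but compared
at full precision.  LD is the composite dosage r² (squared Pearson
correlation of 0/1/2 dosages) — phase-free and standard for array data; no
EM haplotype phasing is attempted.  Pairs are emitted with lexicographically
ordered SNP ids, making scan output independent of input order.  The trait
is centred before either test, so large trait means cannot produce
catastrophic cancellation in the sums of squares.

**Score test.**  The marginal scan statistic is
`[(g−ḡ)ᵀV⁻¹r]² / [(g−ḡ)ᵀV⁻¹(g−ḡ)·σ̂²]` with `σ̂² = rᵀV⁻¹r/n`.  The default
V = I is the GRAMMAR convention (the trait is already a polygenic residual)
and reduces to the textbook OLS score test; the σ̂² factor is required for
that equality and is therefore part of the statistic.  On the V ≠ I path the
trait is centred by its V-weighted mean and missing genotypes are
mean-imputed (the vectorised V = I path drops them per SNP instead).

**Threshold ordering.**  `t_full < t_marginal < t_local` holds whenever the
marginal set is a small fraction of the panel (2k < m) and the marginal scan
comprises more than 0.05/1e−5 tests ((m−1)k > 5000) — true for any
genome-scale configuration; tiny configurations can invert the ordering and
the property test encodes the precondition.

## Model building

Marginal terms enter the background **additive-only** (the convention for
conditioning on lead SNPs); pair terms enter with the full 9-cell coding,
with columns already spanned by the background removed by rank.  Conditional
significance is a rank-aware partial F at α = 0.05 with no multiplicity
correction inside the selection loop — the selection criterion is the quoted
independence rule, not a family-wise guarantee.  Ties in the minimum
conditional P break by genomic order (chromosome, position), making the path
deterministic and input-order invariant.

Variance explained is defined on the residual-trait scale as
`Var(X_terms β̂_terms)/Var(y) × 100`, refitting the (polygenic, or OLS when
no kinship is supplied) model with the accepted terms as fixed effects for
each prefix of the path; the exact estimator behind published tables is not
uniquely determined, so this definition is used consistently, and the
parameter-recovery tests (a SNP planted at 4.5% is reported at 4.5 ± 0.7)
pin down its calibration.  Cumulative values are non-decreasing by
construction and increments sum exactly to the final value.

Replication is SNP-identity based: a discovery pair replicates iff both SNPs
are genotyped in the second cohort and its interaction P there is < 0.05
(strict); otherwise the record is NA.  No LD-proxy lookup is attempted — it
would require external reference haplotypes.

## Enrichment

The background overlap frequency is computed from **all genotyped SNPs
passing QC**, not genome-wide bases, so the expectation respects the array's
ascertainment.  `expected = n_tagged × freq`, `fold = observed/expected`
(half-up, one decimal), and the P-value is the exact upper-tail binomial
`P(X ≥ observed)`.  LD expansion of the tagged set (r² > 0.8 proxies) is
deliberately not performed: the core statistic stays self-contained.

SNP positions are 1-based and BED intervals 0-based half-open; a SNP is
inside an interval iff `start ≤ pos < end` with the 1-based position compared
directly, so a SNP at an interval's end coordinate is outside.  Region
forming is greedy left-to-right: open a region at the first unassigned SNP,
absorb all SNPs within 25 kb of that first SNP, span `[first, first+25000)`.
ChIA-PET counting uses a closed ±100-kb window around each region midpoint;
an interaction counts once per region if either anchor overlaps the window.
The empirical rank is the fraction of regions with *strictly more*
interactions than the focal region (all-ties ⇒ 0).  The exact region-forming
rule behind published region counts is not published; the greedy rule is one
consistent reading and is validated against brute-force oracles, not against
the published region count.

## Problem sizes and limitations

Test and acceptance runs use desk-scale cohorts chosen to make each
statistical property measurable with comfortable Monte-Carlo margins:
n = 2000 with 2000 replicates for the interaction test's type-I error,
n = 4000 / 500 SNPs for planted-pair top-rank scans, n = 6000 for
forward-selection recovery, n = 2500–4000 with 900–1200 SNPs for REML
heritability recovery, and n = 9000 for the 4.5%-variance recovery.  The
package has no GPU kernels, no binary-trait interaction tests, no
X-chromosome dosage model, no imputation/dosage support, and no multi-
component variance models; synthetic cohorts do not emulate genotyping batch
effects, informative missingness or realistic demography, so passing tests
demonstrate correctness of the statistics, not robustness to those
artefacts.
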