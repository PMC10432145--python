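# Methods

This note records the models implemented in `comogen`, their assumptions,
the defaults that matter, and the design choices made where more than one
reasonable reading existed. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

Summary statistics are per-variant effect sizes (`beta`, log-odds for
case-control traits), standard errors, p values and sample sizes, aligned to
an explicit effect/other allele orientation. Coordinates are 1-based
inclusive on GRCh37-style integer positions; chromosome X is out of scope.
Harmonization aligns a second dataset to the first by inverting the sign of
its beta when the allele labels are swapped; incompatible allele pairs are
dropped and logged. Sign-flipping is by allele-label match only; an optional
flag additionally drops strand-ambiguous (A/T, C/G) variants, since label
matching cannot resolve strand for them.

Analysis regions are 2 Mb windows (±1 Mb) around index signals. Index
signals are selected greedily by ascending p value with distance-based
suppression (no further index within the window), with ties broken by
(p, position, id) for determinism; an explicit index list can be supplied
instead when externally established signals exist. The per-trait
significance thresholds default to 5×10⁻⁸ and, for the multi-phenotype
disease, the adjusted 1.3×10⁻⁸.

Colocalized signals are merged into unique loci when their 95% credible sets
share a variant or their lead variants lie within 1 Mb on the same
chromosome, closed transitively (union-find). The merge rule is a design
choice — the collapse from signals to loci admits several consistent
definitions — and the transitive credible-set/lead-distance rule was chosen
because it is deterministic and order-invariant. The locus lead is the
member lead with the highest per-SNP shared-causal posterior.

## Colocalization

Per-SNP evidence is the Wakefield log approximate Bayes factor
`lABF = ½·ln(1−r) + ½·z²·r`, `r = W/(W+se²)`. The prior effect-size SD
defaults to 0.2 on the log-odds scale for case-control traits and 0.15 (in
trait-SD units) for quantitative traits; both are configurable. Note the
lABF depends on `se` through `W/V`, so posteriors are invariant under joint
rescaling of beta, se and the prior SD, but not of beta and se alone.

Pairwise posteriors use per-SNP priors p1 = p2 = 10⁻⁴ and p12 = 10⁻⁵. All
evidence arithmetic is in log space with a shared logsumexp; the
two-distinct-variants evidence is computed as a stable log-difference
`ln(exp(L1+L2) − exp(L12))` and is exactly zero for a single-SNP region.
The 95% credible set is the shortest prefix of SNPs, ranked by descending
conditional causal posterior (ties by position then id), reaching 0.95
cumulative mass. The decision threshold PP4 > 0.8 is a configurable
constant, not hard-coded logic.

The multi-trait engine enumerates partitions of the trait set into a null
subset plus blocks of traits sharing one causal SNP — no divisive
clustering. A block of k traits at a SNP has prior `prior1·(1−prior2)^(k−1)`
with defaults prior1 = 10⁻¹⁰ and prior2 = 0.7 (informative priors for
regions already known to harbor a shared signal). Block evidence factorizes
as a logsumexp over SNPs of the block's summed lABFs. The distinct-SNP
constraint between blocks is applied exactly for two blocks
(product-minus-shared-term) and ignored for three or more; the exhaustive
(n+1)³ oracle in the tests bounds this approximation at ≤ 10⁻⁶ absolute
posterior error on small instances at the default priors. With two traits
the engine reproduces the pairwise posteriors exactly under the prior
mapping p1 = p2 = prior1, p12 = prior1·(1−prior2). Sample overlap between
input GWAS is ignored (treated as independent). When the credible set
driving a multi-trait run contains a single variant, the engine falls back
to all variants in the 1 Mb window and flags the result.

## Cross-trait LD score regression

Model: `E[z²_j] = 1 + a + n·h²·l_j/M` and
`E[z₁ⱼz₂ⱼ] = intercept + √(n₁n₂)·ρ_g·l_j/M`, with the free cross intercept
absorbing phenotypic correlation among overlapping samples. Slopes are
estimated by two-pass weighted least squares: a first pass with weights
1/l_j, then weights `1/(l_j·(1+n·ĥ²·l_j/M)²)` for the univariate fits and
`1/(l_j·(1+n₁ĥ²₁l_j/M)(1+n₂ĥ²₂l_j/M))` for the cross fit, using the
first-pass h² estimates in all three second passes. This makes the cross
weights reduce exactly to the univariate ones when both inputs are the same
dataset, so identical traits yield r_g = 1 to machine precision. The weight
form omits the squared-covariance term the reference LDSC software includes,
and no two-step intercept constraint or MHC exclusion is applied — both
divergences are immaterial for synthetic data and are noted here.
Free-intercept estimates are imprecise relative to the slopes (the design
extrapolates to l→0 under heavy downweighting of high-LD SNPs); only the
slopes carry the scientific conclusions.

Uncertainty comes from a delete-one block jackknife over 200 contiguous
blocks (the conventional count), re-running all three regressions per
deletion with weights fixed at their full-data values; r_g is recomputed per
deletion so its SE propagates the h² uncertainty.

The permutation test shuffles trait 2's Z scores across SNPs while fixing
trait 1 and the LD scores, recomputing the genetic-covariance slope with
weights fixed at the observed fit. The default statistic is ρ_g rather than
r_g: shuffling destroys trait 2's LD-score relationship, driving ĥ²₂ toward
zero and making the r_g denominator unstable, while the covariance slope
ranks datasets identically and has a stable null; r_g is available behind a
flag. The empirical p is two-sided with the add-one estimator
`(1 + #{|perm| ≥ |obs|})/(B+1)`, which can never return 0.

## Mendelian randomization

Instruments are genome-wide-significant exposure SNPs, LD-clumped greedily
(default r² ≥ 0.001 within 10 Mb per side removes a candidate; missing LD
pairs count as r² = 0 with a warning). Steiger filtering retains a SNP iff
its approximate variance explained `z²/(z²+n)` is strictly larger for the
exposure than the outcome; the same formula is used for quantitative and
binary traits (a liability-scale version is out of scope).

Estimators: Wald ratio (`b_out/b_exp`, first-order delta SE by default,
second-order behind a flag); IVW as a weighted origin regression with
1/se²_out weights and multiplicative random effects (SE scaled by
max(1, residual scale)); weighted median with interpolation at cumulative
weight 0.5 and a seeded parametric bootstrap SE (default 1,000 draws);
MR-Egger with exposure effects oriented positive, the same multiplicative
scaling, and t-distributed (n−2 df) p values for slope and intercept. IVW
accepts a single instrument, where it reduces exactly to the Wald ratio.
Heterogeneity is Cochran's Q with chi-square reference; instrument strength
is the summary-level `F = mean(β²/se²)` with F < 10 flagged as weak;
multiple testing uses Benjamini–Hochberg (via statsmodels) per analysis
batch.

The two-step mediation analysis instruments an adiposity-style exposure on
gene expression (step 1) and expression on disease (step 2), excluding
expression instruments in LD with the adiposity index SNPs at the clumping
thresholds (the stricter of the two readings of "excluding independent
eQTLs from the risk variants"). Method dispatch follows instrument count:
one SNP → Wald; two or more → IVW with heterogeneity; more than three →
MR-Egger additionally (weighted median from three). Genes with no surviving
instruments are reported, not raised. Tissue-specific estimates are compared
with `z = (est_a − est_b)/√(se²_a + se²_b)`.

## Effector-gene scoring

Per disease, the score counts positive lines among molQTL colocalization,
differential expression (> 1.5-fold in either direction with adjusted
p < 0.05; linear or log2 input convention is explicit), knockout-mouse
phenotype term matches and OMIM term matches — each at most one point. The
multiple OA molQTL tissues collapse to a single flag (one line per disease).
Established high-confidence genes contribute only by bumping a zero disease
score to one; the alternative always-additive reading sits behind
`hc_additive=True`. Missense variants in the credible set add one point to
the total, but a gene whose only evidence is missense totals zero.
Classification: potential (≥ 1 line for either disease), likely (≥ 1 for
each), high-confidence (likely with total ≥ 3). Term matching is plain
case-insensitive substring search so stems like "osteo" catch
"osteoporosis"; the shipped term lists are configurable. Joint
stratification assigns both knee and hip when a locus colocalizes only with
joint-agnostic phenotypes, adding knee for knee/TKR and hip for hip/THR
(memberships may overlap). Obesity levels: 1 = OMIM obesity disease,
2 = variant-level adiposity association, 3 = neither. The gene universe of a
locus is every gene whose span intersects the ±1 Mb window around the lead
variant (boundary inclusive).

All annotation acquisition (mouse/OMIM/druggability databases, pathway
networks) is upstream: the package consumes pre-extracted flag tables.

## Synthetic-data generator

The generator works at the summary-statistic level, which is exact for every
method here: regional marginal Z scores are drawn as
`z ~ MVN(causal_z·R·e_c, R)` per trait on an AR(1) LD backbone
`R[i,j] = ρ^|i−j|` (PSD by construction), with `beta = z·se` and the
standard SE approximations `1/√n` (quantitative) or `1/√(n·φ(1−φ))`
(case-control, case fraction φ). Defaults are the calibration conditions
used throughout: 200 SNPs, LD decay 0.9, causal noncentrality 8,
biobank-scale samples. A configurable fraction of variants can be emitted
with swapped allele labels to exercise the harmonization path (default 0;
the end-to-end pipeline uses 0.2).

Genome-wide Z pairs follow the LDSC model exactly, including the
sample-overlap covariance term; LD scores are drawn from a shifted gamma
(1 + Γ(2, 30), minimum 1) in place of real reference-panel LD scores.
Defaults — M = 20,000 SNPs, h² = 0.5 for both traits, ρ_g = 0.12
(r_g = 0.24, the knee-scale estimate used as generator truth), N = 50,000 —
are a desk-scale rendition of two well-powered GWAS. The "strong
correlation" scenario used for the permutation separation check sets
ρ_g = 0.45 (r_g = 0.9); the recovery-scale covariance of 0.12 sits only
about 2.5σ above the permutation null at these sizes and is deliberately
not used for the separation property.

Evidence tables are independent Bernoulli flags per line and disease with a
stored ground-truth class computed by an independent restatement of the
scoring rules. MR instrument sets draw exposure effects with random signs
and apply directional pleiotropy along the exposure-increasing allele so it
survives MR-Egger's reorientation.

What the generator does **not** emulate: real human LD structure, allele
frequencies, the true genetic architecture of either disease, linkage
between regions, winner's-curse in instrument selection, or population
stratification. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under its own generative
assumptions, not performance on real consortium data.

## Numerical choices

Log-space evidence arithmetic throughout, with a guarded `logdiffexp` that
returns −∞ on non-positive differences. Posterior vectors are normalized by
softmax of log evidences. Credible-set and clumping ties break by
(posterior/p, position, id). Jackknife and permutation machinery use
per-block sufficient statistics so delete-one refits are O(1). All
generators take explicit integer seeds and are bit-reproducible;
sub-analyses derive child seeds below 2³¹.

## Problem sizes in the test and acceptance runs

Calibration runs use 200 replicates for detection/false-positive rates, 500
for credible-set and IVW coverage, 100 seeds for LDSC recovery, 200 runs at
B = 199 for permutation uniformity and B = 999 for separation, and 10,000
genes for scorer/oracle agreement — sizes chosen to make binomial noise on
the measured rates small relative to the asserted margins. The end-to-end
pipeline scenario uses six regions of 150 SNPs (four H4, one H3, one null)
and 200 evidence genes.

## Known limitations

Single-causal-variant assumption per trait per region (no SuSiE-style
multi-signal colocalization); no divisive clustering tree in the multi-trait
engine; no additive random-effects IVW or MR-PRESSO; no multivariable or
BMI-adjusted MR (collider-bias avoidance); LDSC without partitioned
heritability or LD-score estimation from genotypes; locus merging is one
consistent rule among several the collapse would admit.
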