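# Methods

`forestqg` analyses multi-site open-pollinated (OP) progeny trials of forest
trees: it builds pedigree-expected and genomic realized relationship
matrices, verifies field pedigrees against SNP relatedness, derives
tree-ring drought indices, and estimates heritabilities and genetic
correlations with individual-tree REML models. This note documents the
models, the generative assumptions of the synthetic-data module, the
numerical choices, and the limits of what the tests demonstrate.

## Relationship matrices

**Numerator relationship matrix (A).** Built by the tabular method on a
topologically ordered pedigree: `a_ii = 1 + 0.5 a(s_i, d_i)` and
`a_ij = 0.5 (a(j, s_i) + a(j, d_i))`, with unknown parents contributing
zero. Founders are assumed unrelated and non-inbred (the standard
base-population assumption; nothing in an OP trial identifies founder
inbreeding). Under these rules non-inbred pedigrees give exactly 1.0 on the
diagonal, 0.5 for full sibs and parent-offspring pairs, 0.25 for half sibs
and 0 otherwise. The implementation is dense and targets desk-scale
populations (up to a few thousand individuals); no sparse A-inverse is
provided because the REML engine inverts the phenotyped submatrix
numerically.

**Genomic relationship matrix (G).** VanRaden's first form,
`G = WW' / (2 Σ p_i (1 − p_i))` with `W = M − 2p` and dosages `M` coded as
the count of alternative alleles. Allele frequencies default to the full
filtered sample (per-site or base-population frequencies can be supplied);
with sample frequencies the columns of `W` sum to zero and hence the grand
sum of `G` is zero, an identity the tests exploit. Genotype QC retains loci
with missing fraction ≤ 0.30 (boundary inclusive) and minor allele count
≥ 1, then replaces each missing call by the locus mean of observed dosages,
which leaves per-locus means (and so `p`) unchanged. Because `G` from a
finite SNP panel can be singular or ill-conditioned, `stabilize_G` offers
ridge loading (`G + εI`, default ε = 1e-6 in the pipeline) or blending
`wG + (1 − w)A`.

## Pedigree verification and correction

Field records of OP families carry mislabelled mothers at a low rate, and
the true fathers are unrecorded. Realized coefficients `g_ij` are compared
with the class expectation from the recorded pedigree (0.5
parent-offspring and full-sib, 0.25 half-sib); a pair deviating by more
than a threshold (default 0.15, roughly half the gap between adjacent
relationship classes) is flagged. For each conflicted offspring the
candidate parents are searched among the *recorded* parents of the
population: a unique candidate with `g` inside the parent window (default
[0.35, 0.65], centred on 0.5) is assigned; ties or an empty candidate set
produce a phantom parent with a reserved id prefix; offspring conflicting
with several recorded parents of the same role are listed for removal.
Both thresholds codify a procedure that is done by eye in practice; they
are configurable and their defaults are declared, not estimated. Sib-pair
conflicts without a parent conflict (e.g. hidden full sibs sharing an
unrecorded father) are reported but trigger no reassignment. Phantom
parents inherit their offspring's genetic group, a flagged convention.

With 5000 informative SNPs the sampling noise of `g` is a few hundredths,
far below the 0.25 separation between classes, which is why detection of
mislabelled dams is essentially perfect in the recovery tests; with far
fewer markers or strong frequency misspecification the margins shrink and
the thresholds would need re-examination.

## Drought indices and trait preprocessing

From a tree's basal area increment series (BAI, computed from ring widths
as `π(R_t² − R_{t−1}²)` when not measured directly):

* **Resistance** = (BAI in the drought year) / (mean BAI of the 4 preceding
  years); defaults target a 2015 drought with the 2011-2014 pre-window.
* **Mean sensitivity** = mean over consecutive year pairs of
  `|2(BAI_{t+1} − BAI_t) / (BAI_{t+1} + BAI_t)|`. Years missing from the
  series split it into runs; pairs straddling a gap are excluded and `n`
  counts the years entering retained pairs. A consecutive pair summing to
  zero makes the term undefined and raises unless zero-pair skipping is
  explicitly enabled.

Both indices are ratios, hence invariant to rescaling a series by any
positive constant (property-tested).

Other preprocessing follows common progeny-trial practice: natural-log
transforms for right-skewed traits (the base only shifts the variance
scale, not heritabilities or correlations); BAI-weighted averaging of
per-ring wood properties with rings before 1995 discarded; design
adjustment by subtracting count-weighted replication-effect estimates
within site (effects sum to zero, so the grand mean is preserved, and the
operation is idempotent); and per-trait z-scoring with the n−1 variance
denominator, applied within site before multi-site models (pooled
standardization is available).

## Mixed models

Univariate, per trait and site:

    y = Xβ + Z_d d + Z_a a + e,
    a ~ N(0, K σ²_a),  d ~ N(0, I σ²_d),  e ~ N(0, I σ²_e)

with `K` either A or (stabilized) G and `β` the genetic-group (provenance)
fixed effects. The replication effect `d` is fitted when the data were not
pre-adjusted; plot effects are not modelled (single-tree plots).

Multivariate: trait-site combinations are correlated responses with
genetic covariance `Σ_a ⊗ K` and residual covariance free between
responses measured on the same trees at a site and structurally zero
across sites (no tree grows at two sites, so cross-site residual
covariances are not estimable and are fixed at exactly zero). Missing
responses are handled by row deletion per response; residual covariances
are estimated from jointly observed individuals.

Heritability is re-parameterized as `h² = σ²_a / (σ²_a + σ²_e)` — the
design variance is deliberately excluded from the denominator, which
inflates `h²` relative to full phenotypic-variance definitions and should
be kept in mind when comparing across studies. Genetic correlations are
`r_a = σ_a(i,j) / √(σ²_a(i) σ²_a(j))`, labelled strong at |r| ≥ 0.70,
moderate between 0.40 and 0.70 and low/weak at or below 0.40. A response
with (numerically) zero genetic variance yields NA correlations rather
than zeros. Standard errors come from the delta method applied to the
inverse Average-Information matrix.

### Estimation

Variance components are estimated by EM on the restricted likelihood:
each iteration solves for the BLUPs and conditional covariances at the
current components and updates

    Σ_a ← Σ_a + Σ_a (S'K S − T) Σ_a / q

(and analogous residual and design updates), where `S` scatters the
projected data `Py` and `T` collects traces of `P` against `K` blocks;
`Σ_a` is projected to the PSD cone each iteration by clipping eigenvalues
below 1e-10 of the largest. Convergence is declared when the largest
relative component change falls below 1e-8 (default) or after 2000
iterations, whichever comes first; components below 1e-6 of the phenotypic
variance are flagged "near zero" and excluded from the relative-change
criterion so boundary cases terminate. After convergence exactly one
AI step is evaluated: the average-information matrix
`AI_rs = ½ y'P V_r P V_s P y` over the free parameters, whose inverse is
the asymptotic covariance used for all standard errors. A full AI-REML
optimizer is intentionally not provided.

Two computational routes give identical results. Balanced single-site
layouts (all responses on the same trees, no design random effect, no
missing values) diagonalize `K` once and iterate on t×t blocks per
eigenvector, making EM iterations essentially free. Everything else uses
a dense route that assembles the N×N phenotypic covariance per iteration;
because plain EM converges slowly in weakly identified directions (notably
cross-site genetic covariances), the dense route augments EM with
SQUAREM-style extrapolation, safeguarded by an explicit likelihood
comparison: an extrapolated point is accepted only if its restricted
likelihood is at least that of the plain double EM step, so the recorded
likelihood trace is non-decreasing by construction and any decrease beyond
1e-8 (relative) raises an error. The final likelihood, fixed effects,
AI matrix and BLUPs are always evaluated on the dense route at the
converged components.

EM expectation statistics are computed over the submatrix of `K`
restricted to phenotyped individuals; BLUPs for unphenotyped relatives are
obtained afterwards from the cross-blocks of `K`. Both formulations are
valid EM algorithms for the same REML objective; the restricted one
converges faster. BLUP accuracy is `√(1 − PEV / (K_ii σ²_a))`.

Identifiability caveat: with `K = I` and one record per individual,
`σ²_a` and `σ²_e` enter only through their sum and cannot be separated;
the engine then (correctly) remains at its starting split. Informative
family structure in `K` is what identifies the decomposition.

## Synthetic data

The generators emulate the structure of a three-site OP spruce trial with
known truth, so every downstream stage is testable without field data:

* **Pedigree**: configurable dams × progeny (defaults 80 × 8, matching a
  mid-sized trial), true fathers drawn uniformly from a finite pollen pool
  (default 100 donors — the pool size and selfing rate of a real stand are
  unknown; selfing is excluded by construction and the pool size is a free
  parameter). Recorded pedigrees hide all sires, so recorded families are
  nominal half-sib families that contain occasional true full sibs. Dam
  mislabelling is injected at a configurable rate and logged.
* **Genotypes**: unlinked biallelic SNPs, founder frequencies uniform on
  [0.05, 0.5], founders in Hardy-Weinberg equilibrium, offspring by gene
  dropping, missingness completely at random (up to the 30% QC bound).
  No linkage disequilibrium is simulated.
* **Phenotypes**: breeding values multivariate normal with covariance
  `Σ_a ⊗ K` (phenotypic variance 1 per response, so `σ²_a = h²`);
  replication effects iid normal (default SD 0.25); residuals correlated
  across traits within a tree, zero across sites; optional per-trait
  lognormal transforms and completely-at-random missingness.
* **Ring series**: per-tree lognormal level around 500 area units,
  iid lognormal year noise (log-SD 0.20), and a multiplicative drought-year
  dip `1 − severity (1 − g_i)` with a tree-specific genetic deviate `g_i`
  (SD 0.25). The default severity 0.43 puts the population mean Resistance
  near 0.57, the level observed in drought-stressed OP spruce trials.

All draws flow from a single `numpy` generator per call; the same seed
replays byte-identical outputs, and the truth object (pedigrees,
contamination and swap events, variance components, breeding values)
serializes to JSON.

What passing tests do *not* show about real data: the generator has no
spatial autocorrelation, no linkage, no genotyping error or allele-dropout
structure, no selection or multi-generation structure, and its residuals
are Gaussian after the declared transforms. Recovery results therefore
demonstrate correctness of the estimation machinery under the stated
model, not robustness to field-data pathologies.

## Problem sizes

The test and acceptance workloads run at reduced scale chosen to exercise
every code path with comfortable statistical margins: recovery experiments
use 800 phenotyped trees × 3000 SNPs × 20 replicates (sampling SE of
`ĥ²` ≈ 0.015 for the mean over replicates), pedigree-correction recovery
uses 640 progeny × 5000 SNPs, and oracle equivalence uses 100 random
pedigrees up to 50 individuals plus 20,000 gene drops. These sizes are the
package's own choice of a desk-scale reference experiment; all generators
and the engine accept larger inputs.

## Known limitations

* Dense linear algebra throughout: practical up to a few thousand
  individuals and ~6 responses.
* No single-step (H-matrix) GBLUP, dominance, epistasis, spatial residual
  structures, or genetic-gain/selection-index calculations.
* The correction step assigns recorded parents or phantoms; it does not
  attempt full paternity assignment within the pollen pool.
* Wald/delta standard errors degrade near parameter boundaries (h² near 0
  or 1, |r_a| near 1); the reports flag near-zero components rather than
  pretending precision.
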