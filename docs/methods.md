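# Methods

`gasmgwas` implements gene-haplotype association mapping for structured
panels of inbred accessions, together with the analyses that normally
surround it in a germplasm study: eco-trait derivation from weather series,
variance-component and heritability estimation from multi-environment
trials, evolutionary accounting of allele changes between subpopulations,
and cross recombination-potential prediction. This note records the models,
the numerical choices and the design decisions that were genuinely open.

## Gene-allele sequence markers (GASMs)

A GASM is a multi-allelic marker built per annotated gene: its alleles are
the haplotypes formed by all biallelic SNPs inside the gene's interval
(boundaries inclusive; a SNP inside two overlapping genes contributes to
both). The panel is assumed fully inbred, so each accession carries exactly
one haplotype per gene:

* heterozygous or missing VCF calls are treated as missing and imputed with
  the SNP's major allele before haplotyping (ties go to the reference
  allele) — on an inbred panel heterozygotes are far more likely call
  errors than residual heterozygosity;
* haplotypes rarer than the minor-allele-frequency threshold (`maf`,
  default 0.01) are superseded by the single most frequent pre-collapse
  haplotype, in one pass. Ties for the modal haplotype break to the
  lexicographically smallest string. The single-pass rule (rather than
  iterative re-thresholding) is idempotent: every surviving allele has
  frequency ≥ `maf`, so collapsing twice changes nothing;
* genes left with fewer than two haplotypes are dropped.

Multi-allelic VCF sites are rejected by default; an opt-in flag splits them
into biallelic records (records at one position are then distinguished by
suffix, and the position-sorting invariant allows ties for exactly this
case).

## Population structure

The genetic similarity coefficient between accessions i and j is the
proportion of GASMs at which they carry the same allele,
GSC(i,j) = (1/m) Σ_k 1[a_ik = a_jk]. The allele-identity indicator is the
natural choice for homozygous lines; the partial-sharing weights used for
heterozygous material would reduce to it here. The top q eigenvectors
(default q = 10) of the dense symmetric GSC matrix serve as fixed
covariates in both association stages. Eigenvectors are unit-norm with the
sign fixed so the largest-magnitude entry is positive, making results
reproducible across LAPACK builds. No random polygenic term is fitted: the
procedure corrects structure with fixed eigenvector covariates by design.

## Variance components and heritability

The multi-environment randomized-complete-block model is

    y_ijk = mu + t_i + r_j(i) + g_k + (gt)_ik + e_ijk

with environments i = 1..n, blocks j = 1..r within environments and
genotypes k. On a balanced layout, method-of-moments estimates follow the
expected mean squares: sigma2_g = (MS_g − MS_gt)/(nr),
sigma2_ge = (MS_gt − MS_e)/r, sigma2_e = MS_e, with negative estimates
truncated at zero. Up to 2% of cells may be missing if mean imputation is
explicitly enabled; worse imbalance is an error rather than a silently
biased fit. Entry-mean heritability and the G×E share are

    h2_g  = sigma2_g / D,   h2_ge = (sigma2_ge / n) / D,
    D = sigma2_g + sigma2_ge/n + sigma2_e/(rn)

and GCV = sigma_g / mean.

## Restricted two-stage multi-locus association

The scan runs on per-accession means over environments and blocks (the
main-effect scale); the phenotype aggregation level is a package choice as
the field's software accepts either plots or means.

**Stage 1** tests each marker with a partial F-test of its (k−1) allele
dummies over the baseline of intercept + structure covariates; markers with
p < alpha1 (default 0.05) are pre-selected. Degrees of freedom use the rank
increase of the design, so collinear dummies never inflate a test.

**Stage 2** is forward selection with backward elimination under the joint
multi-locus model, with the trait heritability as an explicit upper bound
on the genetic R²: the candidate with the smallest partial-F p enters if
p < alpha2 (default 0.05; a Bonferroni mode uses alpha/m over the
pre-selected candidates); a candidate whose inclusion would push the
genetic R² — (RSS_base − RSS_model)/TSS, with RSS_base the
covariates-only fit — past the h² cap is skipped in favour of the next
best. After each insertion, in-model markers with partial p ≥ alpha2 are
removed, largest p first, and returned to the candidate pool. Equal
p-values break by larger F, then genome order. The cap guarantees the
invariant genetic R² ≤ h² at termination, and h² − Σ R² is reported as the
unmapped-minor-gene share.

**Final refit.** Allele effects are re-expressed under an unweighted
sum-to-zero constraint per gene; the reported intercept absorbs the mean
covariate contribution, so `intercept + Σ effects` is a genotypic value on
the trait scale. Per-gene R² is sequential in selection order — the
contributions then sum exactly to the model's genetic R² — with the
partial (drop-one) R² also reported for comparison, since printed tables
in this literature do not state which decomposition they use. Genes with
R² ≥ 1.5% are labelled LC-major (large contribution), the rest SC-major.

**G×E extension.** On environment-stacked means, each selected gene's
allele×environment interaction is tested by partial F over a model holding
environment main effects, covariates and all gene main effects, in
selection order; interactions with p < alpha2 are retained while the
cumulative interaction R² stays within the h2_ge budget. Interaction R² is
reported on the entry-mean phenotypic-variance scale (interaction variance
divided by n_env and by the entry-mean variance) so that it is
commensurate with the main-effect R² and with h2_ge. G×E is a
post-selection extension over the main-effect gene set; the scan itself
remains a main-effect scan.

## Allele dynamics

The detected genes' assignments form the gene-allele matrix. For a
contrast of a derived group (or union of groups) against an ancestral one,
an allele is *present* in a group when at least one member carries it (no
frequency floor): inherited = present in both, emerged = derived only,
excluded = ancestral only. The counting identities
|inherited| + |excluded| = |ancestral| and
|inherited| + |emerged| = |derived| hold exactly by construction. An
exclusion is judged against sampling error with the binomial zero-carrier
probability P0 = (1−p)^n (p = ancestral frequency, n = derived group
size), significant at P0 ≤ 0.05; emergence is tested with the mirrored
quantity (zero ancestral carriers at the derived frequency) — the mirror
is this package's explicit choice, as the literature marks emerged alleles
without stating a formula. Alleles with an effect of exactly zero (within
1e-9) count as positive so that sign splits stay two-way.

## Cross prediction

For each unordered parent pair, 2000 fully homozygous progeny are
simulated. Under independent assortment every locus inherits from either
parent with probability 1/2. Under linkage, parent-of-origin along each
chromosome's ordered loci follows a Markov chain with adjacent-locus
switch probability R = 2r/(1+2r) — the recombinant-inbred-line
(selfing-to-fixation) value for single-meiosis recombination fraction r,
from the Haldane map r = (1 − e^(−2d/100))/2, d in cM. A doubled-haploid
scheme (R = r) is available as a flag. Physical anchor positions convert
to genetic distance at 2.5 cM/Mb by default; a user map file overrides the
conversion. Progeny genotypic values are intercept + summed allele main
effects; parents are valued the same way, so simulation and reference
share a scale (predicted, not observed, parent values). The 25th/95th
percentiles use linear interpolation between order statistics (type 7),
and LPT = F25 − LPV, HPT = F95 − HPV flag transgression below the low and
above the high parent. One RNG stream is derived per (pair, model) from
the master seed and pair index, so enumeration order cannot change any
cross's result and the full table is bit-identical across runs.

## Synthetic data

The generator emulates a structured inbred germplasm panel. Its defaults
are the study conditions: 354 accessions in 5 subpopulations (labelled by
geographic group O/A/B/C/D and maturity-group set E/P/L), genes of 1–3
SNPs laid out non-overlapping at 2 Mb spacing (≈5 cM between adjacent
genes at the default conversion — detected genes in a real panel are
Mb-scale apart), four environments with two blocks, entry-mean h² 0.9 and
a G×E share of 0.05. Test and acceptance runs scale the panel down (120–300
accessions, 40–100 genes) to keep runs in seconds; the statistical
structure is scale-free.

SNP frequencies follow a two-level Balding–Nichols-style model: an
ancestral frequency per SNP uniform on (0.05, 0.95), subpopulation
frequencies Beta-distributed around it with variance F·p(1−p)
(divergence F = 0.12, a typical between-region Fst for a worldwide
self-pollinating crop panel), and accessions drawn homozygous at their
subpopulation's frequency. SNPs are exchangeable within and between genes;
the generator does not model coalescent LD, so within-gene haplotype
diversity is somewhat higher than RAD-seq data would show — the MAF
collapse brings allele counts back to the observed 2–8 band.

**Planted QTL architecture.** Phenotypes are built from planted
GASM-allele effects plus a polygenic background, G×E deviations, block
effects and plot residuals, with variances solved from the h² formula so
the generating components hit the h² and G×E targets on a unit
entry-mean-variance scale. Planted gene shares are calibrated net of the
structure covariates (the variance of the gene's effect surviving
projection on them), because that adjusted share is the estimand the
association model reports. QTL genes for recovery benchmarks are chosen to
be identifiable: 2–4 alleles, every allele at frequency ≥ 0.05, and ≥ 80%
of effect variance orthogonal to structure. Without these rules the
benchmark measures something else — masking of small QTLs by the
structured component of larger ones, and the noncentral-F tail power of
rare many-allele markers (an 8-allele gene at a 5% share is missed ~8–10%
of the time at stage 1 by closed form) — rather than the procedure's
recovery of identifiable signal. Passing benchmarks therefore show
recovery of identifiable, well-replicated QTLs in a structured panel; they
do not certify power for rare-allele or heavily confounded architectures,
which genuinely have less power.

**Evolution scenarios** first regularise the base panel so every allele of
every gene is carried in every group (moving donors off each group's modal
allele), then plant emerged alleles by removing their ancestral-group
carriers and excluded alleles by removing their carriers in every derived
group; donors always move to the group's modal allele so no other allele's
presence changes, making the planted sets the exact ground truth.

## Numerical conventions and degenerate inputs

* All fits use `numpy.linalg.lstsq`; rank comes from the factorization, so
  rank-deficient additions are skipped with a warning rather than crashing.
* A perfect fit (zero residual) reports F = ∞, p = 0.
* Frequencies must sum to 1 within 1e-12; effect sums to zero within 1e-9;
  eigenvector orthogonality within 1e-8.
* Eco-trait periods are half-open [start, end), so a D-day growth period
  sums exactly D daily terms; a day with mean temperature exactly 10 °C is
  active. The growth-period window defaults to starting at sowing,
  configurable, as record-keeping conventions differ.
* ADL/AAT are additive over contiguous sub-periods by construction.
* The cross table reports C(n,2) unordered pairs for the input panel.

## Known limitations

* The ANOVA is strictly balanced-design method-of-moments; heavily
  unbalanced trials need a mixed-model fit outside this package's scope.
* The association engine fits fixed effects only — no random polygenic
  term, no permutation thresholds, no epistasis.
* The binomial exclusion/emergence tests treat accessions as independent
  draws, ignoring relatedness within groups; they are sampling-error
  screens, not formal selection tests.
* Progeny values are additive; dominance and epistasis are out of scope.
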