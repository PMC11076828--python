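# Methods

This note documents the models, estimators and numerical choices behind
`locadapt`, and what the synthetic-data generator does and does not emulate.

## Hard filtering and site classes

Sites are biallelic SNPs only. Genotypes with fewer than `min_depth` reads
(default 3) are set missing before any site-level rule. A site is removed if
QD < 2.0, FS > 60.0, MQ < 40.0, MQRankSum < −12.5, ReadPosRankSum < −8.0,
if every genotype is missing, or if the minor allele frequency over
non-missing genotypes is below 0.05. The two rank-sum thresholds follow the
standard hard-filter convention (fail *below* the negative threshold); an
absent rank-sum annotation — normal for sites without both hom and het
calls — never fails a site. Removal counts attribute each site to the first
failing rule in the order QD, FS, MQ, MQRankSum, ReadPosRankSum,
all-missing, MAF, so counts sum to the number removed.

Feature classes use the precedence exon (CDS) > UTR > intron > promoter >
intergenic; the promoter is the 2-kb window strand-upstream of the TSS and
counts only outside gene bodies. Coordinates are 1-based inclusive on disk
(VCF/GFF3) and 0-based half-open in memory throughout.

## Diversity statistics

Per site, θπ contributes 2j(n_h−j)/(n_h(n_h−1)) with j the alt (or derived)
count and n_h the site's own non-missing haplotype count; a 20-kb bin's
value divides the site sum by the bin span (partial end bins divide by
their actual span). D*xy* per site is p_A(1−p_B) + p_B(1−p_A) over
non-missing haplotypes; the default `per_site` mode divides the bin sum by
the span (pixy-style with SNP-only input), while `per_snp` averages over
variant sites — the two differ by orders of magnitude on resequencing data
and both are reported because published D*xy* values on these data are only
attainable as per-SNP averages.

SFS projection is hypergeometric: a site with j derived of n_h haplotypes
contributes C(j,k)C(n_h−j,m−k)/C(n_h,m) to class k at projection size m;
sites with n_h < m are dropped and counted. Projected masses stay
fractional. Polarization takes the ancestral allele from a single outgroup
sample; sites where the outgroup is heterozygous, missing, or carries a
third state are excluded from polarized spectra.

The Mann–Whitney U test enumerates the exact permutation distribution when
the pooled sample has ≤ 20 observations and otherwise uses the
tie-corrected normal approximation with continuity correction.

## Structured-coalescent engine

`coalescent.py` simulates single-locus genealogies backward in time under
piecewise population epochs (constant size or forward-exponential growth),
divergence events, and asymmetric migration declared forward in time as
m[source→dest] (a lineage in *dest* jumps backward to *source* at that
rate). Within a segment bounded by demographic events, the
time-inhomogeneous coalescence time under exponential size change is drawn
by analytic inversion of the cumulative hazard; draws past the segment end
are discarded and redrawn, which is valid by the restart property of the
inhomogeneous exponential. Expected SFS entries accumulate branch lengths
(each genealogy contributes its full conditional expectation), which has
far lower Monte-Carlo variance than mutation dropping; mutation dropping is
used only by the data generator, which needs actual haplotypes.

## Demographic inference

The 15-model catalog instantiates: (1) one-step three-way divergence;
(2–4) the three two-step divergence orders; (5–7) divergence plus a
bottleneck-with-recovery in W, S, or F; (8–10) divergence plus exponential
change in W, S, or F; (11–13) single-pair asymmetric migration (F–S, F–W,
S–W); (14) full asymmetric migration; (15) the composite of one-step
divergence, bottleneck in S, growth in F, and full migration. The
composite-likelihood is multinomial over polymorphic SFS cells (corner
cells excluded; expected cells floored at ε = 10⁻¹⁰; the multinomial
coefficient, constant in the parameters, is omitted). Fitting is ECM-style:
random restarts drawn log-uniformly within bounds, then cyclic
golden-section line searches per free parameter (log scale for sizes and
times, linear for rates), with one shared simulation seed per fit (common
random numbers) so each start optimizes a deterministic surface. Desk-scale
defaults (10 starts, 20 cycles, 2,000 simulations per evaluation) are
deliberately below a full-size analysis (100 starts, 80 cycles, 100,000
simulations); all three are exposed as arguments.

Normalized SFS shape is only weakly informative about absolute scale
(rescaling every N_e and T by a constant leaves the polymorphic spectrum
almost unchanged), so bootstrap confidence intervals on sizes and times are
wide unless one epoch is anchored; the recovery tests anchor the ancestral
size. AIC = 2k − 2lnL with k declared per template; Akaike weights are
exp(−Δ/2) normalized over the compared set. Nm products multiply the
forward migration rate by the source population's present-day N_e.

## Sweep scanning

FST is the Weir & Cockerham (1984) two-population variance-components
estimator, combined over a window as Σa / Σ(a+b+c) (ratio of sums);
negative per-site components are not clamped. XP-CLR models the object
population's allele frequency as a truncated normal around the reference
frequency with variance ω·p(1−p), where ω is the genome-wide mean of
(p_obj−p_ref)²/(p_ref(1−p_ref)) with the largest 2% of per-site terms
trimmed — ω calibrates the *neutral* drift density, and untrimmed means are
inflated by the very selected regions the scan is meant to flag. Under a sweep with escape probability
c = 1 − exp(−r·d/s̃) at distance d from the window center, the post-sweep
frequency is (1−c)·B + c·x with B ~ Bernoulli(p_ref) indicating linkage to
the sweeping haplotype and x the neutral frequency; observed counts are
binomially sampled and the likelihood is integrated on a 64-point midpoint
grid over x, with the grid density renormalized so quadrature error cancels
in the ratio. The selection grid is s̃ ∈ logspace(−5, −0.5, 30) plus the
neutral model; windows cap at 200 evenly downsampled SNPs; the
recombination map is a constant 1 cM/Mb unless supplied; the reference
frequency uses a half-count pseudocount to stay off 0/1. CLR values are
z-normalized per comparison.

Outliers are values ≥ mean + 1.96 SD (upper) or |value−mean| ≥ 1.96 SD
(two-sided), with moments over finite values only; NaN windows are never
outliers. HDRs are maximal merges of windows outlying in both statistics;
book-ended intervals merge. Fay & Wu's H is the unnormalized original
statistic θπ − θH with per-site realized n; the HDR contrast is a one-sided
Mann–Whitney test (HDR < genome).

## MK test

Per codon, ingroup-segregating positions contribute polymorphism and
ingroup-fixed positions differing from the outgroup contribute divergence;
a position polymorphic in the ingroup is never counted fixed. Multi-hit
codons are resolved by averaging syn/nonsyn step classifications over all
orderings of the single-nucleotide path (stop-codon intermediates are not
excluded; no transition/transversion weighting). With more than two
ingroup codons, paths run star-like from the major codon to each minor
variant, an approximation that is exact for the dominant one- and
two-variant cases. Codons with gaps or ambiguous bases are excluded and
tallied. Fractional counts are rounded half-up only at the test stage. The
primary test is the one-sided Fisher exact test toward excess
nonsynonymous divergence; a Williams-corrected G test is available as an
option. BH correction is step-up across genes.

## RDA and PCA

Missing genotype codes are imputed with the per-SNP mean (counted and
reported). RDA centers genotype and environment columns, fits multivariate
least squares, and takes the SVD of the fitted values; eigenvalues use the
n−1 divisor so constrained + residual variance equals total variance.
R²adj is the Ezekiel correction with p = rank(E). Axis significance is a
permutation test of the marginal pseudo-F per axis (rows of E permuted;
add-one p-value rule; default 999 permutations, seeded). Loadings are the
unit-norm right singular vectors per constrained axis; outliers are SNPs
with |loading − mean| ≥ 1.96 SD on axes with permutation p < 0.05, united
across axes. With samples from only three locations the constrained space
has rank ≤ 2 regardless of how many environmental variables are supplied;
the environment matrix's condition number is reported because MAT and MAMT
are nearly collinear. PCA standardizes columns by √(2p̂(1−p̂)) and drops
zero-variance columns. The χ² enrichment test is Pearson without continuity
correction (large counts); KS is the standard two-sample asymptotic test.

## Synthetic-data generator

The generator's default demographic scenario is the composite history with
divergence 4,654 generations ago from an ancestor of N_e 57,833; growth in
F at 1.05×10⁻⁴ per generation to a present N_e of 6,142; N_e 17,072 in S
with a 500-generation bottleneck (N_e/10 — the bottleneck depth is not
constrained by the printed estimates, so a tenfold reduction was chosen
once as a conventional "strong bottleneck") starting 2,250 generations ago;
constant N_e 778 in W; and migration m_FW = 6.35×10⁻⁴, m_SW = 2.62×10⁻⁴,
m_SF = 1.48×10⁻⁴, with m_WF set so Nm_WF = 0.05 and the two unreported
directions at zero. Sample sizes are 14, 17, 15 diploids plus one outgroup
diploid whose population splits from the root 60,000 generations back. The
environment table defaults are the three locations' climate normals
(MAT 19.5/23.5/24.9 °C, MAMT 5.8/12.4/15.6 °C, MAP 1743.3/1889.3/1913.0
mm), broadcast to samples by location.

Chromosomes are simulated as independent 20-kb blocks (loosely linked
loci); the per-site mutation rate is tuned on the realized total branch
lengths. The density target (1/kb) describes the *analysis-ready* SNP
panel — the published density refers to the filtered high-quality set — so
the generator oversimulates (2× by default), screens out sites below the
MAF threshold across all samples after signal injection, and subsamples to
the exact target, protecting causal GEA sites. Only the injected
INFO-annotation failures are then removable by the hard filter. Sweeps are a
deterministic post-hoc transform: a carrier haplotype is chosen and every
other haplotype in the population adopts the carrier's allele at each site
with probability exp(−d/λ) — fixation at the center, high-frequency derived
alleles nearby (negative H), elevated FST and XP-CLR. The test scenarios
use λ = 150 kb ("strong" sweeps at the scan's 20-kb window scale). GEA
causal SNPs get per-population derived frequencies logistic(α + β·MAMT)
with α solved so the across-population mean is 0.5; genotypes are redrawn
binomially (β = 0.8/°C in the recovery tests). Coding alignments use
300-codon genes matching the emitted 3×300-bp CDS exon layout, per-site
polymorphism 0.12 and divergence 0.05 (chosen once so that per-gene MK
tables at this scaled-down gene count carry enough counts for the Fisher
test to have power; the interspecific divergence is deep, consistent with
an ecological-speciation outgroup), and selected genes receive
verified-nonsynonymous fixed differences placed one per untouched codon to
realize an 8× Dn inflation without pathway-averaging dilution.

What the generator does **not** emulate: linkage within blocks beyond a
shared genealogy (no recombination inside a block, free recombination
between blocks), sequencing error and genotype-likelihood uncertainty,
reference bias, indels and repetitive-region artifacts, spatially
autocorrelated environments beyond three discrete locations, and any
coupling between the VCF's SNPs and the coding alignments' polymorphism.
Passing recovery tests therefore demonstrate that the estimators detect
the targeted signals at realistic magnitudes, not that they are robust to
every artifact of real resequencing data.

## Scale of the shipped tests

Test and acceptance runs use 2×1–2 Mb genomes (~2,000–4,000 SNPs),
20 replicates for recovery claims, 6-replicate bootstraps at 120–150
simulations per likelihood evaluation, and 5 neutral replicates for null
calibration; these sizes are the package's desk-scale defaults, with
paper-scale presets (177 Mb, ~190k SNPs, 100 starts / 80 cycles / 100k
simulations) exposed through configuration for full-size runs.

## Known limitations

* The XP-CLR implementation treats SNPs within a window as independent
  (composite likelihood) and does not weight by LD, so its power profile
  differs from implementations that downweight correlated sites;
  z-normalization per comparison absorbs most of the difference.
* The star-like multi-variant approximation in MK counting can miscount
  rare three-variant codons.
* Composite-likelihood AICs ignore linkage between SNPs, as is standard
  for SFS-based model choice; ΔAIC values are comparative, not absolute
  evidence.
* The coordinate optimizer can stall on ridges (e.g., the N·T scaling
  ridge of normalized spectra); more restarts and larger simulation counts
  are the remedy, at cost.
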