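# Methods

This note records the models behind `linkagekit`, the defaults and why,
the numerical choices, and what the synthetic tests do and do not show
about real data.

## Meiosis and genotyping model

Crossovers on a gamete are a Poisson process in genetic coordinate: the
count per chromosome is Poisson with mean `L_g/100` (genetic length in
cM, times any per-parent multiplier), and positions are uniform in cM,
mapped to bp through the inverse of the cumulative genetic map. This is
the no-interference model underlying Haldane map units and is consistent
with estimating distances by the Haldane function downstream. An
`obligate=True` flag forces at least one crossover per gamete, a
simplified stand-in for the obligate chiasma of a bivalent (by default
off; a faithful bivalent model would give the *bivalent* one crossover
and each gamete a 1/2 chance of carrying it).

The recombination landscape is piecewise-constant in cM/Mb per
chromosome, with multiplicative hotspot/coldspot intervals. Defaults
emulate an oyster-like system: 10 chromosomes of 56 Mb, 300 contigs,
~60 cM per chromosome per parent, dam multiplier 1.25 against sire 1.0
(sex-averaged rates near 2 cM/Mb with dams recombining ~25% more),
genotyping error 2.5% and missingness 2%. Mating types follow the
cross-pollinated notation: hk×hk markers segregate from both parents,
lm×ll from the dam only, nn×np from the sire only. Phase is coupling at
every marker (haplotype 0 carries the first allele); recombination
estimates are phase-agnostic so this loses no generality.

RNG discipline: every stream is a `SeedSequence(seed, spawn_key=...)`
child keyed by (parent role, progeny index), so enlarging a family does
not perturb earlier draws, and byte-identical outputs follow from equal
seeds and configs.

What the simulator does *not* model: read-level sequencing, depth and
allele-balance artifacts, segregation distortion (pervasive in real
oyster families through larval mortality — its quantitative form is not
known well enough to simulate without guessing a selection model),
crossover interference, and mapping-software ordering errors.
`maps_from_truth` stands in for an idealized error-free mapper; pipeline
recovery results therefore show correctness of the downstream logic, not
robustness to mapping error. Coordinates in emitted tables are 1-based
inclusive; internal interval arithmetic is half-open 0-based.

## Map statistics

Per-group map length is max−min cM. Average spacing `d` pools gaps
between *unique* positions across groups (sum of within-group spans over
sum of (unique−1)); groups with a single unique position are flagged and
excluded from `d`. Genome coverage is `GC = 1 − exp(−2dn/L)` with each
group extended by `2d` inside `L`. Paired comparisons between two map
sets use the classical paired t on per-family values, two-sided, df =
k−1; an all-zero difference vector degenerates to t = 0, p = 1, and a
constant nonzero difference to t = ±∞, p = 0.

Rank-order map agreement is the r² of regressing one map's marker ranks
on the other's; ties get average ranks (the field's default; note a
fully reversed map scores r² = 1 since ranks are perfectly
anti-correlated). Identical-marker collapsing treats two markers as
identical only when they agree at every individual *including the
missingness pattern* — the strict rule avoids collapsing markers that
merely look alike through missing data.

Recombination-fraction estimation is provided for phase-known gametes
(the simple proportion) and for F2 intercross 3×3 genotype tables
(maximum likelihood by bounded scalar search on [0, 0.5); the double-het
phase mixture is handled by summing gamete-pair probabilities directly).

## Compendium, decision tree and chimeric blocks

Markers mapping to different linkage groups in different families are
excluded at merge and reported; markers translating to the same physical
position are all removed. A contig's consensus LG is the plurality over
its SNPs; exact ties make the contig ambiguous and exclude it from block
statistics rather than resolving arbitrarily (misassembly statistics
must not depend on input order). Block runs are maximal stretches of
positionally contiguous SNPs sharing one non-consensus LG; block length
is last − first + 1 bp. Family support of a block is the union of
families over member SNPs (switchable to requiring a single member
mapped in >1 family); chimeric statistics (contig counts, mean SNPs per
block, median/total bp) are computed over multi-family blocks only.

The 2×2 association layers report OR = ad/(bc) with a Pearson chi-square
without continuity correction. The three-way loglinear analysis fits the
model hierarchy by iterative proportional fitting and reports 1-df G²
likelihood-ratio tests: the three-way term against the saturated model,
each two-way term against the all-two-way model. Wald-style parameter
chi-squares are deliberately not produced: they depend on a package's
coding and parameterization, whereas G² tests are
parameterization-free. Structural zeros are flagged; no small-constant
smoothing is applied by default.

## Anchoring

Contigs with at least one high-confidence SNP are assigned to the
chromosome of their consensus LG. Within a chromosome, each map
contributes the mean cM of the contig's high-confidence, consensus-LG
SNPs, min–max normalized to [0, 1] within that map's linkage group; the
unit-weight average across maps orders the contigs (the normalization
makes the order invariant to per-map affine rescaling of cM). Using only
consensus-LG SNPs keeps chimeric (category 3) SNPs — which belong to a
different chromosome — from polluting a contig's position. Orientation
is the sign of the weighted mean Spearman correlation between
contig-local bp and cM over maps with ≥2 distinct genetic positions on
the contig; |ρ| < 0.1 or no informative map yields "?". Ties in mean
position break by (more supporting SNPs, then contig id). Pseudomolecule
assembly reverse-complements "−" contigs, treats "?" as "+", inserts
100-bp gaps, and keeps AGP and FASTA spans consistent. Unplaced contigs
are reported, not silently dropped.

Concordance categories are assigned per contig in this order: different
chromosome; same relative rank and equal orientation → identical; same
rank, definite but opposite orientation → reversed; test orientation "?"
→ unknown; otherwise different order, with the rank offset over shared
contigs.

## Recombination rates

Chromosome-level RR divides the genetic span between the two most
*genetically* distal SNPs by their physical distance; ties in cM break
by bp so a flat map yields 0 rather than an error. The ANOVA fits main
effects and all two-way interactions; with one observation per
family×sex×chromosome cell the residual is the three-way interaction
(e.g. 6 families × 2 sexes × 10 chromosomes → 74 model df over 45
residual df). Family and chromosome are tested against the
family×chromosome mean square (they are whole-parent factors); sex and
the interactions against the residual. The sex contrast's standard error
is `sqrt(2·MS_res/(N/2))`.

Marey profiles: loci whose cM does not increase monotonically with bp
are removed by retaining one longest nondecreasing subsequence —
deterministic and maximally retentive, since the original outlier rule
is not specified beyond "non-monotone loci". The local rate is the
slope of a degree-1 tricube-weighted regression over the `ceil(span·n)`
nearest neighbors (span 0.3 by default), converted from cM/bp to cM/Mb.
Loci with negative rates are removed and the profile refit exactly once;
any negatives appearing after the refit are kept and visible to the
caller. Standardization is per family across the genome (sample sd), so
families are comparable; a per-chromosome option exists. Hot/cold
candidates are z > 1.28 / z < −1.28, the nominal 90th/10th percentiles.

The CSR test places the extreme points' bounding rectangle ([min, max]
bp × [min, max] z) on a 3×3 grid of equal-area quadrats and compares
counts to the uniform expectation n/9 by a Pearson chi-square with 8 df;
fewer than nine observations, or a degenerate rectangle, leaves the test
undone and flagged. Significance is declared at p < 0.001 to absorb the
multiplicity of per-family, per-chromosome, per-tail testing. Because
the rectangle adapts to the points, a *single* tight cluster with no
scattered extremes elsewhere can look uniform inside its own box; the
test detects clustering relative to the spread of all extreme points,
which matches its use on noisy real profiles.

Centromere checks report the minimum retained local rate inside a
supplied physical interval and its genome-wide quantile; an interval
containing no retained locus is flagged rather than answered.

## Problem sizes in tests

The test suite exercises the pipeline on 2–5 Mb chromosomes with a few
hundred SNPs, families of 10–1,000 progeny, 10,000-replicate
calibrations for the spatial test and Poisson/binomial rate checks, and
1,000-contig oracle sweeps for block detection — sizes chosen so the
whole suite runs in well under a minute while keeping Monte Carlo
standard errors far inside the asserted tolerances. Statistical
assertions use 3-SE bands (or wider, stated inline) fixed when the tests
were designed.
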