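# Methods

## The detection model

A wheat line's genome is modelled as a mosaic of elite breeding background
and donor blocks. Against a common reference, the elite background yields
sparse homozygous SNPs (order 10–25 per Mbp per subgenome, D the sparsest),
while a donor block carries the donor taxon's own divergence — several fold
denser, and identical by state (IBS) with a donor-vs-reference callset in
both position and allele. Detection therefore needs only three ingredients:
per-line homozygous-alt calls, a donor callset on the same coordinates, and
an elite subpopulation to set the local baseline.

Processing order matters. Calls are first *designated*: a sample with no
alternative-allele call at a panel locus is homozygous reference if its
mapping depth there is at least `min_depth` (default 5), else missing — the
branch a de novo caller cannot take on its own. Varietal masking then
removes loci matching the reference-vs-germplasm mask in position and
allele; these are background divergence between the breeding pool and the
reference cultivar, and they are the dominant source of false IBS signal.
The introgression scan runs on this designated, masked, otherwise
*unfiltered* matrix: the missing-data/MAF locus filter (< 10 % missing,
MAF ≥ 5 %) serves panel-level statistics (density tracks, F_ST), and would
wrongly delete donor variants private to one or two lines. The MAF threshold
is inclusive (≥ 5 %) and exposed; missingness is a fraction of all samples.
MAF counts alt alleles over non-missing calls (HOM_ALT = 2, HET = 1), which
degenerates correctly on homozygous panels.

### The 5-fold rule and its floors

Per line, 500-kbp bins accumulate (total, donor-matching) homozygous-alt SNP
counts; the elite baseline is the arithmetic mean of per-line totals per bin
across the elite group. A bin is donor-classified iff

    count >= fold * max(baseline, min_baseline)   and   count >= min_count

with `fold = 5`, `min_baseline = 1.0`, `min_count = 10`. The two floors are
this package's decisions: the ratio is undefined at baseline 0, and the
D subgenome's elite density (~9 SNPs/Mbp, ~4.5 per bin) leaves many bins
where a handful of calls would otherwise clear a 5-fold test. Classification
uses the *total* bin count — the rule as stated — with the donor-match
proportion reported per segment as supporting evidence; a `use_matching`
mode classifies on the matching count instead, which additionally separates
co-located donors. Classified bins merge into segments only when contiguous
(`max_gap_bins = 0` by default): long spans should emerge from the data, not
from a merge rule. Truncated terminal bins contribute their true width to
all span arithmetic.

Donor fraction per line is the summed segment span over the subgenome
length, in percent; the panel union is the set union of classified bins over
all exotic lines; the theoretical pedigree contribution is 100 × 0.5ⁿ for n
crosses after the primary donor cross. The identical machinery serves any
donor taxon on any chromosome (rye, *Thinopyrum*), not just the D-genome
donor.

## Windowed F_ST

Hudson's estimator, as a ratio of sums within each 500-kbp window:

    num_i = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den_i = p1(1-p2) + p2(1-p1)
    F_ST(window) = sum_i num_i / sum_i den_i

Windows tile from position 0 per chromosome, the same grid as every other
track. Two non-obvious choices:

* **Allele counting treats each line as one allele draw.** The panel is
  inbred; a line's two allele copies are identical, not independent. Diploid
  counting (2n alleles) under-corrects the finite-sample term and inflates
  null F_ST by ~+0.05 at these group sizes. Diploid counting remains
  available (`inbred=False`).
* **Control statistics average the unclipped estimate.** Per window the
  report clips to [0, 1] (raw retained alongside); but the raw estimator is
  unbiased around zero under no differentiation, and averaging clipped
  values would bias a genome-wide null mean upward by roughly +0.02. The
  pseudo-split control — a seeded random halving of the elite group —
  therefore reports the mean of raw values, which sits within ±0.01 of zero
  on a homogeneous panel. A panel hiding two diverged subgroups moves that
  mean away from zero in *magnitude*; the sign depends on how the split cuts
  the subgroups, because hidden structure inflates within-half variance
  beyond what the binomial correction expects.

Windows with no SNP contributing a positive denominator carry NaN, never 0.

## Evanno ΔK

For replicate clustering log-likelihoods L(K), interior K get
ΔK = mean over replicates of |L(K+1) − 2L(K) + L(K−1)| divided by the
standard deviation of L(K) across replicates; the argmax is the supported
subpopulation count. At least three consecutive K and two replicates are
required; zero replicate spread is degenerate and raises. The MCMC
clustering that produces L(K) is external to this package.

## Spectral indices

The 17-entry registry is implemented exactly as the study prints it,
including two entries that differ from common literature variants: SIPI as
(R800 − R435)/(R415 + R435) (a literature-style
(R800 − R445)/(R800 − R680) is available behind `sipi_variant`)
and NDMI as the (R1649, R1722) normalized difference. Wavelength lookup is
nearest-neighbour within 1 nm, falling back to linear interpolation for
coarser grids — field spectroradiometers resample to 1 nm, synthetic grids
may not. Near-zero denominators (PSRI when R531 ≈ R570) yield NaN with a
warning, and NaN propagates through the sample × index matrix rather than
being dropped. Normalized differences are antisymmetric under band swap;
pure ratios are invariant to scaling the whole spectrum; EVI, with its +1
soil term, is not — a test documents this rather than hiding it.

## Broad-sense heritability

    H² = σg² / (σg² + σge²/e + σ²/(r·e))

with components from expected mean squares of the balanced two-way
genotype × environment ANOVA with replication: σ² = MS_error,
σge² = (MS_GxE − MS_error)/r, σg² = (MS_G − MS_GxE)/(re). Method-of-moments
was chosen over REML because it is closed-form and directly testable against
an independent ANOVA implementation; unbalanced designs are rejected rather
than silently approximated. Negative component estimates are floored at
zero before the ratio, so H² ∈ [0, 1]. The effective r and e are user
overridable, because measured traits sometimes have fewer effective
replicates than the trial layout (e.g. two spectral measurements on two
plots). Classification: low < 0.30 ≤ medium < 0.60 ≤ high. Genotype means
use simple means; BLUE/mixed-model estimation is out of scope.

## The synthetic-study generator

The generator defines the conditions under which the pipeline's properties
are demonstrated. Defaults (all `SimConfig` fields):

| parameter | default | rationale |
|---|---|---|
| chromosomes | 3 per subgenome, 50–100 Mbp | scaled-down genome keeping the 7×3 structure's A/B/D density contrast |
| n_elite / n_exotic | 20 / 10 | enough elite lines for a stable baseline and a splittable control |
| elite_snp_rate | A 16, B 25, D 9 per Mbp | the per-subgenome shared-marker densities of the emulated capture study |
| donor_snp_rate | 150 per Mbp | donor-block density implied by the exotic-minus-elite count excess on the most affected D chromosome |
| alien snp_rate | 300 per Mbp | inter-generic aliens (rye, *Thinopyrum*) are far more diverged from wheat than the conspecific D-genome progenitor |
| crossovers per chromosome per cross | 1–2 | wheat's low crossover rate, which makes donor material block-structured |
| n_crosses_range | 2–6 | spans theoretical contributions 25 % down to 1.6 % |
| donor_fraction_range | 0.5–43 % | the realised donor-fraction span observed across synthetic derivatives |
| missing_rate | 0.05 | capture panels' realised missingness is unreported; 5 % is typical, config-exposed, not a claim |
| variance components (σg², σge², σ²) | (2, 1, 4), e = 2, r = 4 | two-year four-replicate trial with mid-range heritability (H² = 2/3) |

Donor blocks come from a simulated pedigree: each exotic line starts with a
fully-donor target subgenome and undergoes k backcross-style rounds; each
round places 1–2 uniform crossover points per chromosome and keeps each
resulting donor piece with probability ½, reproducing both the 0.5ᵏ dilution
law and block structure. Breakpoints keep a minimum 2-Mb spacing — strong
crossover interference, and the resolution floor of 500-kbp binning; without
it, sub-bin slivers and gaps exist in truth but are undetectable by
construction. Realised fractions outside `donor_fraction_range` are clipped
by trimming or adding block mass (with a warning when the expected 0.5ᵏ
itself falls outside the range). Inside a donor block the line carries the
donor alleles and *not* the elite-segregating alleles — the haplotype is
donor.

Varietal noise is haplotype-structured: a scattered panel-wide component
plus hotspot blocks (2 Mb, ~80 SNPs/Mbp) each carried by a random subset of
lines with log-uniform carrier frequency. A uniformly panel-monomorphic
model would shift every line's bin count and the elite baseline by the same
amount and cancel exactly in the fold-change — masking would then be
cosmetically irrelevant, which is not how varietal noise behaves in real
panels, where divergent haplotype blocks segregate. Under the structured
model, rare hotspots create genuine false 5-fold bins when masking is
disabled, so the mask's necessity is testable. All varietal positions are
written to the mask VCF.

Homozygous-reference evidence is encoded the way raw de novo calls carry it:
non-carrier genotypes are `./.` with DP ≥ 5, so the designation rule is
exercised end-to-end; i.i.d. missingness sets DP below 5. Depth is otherwise
a pass/fail token (5–45), not a coverage model.

Reflectance spectra are a smooth baseline minus Gaussian absorption
features: chlorophyll deepens 675/700 nm (mildly 550 nm), carotenoids
500 nm, leaf water 1450/1940 nm. This makes index–truth rank correlations
testable (chlorophyll vs R750/R700 Spearman > 0.9 at default noise) but is
not a radiative-transfer model. Trait tables are mu + G + GY + error with
centred normal components.

**What passing these tests does not show.** The generator has no linkage
disequilibrium beyond block structure, no depth-dependent genotyping error,
no reference bias, no selection, and its donor is uniformly diverged; real
capture data has locally varying capture efficiency and donor divergence.
Recovery at precision/recall ≥ 0.95 under these conditions demonstrates the
machinery, not field performance on any particular dataset.

## Problem sizes and estimator calibration

The demonstration studies use a 660-Mbp nine-chromosome genome, 30 lines and
~40 k loci — large enough that each subgenome holds hundreds of 500-kbp bins
and windows, small enough for the whole suite to run in seconds. The H²
recovery check keeps the study size at n = 150 genotypes but averages five
independent replicate studies before applying its ±0.1 band: a single draw
of the EMS estimator at that size has sampling sd ≈ 0.08, so a one-draw test
measures luck, while the replicate mean measures calibration.

## Known limitations

* The scan classifies on total bin counts, so two donors overlapping on the
  same chromosome are not separated by default (use `use_matching`).
* Hudson's estimator needs ≥ 2 allele draws per group per SNP; windows where
  missingness drops a group below that lose those SNPs.
* The heritability path is strictly balanced-design; REML for unbalanced
  trials is deliberately out of scope.
* Mode imputation (`impute_mode`) is a convenience stub, not part of the
  analysis rules; the study-grade step at that position is haplotype-based
  imputation by external tools.
* The Evanno statistic consumes externally produced likelihoods; no
  clustering is performed here.
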