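# Methods

`posclip` implements a positional analysis of protein–RNA cross-linking
(iCLIP-style) data together with the downstream quantitative assays that
typically accompany such a study: in-vitro binding affinity, RNA decay
kinetics, helicase progress curves, qPCR quantification and DNA-content
cell-cycle deconvolution. This note records the models, the parameter
choices, and the design decisions taken where published procedures leave
the details open.

## Transcript coordinates and the five regions

A gene is represented by one spliced, stranded transcript model
(0-based half-open coordinates internally; GTF converted on read, BED
written 0-based). When an annotation offers several coding isoforms the
longest transcript is kept (ties: longest CDS, then lexicographically
smallest transcript id); non-coding genes are dropped and counted.

Every transcript position belongs to exactly one of five regions built
from two anchors: the first CDS base (start anchor) and the first 3'UTR
base (stop anchor):

| region | span |
|---|---|
| 5'UTR | more than 50 nt upstream of the start anchor |
| start | ±50 nt around the start anchor, half-open `[a−50, a+50)` |
| CDS | between the two windows |
| stop | ±50 nt around the stop anchor |
| 3'UTR | more than 50 nt downstream of the stop anchor |

Windows truncate at transcript ends when a UTR is shorter than 50 nt.
When the CDS is shorter than 100 nt the windows overlap; overlapping
positions go to the strictly nearer anchor, ties to the stop. The stop
anchor is the CDS/3'UTR junction (not the first stop-codon base) so the
stop window is symmetric around the junction. Both conventions are
package decisions — published region definitions state neither boundary
inclusivity nor short-CDS behaviour — and are pinned by oracle tests
(materialized-interval comparison over random geometries).

## Cross-link sites and peaks

Reverse transcription in iCLIP truncates one nucleotide 3' of the
cross-linked base, so the protein contact is taken as `start − 1` on the
plus strand and one past the rightmost aligned base on the minus strand.
Reads sharing a contact aggregate into a count; contacts at position −1
and unstranded records are dropped and logged.

Peaks are called per gene in transcript coordinates. The score of a
position is the summed count within ±3 nt. The null redistributes the
gene's total count uniformly over its positions 100 times. The local
FDR of a score s is `(mean null positions ≥ s + 1/n_perm) / (observed
positions ≥ s)`, capped at 1 — the numerator pseudo-count is one
permutation-level event, so a single overwhelming spike can reach a
small FDR while an exceedance of zero never reports FDR 0. Positions
under the threshold (default 0.05) seed peaks; seeds within 6 nt merge.
Adjacent peaks within 20 nt merge into binding regions and regions with
≤ 20 reads are discarded (strictly more than 20 required). On
exchangeable input the fraction of genes acquiring any peak stays at or
below the nominal level (property-tested at 200 uniform genes).

## Enrichment of iCLIP signal over total RNA

Per gene, reads-in-peaks (iCLIP) are compared with total-RNA counts by a
negative-binomial Wald test with one observation per condition:

* **Normalization.** Median-of-ratios size factors (the library-size
  normalization of standard count-based differential tools). Because a
  genuinely enriched minority shifts the plain median, the factors are
  re-estimated on the genes the current pass calls non-differential
  (p > 0.1), iterating to a fixpoint (≤ 3 passes).
* **Dispersion.** Method of moments with a trend over the mean and a
  floor of 0.01. With one observation per side, the squared difference
  of normalized counts `w = (x_c − x_r)²/2` has null expectation
  `μξ + αμ²` and is approximately that expectation times a χ²₁ draw.
  A robust first pass bins genes on `min(x_c, x_r)` — a baseline proxy a
  planted fold change cannot shift upward, so no bin turns
  majority-differential — and solves α from per-gene median
  contributions. Refinement passes drop candidate genes (|log2FC| ≥ 1
  or p ≤ 0.1), correct the remaining means exactly for the χ² truncation
  this trim imposes, pool the bins through the asymptotic trend
  `α(μ) = a0 + a1/μ`, and damp the update on the log scale (the
  truncation threshold feeds back on the trend; damping keeps the
  fixpoint stable).
* **Test.** `log2FC = log2((y_c+½)/s_c) − log2((y_r+½)/s_r)`, standard
  error `sqrt(1/y_c + 1/y_r + 2α)/ln 2` (delta method), two-sided normal
  p, Benjamini–Hochberg across tested genes. Genes with both counts
  zero are indeterminate.

Status thresholds are strict: *enriched* ⇔ fold > 2 and adjusted
p < 0.05; *non-binder* ⇔ |log2FC| < 0.2 and p > 0.1. Measured on the
synthetic cohort (2000 genes, dispersion 0.05): null p < 0.05 fraction
≈ 0.05, planted 4-fold sensitivity ≈ 0.94 at mean ≥ 100 reads, median
recovered log2FC ≈ 1.95 (the residual shortfall from 2.0 is the
pseudo-count plus leftover normalization shift).

## Occupancy and consensus clustering

Occupancy is the five-region RPKM vector of each enriched gene with more
than 20 site reads; the RPKM library size defaults to the total site
reads over the considered genes. Zero-length regions have RPKM 0.

Clustering is perturbation-consensus k-means (k = 5, 200 rounds, 70%
occurrence): each round (i) parametrically bootstraps every gene's
region counts at the gene's own read depth (multinomial resampling,
mapped back to the RPKM scale through the implied region lengths), and
(ii) runs k-means with distance 1 − Pearson correlation, component-wise
median centres, and k-means++ seeding. Rounds are aligned by greedy
centre matching to the best round (highest mean gene-to-centre
correlation); a gene's occurrence is the fraction of rounds in its modal
aligned cluster, and clusters are labelled by their centre's largest
component. Constant rows (Pearson undefined) fall back to Euclidean
assignment and are flagged.

The bootstrap is the load-bearing part: with only five components,
correlation margins are coarse (≈ 0.4 even for a noise row), so
re-initialization alone never flips an ambiguous gene and every gene
would reach high occurrence. Resampling at the gene's own depth flips
genes whose apparent regional preference rests on sampling noise while
leaving genuinely structured genes fixed. Clean one-hot profiles get
occurrence exactly 1.0; uniform-placement genes typically land at
0.2–0.6 and are unassigned. One caveat: a shallow gene with a couple of
reads in a very short region has a *sampling-stable* apparent
preference, and no bootstrap centred on the observed counts can unmask
it — a small tail of uniform genes (≈ 15–25%) therefore remains
assigned.

## Profiles, motifs, overlap

Metagene profiles normalize each gene's per-position counts to sum 1
over the transcript, take offsets from the start or stop anchor, and
average per offset over covering genes. Stem-loop profiles use offsets
−window..window−1 from the stem-loop's first base with per-gene
proportion normalization; the summary reports the upstream/downstream
split.

Motif targets are, per enriched gene, the binding region with the most
peaks (ties: most reads, then 5'-most), trimmed to ±20 nt around the
region centre; the background is every region with > 20 reads on a
non-binder gene, trimmed identically. The k-mer scorer uses
presence/absence per sequence (windows are only ~40 nt) with a one-sided
hypergeometric test and BH adjustment within each size (4/6/8/10).

The overlap test re-places the query segments (lengths preserved,
mutually non-overlapping, rejection sampling) uniformly within the
workspace and reports `p = (#samples with overlap ≥ observed + 1)/(N+1)`
and observed/expected fold. The empirical p is valid but discrete: with
few or tiny segments, ties at overlap 0 pile mass at p = 1, so
uniformity diagnostics need configurations where the overlap statistic
takes many values.

## Assay models

* **One-site binding** `FP(c) = FP_free + (FP_bound − FP_free)·c/(K_D + c)`
  fitted by least squares on total protein concentration (the
  ligand-depletion quadratic is unnecessary at ≥ 50-fold protein excess
  and is out of scope). Initialization: extremes of the readings and the
  concentration nearest half-saturation. Failures never raise:
  flat readings, optimizer failure, or K_D above 10× the top
  concentration return `converged=False` with a flag. Condition
  comparisons use one-way ANOVA on replicate K_D values; groups
  containing non-converged fits are excluded with a warning.
* **One-phase decay** `y(t) = (1 − plateau)·e^(−kt) + plateau` with y(0)
  fixed at 1, k ≥ 0, plateau ∈ [0,1), replicates pooled into one fit;
  t½ = ln2/k, with k < 10⁻³/h reported as stable (infinite t½). The
  fitter runs both the plateau and plateau-free models and keeps the
  AICc-preferred one: with short series a free plateau the data cannot
  support trades off against k and inflates half-life error. Rates are
  exactly unit-equivariant (hours→minutes divides k by 60).
* **Unwinding velocity**: if the whole curve is linear at r² ≥ 0.999 its
  slope is used; otherwise the baseline (mean/sd of the first
  `min_points` readings) defines the end of the lag — windows may start
  one point before the first exceedance, since that reading sits on the
  lag/linear breakpoint — and the longest window at r² ≥ 0.999 wins
  (ties: earliest). The strict default is deliberate: a window spilling
  a few plateau points still reaches r² ≈ 0.997. For noisy curves a
  lower threshold with a larger `min_points` is advisable.
* **qPCR**: comparative-Ct with efficiency fixed at 2.0 (configurable);
  RIP enrichment is the IP/input ΔCt against the IgG/input ΔCt,
  expressed as a fold.

## Cell-cycle deconvolution

The Watson pragmatic model: G1 and G2/M are Gaussians in DNA content,
S phase is a uniform distribution of content between the two means
blurred at the peaks' CV. The tallest peak initializes G1 (a lone peak
in the upper half of the axis with no companion at half its position is
read as G2/M with G1 absent); Gaussians are first fitted on their
uncontaminated flanks (left of G1, right of G2, extent from a half-width
estimate refined once), then all parameters are refined jointly by least
squares with the G2 mean constrained to 1.8–2.2× the G1 mean. Fractions
are the fitted component areas, normalized to 1. The joint refinement
matters: flank-only fitting leaves the S shoulder under the G2 peak
unexplained and overestimates G2/M by ~70% at CV 0.05. Debris/doublet
gating is assumed done upstream.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes;
its defaults are the study conditions of the test suite:

* 2000 genes, log-normal 5'UTR/CDS/3'UTR lengths (medians 150/900/400 nt,
  σ = 0.6, CDS ≥ 150 nt so the ±50 windows never overlap), 1–4 exons,
  both strands, eight chromosomes.
* Archetype mix 7/9/3/6/6% for 5'UTR/start/CDS/stop/3'UTR binding and
  69% unbound — a bound minority with unequal archetype prevalence
  (start and 5'UTR commonest, CDS-internal rare), mirroring the relative
  cluster sizes such positional analyses report; 50 histone-like genes
  (short 3'UTR ending in an annotated 16-nt stem-loop: 6-base stem,
  4-nt loop) whose sites all fall in the 30 nt upstream of the
  stem-loop.
* Counts: total RNA ~ NB(mean, dispersion α = 0.05; variance μ + αμ²);
  iCLIP mean = RNA-proportional baseline × 4 for bound genes. Library
  sizes 10⁶ each.
* Site placement: bound genes put 95% of reads in a Gaussian (sd 15 nt,
  comparable to the 50-nt region half-width, so clustering is
  non-trivially noisy) at the archetype anchor over a uniform floor;
  unbound genes draw 40% of reads from 1–3 nonspecific hotspots and the
  rest uniformly. The clumpy background is deliberate: real cross-link
  background is not uniform, and without it unbound genes get exactly
  zero reads-in-peaks and the enrichment normalization has nothing to
  anchor on.
* Assay tables: one-site curves (default noise 5 mP), decay series
  (t = 0 exactly 1 before noise), progress curves (flat lag, linear
  rise, plateau cap), DNA histograms (G1 Normal(μ, cvμ), G2/M at 2μ,
  S uniform-between-means then multiplicatively blurred; 128 bins over
  [0, 3.2μ]).

Identical configurations are byte-identical on disk. What the cohort
does **not** emulate: mappability and alignment artefacts, PCR
duplication, isoform mixtures, sequence-dependent cross-linking bias,
and overdispersion structure beyond a single NB dispersion — passing
tests certify the statistical machinery under the stated model, not
performance on any real library.

## Problem sizes and numerics

The default test-suite sizes are 120–550 genes for unit tests and the
full 2000-gene cohort for the end-to-end determinism check (≈ 25 s per
pipeline run); statistical criteria use 100–200 replicates. All
stochastic operations take explicit seeds; the pipeline derives
per-stage seeds by hashing the global seed with the stage name so
adding or skipping a stage does not shift downstream randomness.
Optimizers are scipy least squares with analytic initialization;
ill-posed fits return flagged results instead of raising. Known
numerical edges: empirical overlap p-values are discrete; k-means with
median centres can cycle (iteration cap 100, convergence on assignment
fixpoint, ties to the lowest cluster index).
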