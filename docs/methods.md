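# Methods

`clonalpop` analyses the population genomics and demography of a nearly
monoclonal, triploid freshwater crayfish meta-population: every animal
descends clonally (apomictically) from a single founder genotype, so all
genetic variation is created by new mutation, not by recombination or
allele-frequency dynamics. This note records the models, the parameter
choices, and the places where the design was genuinely open.

## Genomic model and variant pipeline

**Dosage recoding.** Genotypes are triploid; a site's state per specimen
is the alternative-allele dosage 0–3 (0/0/0 → 0, 0/0/1 → 1, 0/1/1 → 2,
1/1/1 → 3). Missing genotypes carry the code −1 and are excluded from
pairwise comparisons (no imputation in distances; per-site mean imputation
in PCA only).

**Site filters.** SNVs only (single-base REF and ALT; multi-allelic
records are split per alternative allele, indel/MNP alleles discarded);
per-sample read depth in [20, 200]; site quality ≥ 30; the site must be
covered in the reference specimen; reference-heterozygous sites are
eliminated so "polymorphic site" always means a reference-homozygous
position where at least one specimen carries a substitution. The quality
filter acts on the site (record) quality; whether the per-sample genotype
quality should be used instead is not decidable from the protocol, so the
choice is documented here and the filter configurable.

**Sharing analysis.** Sharing is computed on presence/absence
(dosage > 0), not on the dosage value: a site "shared within a group" is
carried by every member of that group. The two-set Venn compares the
within-group shared sets; per-specimen totals, unique counts, the
shared-by-k spectrum, and the fixed-site count partition the polymorphic
sites exactly (an identity the tests enforce).

**Annotation.** Gene context is assigned by interval containment against
a GFF3 (first match wins: CDS → coding, exon → UTR/noncoding exon, gene →
intronic, otherwise intergenic); GFF 1-based inclusive coordinates are
honored at parse and converted to half-open intervals internally. The
substitution spectrum is tabulated over the 12 ordered base changes with
transition/transversion totals.

## Population structure

**Distances.** Euclidean (default) or Manhattan on dosage vectors with
pairwise-complete handling of missing calls. Manhattan has the cleanest
semantics for clonal data: one dosage unit at one site contributes exactly
one count, so branch lengths read as allele-count differences. No single
canonical metric exists for dosage data; Euclidean matches the default of
common distance-tree tooling and is therefore the default here.

**Neighbor joining.** Classical Saitou–Nei agglomeration with the
Q-criterion, implemented in-package because the contract pins details the
library implementations do not expose: deterministic tie-breaking (the
lowest index pair of the working matrix wins), and clamping of negative
branch lengths to zero for output while the raw values are retained on the
result object. NJ is exact on additive matrices; the tests verify this
against a brute-force enumeration oracle (all topologies, least-squares
branch fits) for five taxa and against random additive trees for up to
six, with dendropy as the independent parser/path-length cross-check.

**PCA.** Column-mean centering only (no unit-variance scaling — dosages
share a scale), exact SVD, scores for min(samples − 1, sites) components.
Sign convention: the largest-magnitude loading of every component is
positive, making runs reproducible. An all-constant matrix yields a
zero-variance result with a warning rather than an exception.
scikit-learn's PCA serves as an independent cross-check in the tests,
never as the implementation.

**k-means row aggregation.** Sites are clustered into k = 200 centroid
rows (Lloyd, k-means++ init, one run, ≤ 100 iterations, fixed seed) for
heatmap display; centroids are ordered by average-linkage hierarchical
clustering. k equal to the number of sites short-circuits to the identity
aggregation. On strongly clonal matrices the number of distinct site
patterns can be far below 200; the analysis driver caps k at that number.

## VAF windows and LOH scan

At reference-heterozygous positions (dosage 1 or 2; quality strictly
> 30, depth strictly > 5) the variant allele frequency per site is
alt reads / total reads, expected at dosage/3. Windows contain a fixed
count of heterozygous positions (default 10,000; the analyses here use
1,000 at their smaller scale), never span contig boundaries, and retain
the final partial block flagged with its actual size. A window is flagged
when |observed mean − expected mean| > δ with δ = 0.10, half the gap
between the 1/3 and 2/3 heterozygous expectations. The δ rule makes
quantitative what is usually assessed visually on VAF plots.

Windowed means detect LOH only if the homogenization shifts the mean: in
an AAB-style triploid the great majority of heterozygous sites carry the
divergent allele on the single B haplotype (dosage 1), so LOH (1 → 0)
drags the window mean from ≈ 1/3 toward 0. The synthetic reference
mirrors this with an 85:15 dosage-1:dosage-2 mix; under a 50:50 mix,
balanced homogenization (1 → 0, 2 → 3) would partially cancel and windowed
means would lose power — a genuine limitation of the windowed-mean method,
not of this implementation.

## Mark-recapture census

**Schnabel.** N̂ = Σₜ CₜMₜ / Σₜ Rₜ with days pooled across traps (one
closed lake-wide population). The SE treats the total recapture count as
Poisson and propagates through the ratio: SE = N̂/√ΣR. This classic
treatment is one of several defensible variance choices; it is isolated
in one place and swappable. Zero recaptures
raise an explicit error pointing to the Chapman-style +1 correction
(available by flag).

**Saturation fit.** The cumulative marking curve is fit by nonlinear
least squares to y = a(1 − e^(−cx)) (both parameters free; trust-region
with a₀ = 1.2·max y and c₀ from a log-linearization; SEs from the
Jacobian). When the curve is still linear (c·x_max < 0.1) the asymptote
is an extrapolation with no data support; the fit warns and the bootstrap
ignores a non-finite asymptote SE.

**Stratified extrapolation.** Each trap is the sampling point for its
depth stratum's area-per-trap (47,500 m²/10 = 4,750; 16,000 m²/4 = 4,000;
29,000 m²/4 = 7,250). With per-trap catch totals the mature estimate is
reweighted by factor = Σ cᵢaᵢ / (ā Σ cᵢ), a no-op when all traps cover
equal areas. The total population is the corrected mature abundance
divided by the mature fraction f of the hand-catch size distribution
(share above the 6 cm trap cutoff); hand-catch density × lake area is
reported as an independent cross-check, because neither path alone pins
down the abundance of the small size classes.
Note that with catch-weighted correction the total is *not* guaranteed
monotone in a single stratum's area (the normalizing mean area moves
too); the density cross-check path is.

**Bootstrap SE.** 10,000 replicates, each perturbing: the mature estimate
(normal, its SE), the saturation asymptote (normal, its SE, applied as a
multiplicative ratio), stratum areas (normal, 10% relative SE), and the
hand-catch sizes (resampled with replacement, which varies f). Nonpositive
draws are rejected and redrawn, with the count reported. The combined SE
is the SD of replicate totals. Resampling the size distribution is this
package's interpretation of the size-ratio uncertainty component.

## Growth models and genetic variability

Three deterministic models from a single founder (N₀ = 1):

- exponential, N(t) = N₀e^(gt) with exp(g) = 200 (± 100) offspring per
  animal per year; the discrete step composes exactly to the closed form;
- discrete logistic, N_{i+1} = N_i + (g·dt)N_i(1 − N_i/N_max) with
  N_max = 192,000; N_max is a fixed point and the approach monotone for
  g·dt ≤ 1 (exceeding 1 warns of the oscillatory regime);
- strong Allee, ΔN = N(g·dt)(1 − A/N) with A = −3.1; a negative threshold
  makes small populations grow *faster* than exponentially, as expected
  for a parthenogenetic founder that needs no mate.

The step is dt = 1/365 year. The updates are stated per step with an
unscaled g; at exp(g) = 200/year a unit step is numerically meaningless,
so g is scaled by dt per step — the continuum limit of both discrete maps.

**Variability.** The current population's variability is the mean
per-specimen SNV count times the census size (≈ 5,865 × 192,000 ≈
1.1 × 10⁹, reported at its one-significant-figure level 1e+09). Mapping a
simulated trajectory onto a variability curve is the one genuinely open
reconstruction in this package; three strategies are implemented and every
result records which produced it:

- **population-history** (default): v(t) = μG·∫₀ᵗ N(s)ds — the expected
  number of mutation events over the population's entire history. Every
  mutation event in any lineage of a clone creates a distinct heritable
  variant, so the integral of mutation events over all lineage-years is
  the natural total-variability measure; it is also the only strategy
  whose central-parameter intersection falls inside the reported
  uncertainty band, which supports it as the reconstruction.
- census-accumulated: v(t) = N(t)·μG·t (per-lineage accumulation times
  census size — the current-population formula applied at time t);
- annual-rate: v(t) = N(t)·μG (new variants arising per year).

with μ = 3.6 × 10⁻⁹ per bp per year and G = 3,511,656,756 bp. The
intersection time t* is the smallest t with v(t) ≥ target, refined
between bracketing samples (log-linear interpolation + bisection) to
10⁻³ year. The error band evaluates t* at exp(g) = 300 and 100; the
logistic band would additionally admit the N_max SE. Under the default
strategy and central parameters, t* ≈ 3.75 y with band ≈ [3.49, 4.28].

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not sequencing physics:

- a reference profile with a chosen fraction of heterozygous sites
  (dosage 1:2 at 85:15, see the VAF section), fixed bases, qualities and
  depths;
- mutations placed on a fixed founder → population → individual
  star-of-stars lineage (the aquarium-ancestor history), each mutation a
  0 → 1 dosage change at a distinct reference-homozygous site — matching
  the pipeline's domain exactly;
- reads: per-site depth from a negative binomial (mean 40, dispersion 0.1;
  Poisson at zero dispersion), alt counts binomial around dosage/3 folded
  with an error rate (default 10⁻³), written as a plain-text VCF v4.2
  that is byte-identical for a fixed seed;
- a closed-population trap survey: each day every animal is captured with
  probability 1 − (1 − p)^(n_traps) and assigned a trap uniformly; marks
  persist; defaults (18 traps, 10 days, ~23,000 trappable animals,
  p chosen to yield a few hundred captures) put the survey in the same
  sparse-recapture regime as the original field design;
- hand-catch tables: three density points around true N/area and a
  two-component size distribution with 12% of animals above the 6 cm
  cutoff (the ratio of the mature to the total census estimate).

Not emulated: read-level errors correlated along fragments, mapping
artifacts, indels, trap heterogeneity or behavioral response (trap-shy /
trap-happy animals), and open-population demography during the survey.
Passing tests therefore demonstrate the correctness of the estimators on
data satisfying their own assumptions, not robustness to these real-world
violations.

## Numerical choices and problem sizes

Determinism: every stochastic component takes a seed and uses an isolated
`numpy` generator; identical seeds give bit-identical VCFs, surveys and
bootstrap SEs. Degenerate inputs are handled explicitly (empty VAF tracks
warn; constant matrices warn in PCA; zero recaptures and zero mature
fractions raise; N = 0 absorbs in the Allee map).

The bundled analyses and tests run at reduced scale chosen to exercise
every code path with comfortable statistical margins: 30,000 sites and 15
specimens in the analysis cohort (2,000 sites in test fixtures), VAF
windows of 1,000 heterozygous positions, 100-seed error-rate studies for
the LOH scan, and 100–200 replicate calibrations for the Schnabel
estimator and the saturation fit. All thresholds above are package
defaults and can be set per run.
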