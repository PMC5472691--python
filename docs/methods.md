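# Methods

This note documents the models, parameter choices and numerical conventions
behind `hyenabiome`, and what the synthetic-data generator does and does not
emulate.

## Study design being emulated

A cross-sectional fecal survey of a social, female-dominated carnivore:
adult females carry a standardized dominance rank spread evenly over
[−1, +1] (top = +1, bottom = −1, median = 0; a single-member hierarchy
scores 0), and hosts below 24 months are juveniles. Juveniles carry no rank
class because the rank analysis concerns adult females only. Each fecal
sample is amplified across a panel of 16S (bacterial) and 18S (eukaryote)
amplicons in technical replicates on one PCR array that also carries water
negative controls, and a subset of samples is examined by McMaster
flotation for parasite eggs and oocysts.

## Synthetic-data generator

The generator produces the statistical structure the pipeline consumes;
its defaults are the study conditions.

* **Cohort**: 42 hosts (35 adults with ranks, 7 juveniles), one sample
  each; 2 technical replicates per sample, 2 water controls, 2 deliberately
  failed replicate PCRs. The panel has 4 16S + 44 18S amplicons with
  20-base primer pairs.
* **Community**: a pool of ~39 bacterial genera in 6 phyla and ~47
  eukaryote genera in 8 phyla plus 10 real parasite genera with correct
  lineages (needed by the taxonomic-agreement screen). Eight genera per
  domain form a *core* present in every host, drawn log-normal with a +1.5
  location bonus — core members of real gut communities are the abundant,
  ubiquitous fraction, and their presence makes median-of-ratios size
  factors well defined. The remaining richness is drawn per host:
  juveniles draw 18 bacterial genera and adults 18 + 8 (the adult/juvenile
  richness gap scaled to the pool, matching the direction and order of the
  reported medians 49 vs 41); high-ranking adults draw 20 + 8 eukaryote
  genera against 20 for low-ranking ones. Non-core abundances are
  log-normal(4, 1.5) on the read scale.
* **Parasites**: seeded at 80% prevalence with log-normal(7, 1.5)
  intensities, i.e. median ≈ 1,100 epg — inside the printed intensity range
  of the surveyed helminths and coccidia (means roughly 800–21,000 epg) and
  well above the McMaster detection limit, where log-log slope recovery is
  meaningful.
* **Reads**: each genus is amplified by a fixed subset of same-domain
  amplicons; the template is an amplicon-specific 400-base slice of the
  genus reference (1,500 bases, random). Read 1 is the forward primer plus
  the template 5′ end, read 2 the reverse primer plus the reverse
  complement, 2×250 at constant Q35, with substitutions applied uniformly
  over the whole read (primer included). With probability `chimera_rate` a
  pair derives from a two-parent prefix+suffix join within the same
  amplicon; the second parent is chosen proportionally to its template
  concentration, as chimera formation in PCR is. Failed replicates receive
  Poisson(2) pairs and water controls Poisson(5) cross-contamination pairs
  drawn uniformly from all templates.
* **Coprology**: per morphotype, expected eggs per gram follow
  log10(1+FEC) = a + b·log10(1+abundance) of the coupled taxa (defaults
  a = 0, b = 1). The total counted eggs are gamma-Poisson around
  FEC/25 with the configured overdispersion (pure Poisson at dispersion 0),
  split multinomially over four chambers and over the morphotype's size
  classes.

**What the generator does not emulate**: primer binding biases, chemistry
artifacts (primer dimers, index hopping), quality-score decay along the
read, length variation between amplicons, phylogenetic correlation between
reference sequences (references are independent random sequences, so
genera are easier to classify than real 16S/18S genera), and abundance
covariance between taxa. Passing tests therefore demonstrate the
correctness of the pipeline's logic and its statistical calibration, not
classifier performance on real reference databases.

## Stage conventions and numerical choices

* **Quality filter** (truncLen 170, maxN 0, maxEE 2, truncQ 2): truncation
  applies to the raw read including the primer, then the primer is trimmed
  during stratification; primers sit well inside 170 bases so the order
  cannot change assignments.
* **Stratification**: zero-mismatch IUPAC match of both primers at base
  one. A pair matching several panel entries goes to the longest combined
  primer; exact ties are left unassigned (deterministic and conservative).
  N in a read never matches. Panels with primer pairs identical under
  IUPAC expansion are rejected outright.
* **Variant inference** replaces the upstream error-model denoiser with a
  fully specified abundance-skew rule (d_max 1, skew 0.1), exposed behind a
  pluggable interface. Ties in abundance are broken lexicographically so
  the result is order-independent. Mates are kept in lockstep and
  concatenated (forward + 10 N + reverse complement of reverse) before
  dereplication.
* **Bimera removal**: parents must be ≥ 2× as abundant as the candidate in
  the same sample; the flag applies table-wide when a candidate is flagged
  in a majority of the samples where it occurs, and the table's most
  abundant variant is never flagged. No published screening parameters
  exist for this step; the 2× one-off-parent convention is this package's
  documented default.
* **Replicate QC**: complete-linkage clustering on Euclidean distances of
  log10(1+count) vectors, cut at k = 2; the cluster holding the majority of
  water controls is the failure cluster. Linkage, distance and cut are this
  package's choices — failed-vs-working PCRs are strongly bimodal, so any
  reasonable combination separates them; this one is deterministic.
* **Median scaling** is interpreted as scaling every sample total to the
  median total (the one reading that makes samples comparable by a single
  scalar each). Diversity uses rarefied counts (multivariate
  hypergeometric at the smallest sample total); ordination, PLS and the
  correlation screen use normalized counts.
* **Classifier**: word length k = 8; bootstrap 100 × ⌊W/8⌋ words;
  min_boot 0.5 (the conventional assignment default). Words containing N
  (the mate spacer) are skipped. Exact score ties in a bootstrap draw are
  broken at random from the seeded generator — an uninformative query must
  not accumulate support for the lexicographically first genus. Because
  lineages are nested, per-level support is monotone non-increasing from
  phylum to genus and cutting below min_boot always leaves a defined
  prefix.
* **Genus exclusions** run in the order: uninformative genus names
  (undefined/uncultured/unidentified/environmental/metagenome/incertae
  sedis, case-insensitive) → sole genus of its phylum → undefined phylum.
* **McMaster multiplier**: dilution/(chambers × chamber volume)
  = 15/(4 × 0.15) = 25 epg per counted egg — the unique multiplier
  consistent with minimum non-zero intensities of 25 in the printed
  summaries.
* **Intensity statistics** are computed over positive samples only
  (standard intensity-of-infection usage). The mean interval is a
  t-interval floored at 0 with the raw lower bound retained; the median
  interval comes from binomial order statistics and is NA when the
  positive count is too small. The published tables do not state their CI
  method; these choices are documented, not asserted to be identical.
* **Spearman p-values** use the t approximation with n−2 df (the common
  default at n ≈ 32 with ties).
* **Exact Mann-Whitney**: U from tie-averaged ranks; the two-sided p
  doubles the smaller tail of the exact permutation distribution of the
  rank-sum (capped at 1), computed by a shift algorithm over doubled ranks
  (integers even under ties). It matches brute-force enumeration for all
  n1+n2 ≤ 10. Tie conventions differ between implementations, hence the
  explicit definition.
* **Chao1** is the bias-corrected form S + f1(f1−1)/(2(f2+1)), defined at
  f2 = 0. Shannon and Pielou use natural log.
* **NMDS** minimizes Kruskal stress-1 by iterative majorization with
  pool-adjacent-violators monotone regression; best of n_restarts random
  starts, deterministic given the seed. A metric (classical) variant is
  available behind a flag. Stress is non-increasing within a restart by
  construction (the iteration stops on a numerical stall).
* **PLS-DA** is PLS1 (NIPALS) on a ±1-coded response; a held-out sample is
  classified by the sign of its predicted response. The retained axis
  count is the smallest one attaining the maximal LOO accuracy. Under
  label permutation the calibrated null quantity is the LOO accuracy at a
  *fixed* axis count; taking the best count adds selection optimism
  (~4 points on the fixtures here).
* **Loading enrichment**: working loading is axis 1, or the elementwise
  product of axes 1–2 when two axes separate the groups (whether the
  original combined-quartile test used the product's quartiles or the
  union of per-axis quartiles is ambiguous; the product is the default and
  both are available). Quartile boundaries include ties. The odds ratio is
  the sample ad/bc (not the conditional MLE), documented divergence from
  the common R implementation.
* **Differential abundance**: median-of-ratios size factors normalized to
  geometric mean 1; when no taxon is positive everywhere the fallback uses
  taxa positive in ≥ 90% of samples with geometric means over positive
  entries, and samples still uncovered are scaled by relative total depth.
  Per-taxon NB dispersion is estimated by profile maximum likelihood
  (moment initializer/fallback, bounded in [1e−8, 1e3]) on the full model
  and held fixed in both fits of the LRT; there is **no** empirical-Bayes
  shrinkage across taxa — a documented simplification of the cited
  approach. Taxa with fewer than 3 positive samples are reported NA and
  excluded from the BH family.

## Problem sizes used in tests and the acceptance script

Unit tests run on 6–16 host cohorts with 7–10 amplicon panels and depths of
120–400 pairs per replicate. The chimera-screening check uses a ~200
template fixture at depth 4,000 (parents must be sequenced for a de novo
screen to see them). Calibration checks use 100–500 replicates (PLS
permutations, NB null taxa, rank-test power runs at n = 40 hosts). The
acceptance script's end-to-end run uses 16 hosts, 8 amplicons and depth
200. These sizes were chosen so each recovery or calibration quantity has
enough replication to be a stable assertion while the whole suite stays
desk-scale.

## Known limitations

* The simplified variant-collapsing rule has no quality-aware error model
  and no pooled multi-sample inference; it is exact on the synthetic error
  process it is tested against, not a replacement for a learned denoiser
  on real data.
* The classifier trains on whatever reference FASTA + lineage table it is
  given; curation of the training set (the original study expanded a
  public database with BLAST hits) is out of scope.
* Three-parent chimeras, batch effects, compositional (log-ratio)
  transforms and PERMANOVA are not implemented.
* The exact Mann-Whitney distribution is computed by dynamic programming
  in float64; subset counts are exact well beyond the cohort sizes used
  here, but for n in the many hundreds a log-space implementation would be
  needed.
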