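# Methods

## Background and model

Cell-free DNA is released into the cerebrospinal fluid as nucleosome-protected
fragments: DNA wrapped around histones resists nuclease digestion, while linker
and nucleosome-free DNA is degraded. At an active promoter the nucleosome-
depleted region (NDR) around the transcription start site (TSS) therefore
leaves a local dip in sequencing coverage, whereas a silent, densely
nucleosome-packed promoter yields a flat profile. The footprinting module
exploits this to infer promoter activity from targeted deep sequencing of
2 kb windows (TSS ± 1 kb) over a tumor-classification gene panel, while the
concordance modules compare somatic SNVs and copy-number alterations between a
patient's primary tumor and CSF cfDNA.

## Coordinates and formats

BED and bedGraph are 0-based half-open on disk; SEG and VCF are 1-based.
Internally, single positions are 1-based; TSS windows are stored in genomic
orientation and flipped into transcript orientation only when the coverage
matrix is built, keeping on-disk files standard-compliant. Coverage tracks are
sparse per-chromosome interval sets; positions absent from a bedGraph read as
depth 0. Readers validate what the formats cannot express (non-overlap,
non-negative depth, unique gene ids, end ≥ start) and report the offending
line.

## TSS footprinting

* **Matrix.** Per gene, per-base depth over the 2 kb window is averaged into
  bins (default 20 bp, 100 bins; the bin width is a resolution/noise
  compromise — fine enough to resolve a ~300 bp NDR, coarse enough to damp
  Poisson noise). Minus-strand rows are reversed so bin 0 is always 1 kb
  upstream.
* **CPM.** Values are scaled by 10⁶ / library size (deduplicated reads) so
  samples of different sequencing depth are comparable.
* **Two-state clustering.** Euclidean k-means with k = 2, 10 seeded restarts.
  Rows are put in a canonical (lexicographic) order before fitting so the
  result is invariant to input row order. The cluster with the lower mean NDR
  coverage is labelled *open* (ties go to the cluster containing the first
  gene). Cluster quality is summarized as the mean silhouette score.
  All-zero windows are dropped with a warning rather than clustered as flat;
  identical profiles yield a flagged degenerate result.
* **Informativeness.** A sample enters cross-sample analysis only if
  cfDNA concentration > 10 ng/mL, library ≥ 10⁶ deduplicated reads, and mean
  silhouette ≥ 0.25. The first two cut-offs are the empirical boundaries that
  separate informative from non-informative footprinting samples; the
  silhouette threshold is a quantitative surrogate for the visual judgement
  that two coverage patterns are "clearly distinguished" — 0.25 sits between
  the near-zero silhouettes of noise-dominated samples and the ≥ 0.5 values
  of cleanly bimodal ones.
* **NDR z-scores.** The NDR is taken as TSS ± 150 bp (bins whose centres fall
  inside that window), a conventional promoter-NDR extent. Per gene and
  sample, v = log₂(mean NDR CPM + 1); rows are z-scored across samples with
  the population SD; zero-dispersion rows are set to all zeros. z < 0 ⇒
  *expressed* (less protected cfDNA than the row average), z ≥ 0 ⇒ *silent*;
  the z = 0 boundary maps to silent, a measure-zero convention.
* **Discriminating genes.** A gene discriminates two entities when every
  sample of one entity has z < 0 and every sample of the other z > 0; the
  reported direction is the entity the gene appears expressed in. This strict
  all-samples rule needs no multiplicity correction but is only meaningful for
  the small per-entity sample counts it is designed for.
* **Heatmap.** Gene rows are clustered agglomeratively (Euclidean distance,
  average linkage — a standard choice where no linkage is dictated by the
  data); leaf order is scipy's deterministic order. Samples are ordered by
  entity, or clustered the same way on request.

## Variant concordance

Records are keyed by (chrom, pos, ref, alt); matching is exact, assuming
indels were normalized upstream. The detection filter (alt reads ≥ 3, depth
≥ 10, VAF ≥ 1%) mimics conventional post-caller somatic filters. Partitions
are plain set algebra, so conservation (|shared| + |private| = table size),
disjointness and tumor/CSF symmetry hold by construction and are property-
tested. VAF concordance is the Pearson product-moment correlation with the
two-sided t-distribution p-value (n − 2 df), requiring ≥ 3 pairs and
non-degenerate variance.

The ctDNA fraction is estimated as min(1, 2 × median CSF VAF) over shared
somatic variants, excluding variants inside non-neutral CSF segments when
segment calls are supplied: a clonal heterozygous diploid variant has
expected VAF = ctDNA fraction / 2, and the median is robust to a subclonal
minority. The estimate's method tag records this choice; the interface
accepts any variant subset, so alternative estimators can be layered on.
The estimator is biased upward when most shared variants are subclonal and
breaks down under heavy aneuploidy without segment data.

## Copy-number concordance

Segment classes use conventional log₂-ratio thresholds: ≥ 2.0 amplification,
≥ 0.3 gain, ≤ −0.3 loss, ≤ −1.5 homozygous deletion, else neutral. Matching
operates at alteration granularity: two non-neutral segments match when they
share a chromosome, point the same way (amplification pairs with gain,
homozygous deletion with loss) and have reciprocal overlap ≥ 0.5 (greedy
best-overlap pairing). Every non-neutral segment receives exactly one status
(both / tumor_only / csf_only), and raising the overlap threshold can only
remove matches — both are property-tested. Canonical descriptors resolve
segments covering ≥ 50% of a chromosome arm to arm-level names ("17p loss")
against a packaged GRCh37 arm table; focal events are named by locus.

## Diagnostic tallies

Each cohort patient carries the alterations that established the molecular
diagnosis, flagged `diagnostic` or `suggestive` (a subgroup-compatible but
not per-se diagnostic finding, e.g. a 1q gain in CNS neuroblastoma FOXR2),
with CSF detection status and optional notes (non-contributive sample, gene
absent from the CSF panel, no copy-number analysis possible for targeted
data). Notes never count as detection. A patient counts as diagnosable from
CSF when at least one *diagnostic*-flagged alteration was detected; the
suggestive flag keeps CNA-detection tallies and diagnostic tallies distinct.
Entity labels in the packaged fixture are assigned from the driver
alterations; medulloblastomas without a subgroup-defining driver in the table
remain `MB_NOS`, so one of them is in truth the cohort's second CNS
neuroblastoma FOXR2 case — this affects no tally, since entity-restricted
tallies are only taken over the driver-labelled entities.

## Synthetic data

The generators emulate the statistical structure of a CSF cfDNA study, not
its biology in detail:

* **TSS coverage.** Expected depth is
  base × (1 − d·exp(−(x−TSS)²/2σ²)) × (1 + d·A·cos(2πx/190)) for expressed
  genes and flat base for silent ones, with per-base Poisson counts.
  Defaults: depletion d = 0.8, σ = 75 bp (a ~300 bp NDR), flank ripple
  A = 0.1 with the 190 bp nucleosome repeat, scaled by d so that d = 0 makes
  the states indistinguishable by construction. Base depth =
  0.2 reads/bp × (ng/mL cfDNA) × (library reads / 10⁶): 10 ng/mL at a
  one-million-read library gives 2 reads/bp, placing the 10 ng/mL
  informativeness boundary in a regime where clustering genuinely degrades.
  Because depth scales with concentration, cross-sample z-scoring is most
  meaningful between samples of comparable concentration; the
  informativeness gate bounds this in practice.
* **Variants.** Per patient, planted shared / tumor-only / CSF-only key sets
  (defaults 83 / 18 / 5, the reported cohort means) on random loci; tumor VAF
  ~ Beta(10, 10) (clonal heterozygous with purity spread); CSF VAF = tumor
  VAF × ctDNA fraction (default uniform on 0.15–0.86, the reported range);
  depths Poisson around 100× (exome-scale), alt counts binomial. Not modelled:
  sequencing error, mapping artifacts, fragment-length profiles, copy-number
  interaction with VAF.
* **Copy number.** Each planted alteration occupies its own autosome
  (non-overlap by construction) with a class-consistent log₂ ratio drawn
  independently per compartment; defaults 4 shared / 2 tumor-only /
  1 CSF-only alterations reflect the mostly concordant profiles with
  occasional compartment-private changes seen in such cohorts.

Passing recovery tests on these generators shows the pipeline's operations
are correct and well-calibrated under the assumed noise model; it does not
certify performance on real cfDNA, where GC bias, capture efficiency,
duplication structure and subclonal architecture add variance the simulator
omits.

The packaged TSS panel (`tss_panel_synthetic.bed`) is likewise a synthetic
stand-in: it reproduces the panel's structure (112 2-kb TSS windows including
named marker genes, 8 control TSSs — 4 ubiquitously expressed, 2 CNS-silent,
2 CNS-expressed — 6 coding regions, 5 hotspot loci) with placeholder names
and coordinates where the real design is not public.

## Problem sizes and numerical choices

The recovery suites run 25 replicate samples of 40 genes (20 expressed, 20
silent) for footprinting and 100 replicate patients of 50 variants for the
ctDNA estimator — sizes at which the Monte-Carlo error of the checked
quantities is well below the asserted margins. k-means uses 10 restarts;
exhaustive-enumeration cross-checks are limited to ≤ 12 genes (2¹¹ partitions)
and hand-rolled linkage checks to 6 rows. Z-score assertions use 1e-9
tolerances (pure arithmetic); simulation-based assertions use margins derived
from binomial/Poisson standard errors.

## Known limitations

* Exact-key variant matching misses representation-shifted indels.
* The ctDNA estimator assumes diploid heterozygous clonal variants; no
  purity/ploidy model.
* Arm-level descriptors use fixed GRCh37 arm boundaries; no other genome
  build is packaged.
* The two-state occupancy model is a simplification: partially accessible
  promoters produce intermediate profiles that k-means must force into one of
  two states.
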