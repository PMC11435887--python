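# Methods

This note documents the statistical procedures fmtkit implements, the
choices made where the design was genuinely open, and what the synthetic
trial generator does and does not emulate.

## Study design the pipeline assumes

A placebo-controlled oral-FMT trial in dogs with tylosin-responsive
enteropathy, with five sampled visits per trial dog — screening (on
tylosin), inclusion (relapsed after tylosin withdrawal), endoscopy (back on
tylosin, the pre-treatment baseline), end of treatment, and end of
post-treatment follow-up — plus fecal samples from the single stool donor
and from a healthy reference cohort. Analyses start at the ASV level;
read-level processing (denoising, chimera removal, taxonomy classification)
is out of scope, as is rarefaction.

## Feature-table processing

Processing order for the diversity/composition branch is rare-ASV removal →
low-count filter → genus aggregation → low-variance filter → total-sum
scaling. The order of the middle steps is configurable
(`feature_table.order`); scaling at the genus level is the default because
the protocol the pipeline mirrors applies total-sum scaling to the
genus-aggregated table. The engraftment branch consumes the rare-ASV-filtered
ASV-level table directly, and differential abundance applies its own
prevalence filter to the aggregated counts.

* **Rare-ASV removal** drops ASVs whose summed count across the entire
  dataset is ≤ 2 (singletons/doubletons). Rationale: such ASVs are likely
  sequencing artifacts, and in the engraftment computation a spurious ASV
  shared between donor and recipient by chance inflates the rate.
* **Low-count filter**: keep features with ≥ `min_count` (4) counts in
  ≥ `min_prevalence` (20%) of samples, both boundaries inclusive. The
  one-sentence description this rule descends from ("filter features with
  <4 counts in at least 20% of the values") is ambiguous; the conventional
  minimum-count/minimum-prevalence retention reading is implemented.
* **Low-variance filter**: rank features by interquartile range across
  samples and remove the lowest floor(`drop_fraction` × n) of them, ties
  broken by feature id so the result is deterministic. Note this is a rank
  trim, not a projection: reapplying it removes a further 10%. The pipeline
  applies it exactly once.
* **Total-sum scaling** divides each cell by its sample total. Zero-total
  samples are excluded with a collected warning rather than an error so
  partial datasets still process. One practical consequence: with a
  whole-dataset prevalence filter and only two donor samples among ~100,
  donor-specific taxa can be filtered away entirely, leaving the donor
  samples empty at scaling time; they are then simply absent from the
  diversity branch (the engraftment branch, which is where the donor
  matters, never sees these filters beyond rare-ASV removal).
* **Aggregation** sums counts over ASVs sharing a rank label; ASVs without a
  label at that rank pool under "unclassified <nearest assigned parent>"
  (e.g. "unclassified Lachnospiraceae"). Per-sample totals are conserved
  exactly.
* **"Other" pooling** for composition summaries: taxa whose mean relative
  abundance across the displayed samples falls below 1% (genus) or 1.4%
  (species) are summed into an "Other" column; rows still sum to 1.

## Engraftment

Presence means count ≥ 1 in at least one contributing sample, evaluated on
the rare-ASV-filtered table. Pre-FMT presence uses the endoscopy visit (the
last sample before the first capsule); a per-dog `baseline_visit_overrides`
config entry handles dogs that skipped endoscopy. Post-FMT presence pools
the treatment and post-treatment samples (detection in either counts).
Donor presence pools all donor samples by default. The candidate set is
donor minus pre-FMT presence; the rate is 100·|candidates ∩ post|/|candidates|.
An empty candidate set is an error instructing that the dog be excluded —
with a real donor it means the recipient already carried every donor ASV,
so the rate is undefined rather than 0 or 100. Rates are reported to two
decimals; summaries give mean, median (midpoint convention), min, max, and
per-ASV engraftment frequency across recipients. No sequencing-depth
correction is applied to the denominator, and engraftment is binary
presence — abundance-weighted variants and sub-ASV (strain) resolution are
out of scope.

## Diversity

Shannon entropy H = −Σ p log p uses the natural log by default (the
convention of the platform this mirrors); the base is configurable.
Group comparisons use Kruskal–Wallis with tie correction; the all-identical
degenerate case returns (H = 0, p = 1). Pairwise contrasts are two-group
Kruskal–Wallis tests reported as raw p-values by default, matching how such
pairwise comparisons are usually reported; a Benjamini–Hochberg option
exists but is off.

Bray–Curtis dissimilarity 1 − 2Σmin(x,y)/(Σx+Σy) is computed on relative
abundances; the op itself performs no normalization, so callers decide the
scale (this makes the metric's scale dependence explicit). PERMANOVA
partitions squared distances: SS_total = Σ_{i<j} d²/n, SS_within summed per
group over within-group pairs divided by group size, pseudo-F =
(SS_between/(a−1))/(SS_within/(n−a)). The p-value is (exceedances+1)/
(permutations+1) under seeded label permutation, switching to exhaustive
enumeration over the distinct labelings of the label multiset when there
are ≤ 10,000 of them — the p-value is then exact, with the identity
labeling counted as an exceedance. 999 permutations is the default (the
p-grid then includes 0.001); the seed is recorded in the output so
permutation p-values are bit-reproducible.

## Differential abundance

Compositional data only identify relative abundances, so per-taxon
log-linear-model coefficients share an additive bias (the log fold change
of the unobserved total load). The model implemented here follows the
bias-corrected linear-model approach: per taxon,

  log(winsorized proportion + c) ~ phase + (1 | dog)

where c = pseudocount (0.5) × the smallest positive proportion in the
matrix — a global detection-floor surrogate chosen for determinism — and
winsorization caps each taxon at its 0.97 empirical quantile
(linear-interpolation convention, applied per taxon across samples before
the log transform, no re-normalization). The random-intercept fit profiles
the REML criterion over the single variance ratio λ = σ²_dog/σ²_e; at each
candidate λ the GLS solution is exact via the grouped Woodbury identity, so
the fit is fast and deterministic. When λ̂ hits the zero boundary (or the
standard error degenerates) the taxon is refit with dog fixed effects and
flagged `fixed` in the output. t-tests use the fixed-effect residual
degrees of freedom (n − dogs − 1) in both paths, again for determinism.

The compositional bias is estimated as the mode of the per-taxon raw
coefficients (Gaussian KDE on a 512-point grid; median fallback below 10
taxa) and subtracted from every coefficient — a rigid shift that preserves
the coefficient ranking. The primary p-value tests the corrected
coefficient and feeds BH adjustment; the uncorrected coefficient's p-value
is also reported (`raw_p_value`) because it is the exactly calibrated
quantity under the null — with one pre and one post sample per dog the
mixed fit reduces to a paired t-test — whereas the mode-estimated shift
adds a small cross-taxon noise term to the corrected statistic. Arms are
fitted separately (FMT pre-vs-post, placebo pre-vs-post); zero-variance
taxa are excluded with a warning, and fewer than 3 taxa is an error since
the bias is then not estimable.

## Clinical layer

CCECAI is the sum of nine 0–3 items; bands are 0–3 insignificant, 4–5 mild,
6–8 moderate, 9–11 severe, ≥ 12 very severe. Remission requires CCECAI ≤ 3
and mean FCS ≤ 3 over the 3-day window ending at the evaluation day (all
defecation events pooled, no per-day pre-averaging). Relapse is CCECAI > 3,
or clinical signs of chronic enteropathy together with FCS ≥ 4 — parsed
with that precedence, which is the only reading under which a dog can
relapse on CCECAI while keeping normal fecal consistency (a case the
scoring rules must support), and under which remission and relapse are
mutually exclusive on the entire score grid (verified exhaustively).

FDM% from duplicate weighings is reported as the mean of the two replicate
percentages with their CV. Two conventions exist because the formula that
circulates in the literature, ((wet − dry)/wet)·100, computes the moisture
percentage while reported dry-matter values are on the dry/wet scale; the
default is dry/wet·100 with the printed variant available explicitly, and
the two always sum to 100.

Capsule dosing covers all weights above 5 kg with half-open bands
((5,10] → 1, (10,20] → 2, (20,30] → 3, > 30 → 4); the printed table leaves
(10, 11) kg unassigned, and the half-open reading closes that gap. Weights
below 5 kg are outside the dosing table and an error.

Phase outcomes count a dog as evaluable in a phase if it has a disposition
record there and was not excluded; responder/relapse percentages are
rounded half-up to one decimal, matching clinical reporting. The group
contrast uses Fisher's exact test on the 2×2 relapse table — at 6–7
evaluable dogs per arm an exact test is preferable to an asymptotic
logistic model, and its p-values do not depend on any software's model
settings. Cumulative relapse across phases counts dogs relapsed in either
phase over dogs never excluded. The FCS~FDM relationship is ordinary least
squares with Pearson r and r²; change-from-baseline contrasts use ANCOVA
(follow-up ~ group + baseline).

## Synthetic trial generator

The generator emulates: one donor community (Dirichlet over a power-law
base with one dominant taxon, total concentration 100 so nearly the whole
60-ASV donor pool clears the detection limit at depth 20,000, giving
per-recipient candidate sets in the mid-50s); dysbiotic pre-FMT recipients
(a steeper power law with total concentration scaled down by
1 + dysbiosis_severity, lowering expected Shannon diversity and shifting
composition away from the healthy centroid); placebo post visits as drift
redraws; FMT post visits that add each donor-specific ASV independently
with probability `engraft_prob` (default 0.30) at a relative abundance
floored at `transfer_floor_reads`/depth (default 5 reads, making detection
near-certain; raise the floor to 50 to make ground-truth recovery exact,
lower it to study detection-limited engraftment); a healthy cohort of 30;
and the clinical layer (per-phase relapse draws at the observed study
rates — treatment-phase probabilities 2/7 for FMT and 0.5 for placebo,
post-treatment 0.5 and 0, all configurable — CCECAI totals ≤ 3 in
remission and ≥ 4 at relapse,
FDM ~ Normal(35, 5²) shifted down by 8 points at relapse, and diary FCS =
5 − 0.09·FDM + Normal(0, 0.397²) clipped to the half-point grid; the
analytic Pearson correlation of the unclipped link is
−0.45/√(0.45² + 0.397²) = −0.75).

Donor-specific ASVs are disjoint from the recipients' background pool by
construction so transfer ground truth is unambiguous; an overlap fraction
is configurable to stress the set-exclusion logic. All randomness flows
from the single config seed, and bundles are byte-identical across runs.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: taxonomic correlation structure (taxa are
independent given the Dirichlet draw), longitudinal autocorrelation beyond
independent redraws, sequencing error and chimeras, variable library sizes,
donor lot-to-lot variation beyond resampling, and any biological coupling
between microbiome state and clinical relapse (the two layers are
simulated independently).

## Numerical choices

* Proportions validate to row sums within 1e-9; distance matrices to
  symmetry within 1e-12.
* Quantiles (winsorization caps, IQR) use the linear-interpolation
  convention throughout.
* Percentages print with decimal half-up rounding (0.25 → 0.3), not
  banker's rounding.
* Permutation tests derive all draws from an explicit integer seed;
  exhaustive enumeration uses lexicographic next-permutation over the label
  multiset, so results are independent of hash ordering.
* The REML profile in the mixed model is optimized on log(1+λ) over
  λ ∈ [0, 1e4] with a bounded scalar minimizer (xatol 1e-8); a boundary
  comparison against λ = 0 decides the fixed-effect fallback.

## Known limitations

* Engraftment is presence/absence at the ASV level; two recipients sharing
  an ASV with the donor by environmental coincidence are indistinguishable
  from true transfer (mitigated, not removed, by excluding pre-FMT-shared
  ASVs).
* The trial-scale statistics (6–7 dogs per arm) are reported exactly but
  are inherently underpowered; the exact-test p-values in the disposition
  summary should be read accordingly.
* The differential-abundance model assumes the winsorized log-proportion is
  approximately Gaussian; at very low depths or for very rare taxa the
  pseudocount floor dominates and coefficients shrink toward zero.
* BIOM support is read-only and covers the common 1.0 JSON and 2.1 HDF5
  layouts (ids + matrix); rich observation metadata beyond taxonomy is
  ignored.
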