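# Methods

## Neighbourhood co-localisation enrichment

For one sample, all ordered cell pairs (i, j), i ≠ j, with centroid
distance ≤ R contribute one encounter to C[type(i), type(j)]. The distance
threshold is inclusive and no edge correction is applied at field
boundaries — cells near the border simply see fewer neighbours, which
cancels between observed and expected to first order. The expected count
under random architecture is X_exp[q,n] = (N_n/N_total)·T_q: the neighbours
a q-cell encounters, allocated proportionally to type abundance. The
centred statistic e = log2(C/X_exp + 1) − 1 is exactly 0 at C = X_exp,
bounded below by −1 (total depletion) and unbounded above. The +1 shift
stabilises the log at sparse counts; the −1 re-centres it.

Two implementation choices deserve note:

* **Observed frequency.** The ratio is implemented as the count ratio
  C/X_exp. An alternative reading that additionally divides the observed
  counts by the neighbour-type abundance is available
  (`enrichment_matrix(..., literal_fobs=True)`) but is not 0-centred under
  complete spatial randomness, which contradicts the statistic's defining
  property (0 = no enrichment); the count ratio is the default.
* **Symmetrisation.** The symmetric pair value is the arithmetic mean of
  the two directed centred values, equivalently log2 of the geometric mean
  of the two shifted ratios minus 1. Multiplying the shifted ratios and
  re-centring once would put the null at log2(2·2) − 1 = 1 instead of 0,
  so the geometric-mean rule is used.

Pairs with X_exp = 0 (query type absent or with zero encounters, neighbour
type absent) are missing, never 0, and propagate as missing through
symmetrisation and pooling. Pooling across samples weights each sample's
directed value by its query-type cell count, so large samples and abundant
query types dominate, matching how a pooled heat map should read. Pair
comparisons across samples use a paired two-sample t test on the per-sample
directed values; zero-variance difference vectors are reported degenerately
(t = 0, p = 1 if all differences are zero, otherwise t = ±∞, p = 0) rather
than erroring.

Null calibration: on 20 simulated samples of 2,000 cells with types
assigned independently of position, the grand mean of e over all pairs and
samples is ≈ −0.001 (|mean| < 0.05), computed from scratch by
`scripts/acceptance.py`.

## Radial transcript profiles

Annuli are half-open [k−1, k) µm, k = 1..K (default K = 50), with area
π(2k−1). A molecule inside the annuli of several cells counts once per
(cell, molecule) incidence, because the profile is an average over query
cells, not a partition of molecules. Densities are counts / (area ×
n_cells); aggregation across samples sums counts and cell numbers before
normalising, which weights sections by the number of query cells they
contribute. The reference profile samples cells uniformly without
replacement (default 10,000, seeded) regardless of type. Enrichment is
log2(d_target/d_ref + 1), so parity with the reference sits at 1 and an
absent gene at 0; the variant log2(ratio) + 1 (same parity baseline,
symmetric tails) is available via `log_then_shift=True`. Annuli with zero
reference density are masked.

## Niche model

Neighbourhood composition uses a 75 µm radius — three times the
co-localisation radius, wide enough to capture multicellular architecture
rather than direct contact. Rows are neighbour-count vectors divided by the
neighbour total; cells with zero neighbours are flagged, excluded from
fitting, and labelled "unassigned".

The mixture is a Gaussian mixture with equal-volume spherical covariance: a
single σ² shared by all K components (default K = 20). EM details: k-means
initialisation, best of n_init = 10 restarts by log-likelihood,
convergence when the relative log-likelihood improvement drops below
tol = 1e-6, σ² floored at 1e-12 to avoid collapse onto duplicated rows.
Hard assignments take the maximum posterior, ties to the lowest component
index. scikit-learn's spherical GMM (per-component variances) is close but
not identical; on well-separated equal-variance data both find the same
partition, which the test suite uses as an independent cross-check.

Merging components into named niches is user-supplied (`merge_niches`),
since published niche labels reflect curation; `propose_merges` suggests
groups by cosine similarity of component means (> 0.95, single linkage) as
a starting point only.

Niche enrichment per (niche m, type t) is log2(obs/exp + 1) − 1 with
exp = overall type proportion × niche size. Because Σ_m obs = Σ_m exp per
type, the size-weighted mean ratio over niches is exactly 1 — a
conservation identity the tests assert.

## Transcript origins

η is subtracted once per (cell, gene) for every cell of the niche,
including cells with zero counts of that gene, and the per-type sum is
clamped at 0 before normalising. Charging silent cells is deliberate: the
false detections are uniform over cells, so every segmented cell collects η
expected stray molecules per gene regardless of expression. The clamp
prevents negative mass for rare genes in abundant silent types. Unassigned
molecules never enter the sums. The default η = 0.09 is the assay's
empirical per-cell per-gene false-detection rate, and the synthetic
generator plants background noise at exactly that rate; with background
molecules folded into their nearest cell, the corrected decomposition
recovers planted emitting-type shares within 3% while the uncorrected one
is biased toward abundant silent types.

## Tubule morphometry

Classification operates on log2(x+1)-transformed mean intensities with
strict inequalities: objects with CD68 > 0.6 or FAP > 1.8 are excluded as
mis-segmentations; VCAM1+ requires VCAM1 > 2 and PanCK in (4.8, 7); ICAM1+
additionally requires ICAM1 > 0.6. The PanCK gate is attached to the VCAM1+
call only; VCAM1− tubules are not PanCK-gated. All thresholds are config
keys.

The buffer ring is the 25 µm dilation minus the original polygon (the open
ring outside the boundary); `include_interior=True` keeps the interior for
sensitivity analysis. Dilation approximates circular arcs with 16 segments
per quadrant (a 64-gon for a point), giving areas within 0.5% of the
closed form on the analytic circle/ring cases, which is the documented
discretisation tolerance. Marker polygons are unioned per class before
intersection so overlaps are not double-counted. Class comparisons use the
two-sided Wilcoxon rank-sum (Mann-Whitney U) on log2(pct+1) values — the
transform does not alter ranks, so the p-value equals the raw-scale test —
with the exact null for untied samples of ≤ 20 per group.

## Pooled-donor demultiplexing

Reconciliation rules, in order: doublet in either modality or unassigned in
both → removed; unassigned in exactly one → the other modality's donor;
both called but different → removed (conflict); both called and equal →
that donor. Tallies report removal/rescue as fractions of all barcodes and
the matching/conflicting split as fractions of barcodes surviving the first
rule, mirroring how such QC is usually quoted.

The genotype distance is the mean over shared, pairwise non-missing SNP
sites of |g_a − g_b| on the 0/1/2 dosage scale — a per-site Hamming-type
distance that weighs hom-ref vs hom-alt disagreements (2) more than
het disagreements (1). The 0/1 mismatch indicator is available
(`method="mismatch"`). Missing calls exclude the site for that pair only.
Donor-to-sample matching minimises total distance by the Hungarian
algorithm rather than per-row argmin, guaranteeing a one-to-one mapping,
with design-inconsistent pairs made infeasible (a donor predicted in
library L may only match samples pooled in L) and a per-match margin
(second-best minus best) as an ambiguity diagnostic.

## Synthetic data

The tissue generator emulates: uniform cell placement (background types),
annular tubule rings with a per-tubule epithelial state, disc niches with
exact planted mixing proportions, per-cell Poisson transcript clouds
scattered uniformly in a disc (default 4 µm) around the centroid, uniform
unassigned background molecules at rate 0.09 per cell per gene, and
regular 12-gon cell polygons. Background cells are placed outside niche
discs so the planted mixing proportions hold exactly inside them. It does
**not** emulate: realistic cell shapes, gene-gene covariance, segmentation
errors, cell-density gradients, or 3-D structure — so passing tests show
the statistics are computed correctly and recover planted effects, not that
real tissue meets the models' assumptions.

Default scene (used by the recovery tests): a 2,000 × 2,000 µm field —
niche discs of radius 150 µm separated by interstitium much wider than the
75 µm composition radius, as in real sections where fibrotic foci are
focal — three niches (fibrotic: 40% inflammatory PT / 30% myofibroblast /
30% monocyte; injury: 70% injured PT / 30% fibroblast; healthy epithelium:
80% healthy PT / 20% endothelium; 300 cells each) and 800 diffuse
background cells. This satisfies the planted-separation condition
(between-niche mean distance / within-niche s.d. > 3) by construction.

The pool generator draws per-SNP allele frequencies from Uniform(0.05,
0.95) and dosages Binomial(2, f); the default design pools 5 donors into 3
libraries of 3 donors with overlapping windows, 500 barcodes per library,
5% doublets, 2% unassignment and 2% mis-assignment per modality, and
predicted per-library genotypes carrying 2% call errors and 5%
missingness — realistic magnitudes for droplet doublet rates and
variant-based deconvolution noise. Doublets are represented at the call
level (the package reimplements reconciliation, not variant calling).

Determinism: one global seed spawns fixed per-component, per-sample
substreams (`default_rng([seed, stream, sample])`), so adding a generation
stage never perturbs earlier draws.

## Problem sizes in the test suite

Oracle-equivalence checks run 50 random instances of ≤ 200 cells / ≤ 1,000
molecules against O(N²) scans; null calibration uses 20 × 2,000 cells;
recovery suites use 20 seeds (niche ARI, pooled demultiplexing) and 50
seeds (co-localisation ordering) at ~400–1,700 cells per scene. These sizes
give Monte-Carlo bands comfortably tighter than the asserted tolerances
while keeping the full suite around ten seconds.

## Known limitations

* No edge correction: enrichment near tissue borders is estimated from
  truncated neighbourhoods (consistent with the statistic's definition, but
  a bias if query types concentrate at borders).
* The EII mixture fixes spherical, equal-variance components; elongated or
  unequal-spread niches will be over-split (mitigated by merging).
* K is user-chosen; no BIC model selection is provided.
* The origin decomposition assumes the noise rate is gene- and
  region-independent; a spatially structured background would bias it.
* Genotype matching assumes each physical sample appears at most once per
  library and that the pooling design is known exactly.
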