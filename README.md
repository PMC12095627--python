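# nichestat

Spatial statistics for in situ single-cell transcriptomics of diseased
tissue, built around the question: *which cell types and transcripts
co-localise, and where do tissue niches form?* The package grew out of
analyses of fibrotic kidney, where inflammatory proximal-tubule (PT)
epithelial cells, myofibroblasts and myeloid cells jointly occupy a
"fibrotic niche" — but every statistic here is generic to any imaging-based
single-cell dataset with cell centroids, transcript locations and
segmentation polygons (CosMx, Xenium, MERFISH and similar platforms).

It is aimed at computational biologists who have segmented cells with type
annotations and want quantitative, null-calibrated answers rather than
density-map pictures.

## What it computes

**Neighbourhood co-localisation enrichment.** For each ordered pair of cell
types (query q, neighbour n), count encounters C[q,n] within a fixed radius
R (default 25 µm, centroid to centroid). With T_q the total neighbours seen
by q-cells, N_n the abundance of type n and N the total cell count, the
expected count under random tissue architecture is X_exp = (N_n/N)·T_q and
the centred log2 enrichment is

    e[q,n] = log2( C[q,n] / X_exp[q,n] + 1 ) − 1

so e = 0 means "as expected", e = −1 total depletion. Matrices are
symmetrised by averaging the two directions, pooled across samples with
query-abundance weights, and compared pair-against-pair across samples with
a paired t test.

**Radial transcript enrichment.** Molecule density of a gene in 1 µm annuli
[k−1, k) around the centroids of a cell group, normalised by annulus area
π(2k−1) and cell number, expressed as log2(d_target/d_reference + 1)
against a reference of 10,000 random cells — distinguishing cell-intrinsic
transcripts (peak inside the ~5 µm cell boundary) from transcripts of
adjacent cell types (enriched just outside it).

**Niche detection.** Each cell's neighbourhood composition (fractions of
neighbour types within 75 µm) is clustered with a Gaussian mixture in the
EII parameterisation — spherical components sharing one variance σ² — via
EM from k-means starts; components are merged into named niches, and per
niche the cell-type enrichment log2(obs/exp + 1) − 1 is reported.

**Transcript origins.** Within a niche, each gene's counts are decomposed
into cell-type-of-origin proportions after subtracting a fixed per-cell
noise constant η = 0.09 (the uniform false-detection rate of the 6,000-plex
assay): S'_t = max(0, Σ c_i − η·n_t), p_t = S'_t / Σ S'_t.

**Tubule morphometry.** Threshold classification of tubule segmentation
objects from log2(x+1) mean intensities (VCAM1− / VCAM1+ICAM1− /
VCAM1+ICAM1+, with CD68/FAP exclusion gates), and the percentage of a 25 µm
buffer ring outside each tubule covered by FAP+ or CD68+ objects, compared
between classes by Wilcoxon rank-sum.

**Pooled-donor demultiplexing arithmetic.** Cross-modality (GEX/ATAC)
reconciliation of per-barcode donor calls, mean Hamming-type distance
between genotype dosage vectors (0/1/2 coding) over shared SNPs, and
design-constrained one-to-one matching of predicted donors to physical
samples.

A synthetic-tissue generator plants all of this structure — tubule rings,
niche discs with controlled mixing proportions, transcript clouds, uniform
background noise, pooled libraries with doublets and call errors — with
full ground truth, so every statistic is validated end to end.

## Worked example

Plant myofibroblasts and monocytes around an inflammatory tubule but not an
injured one, then ask the enrichment statistic whether it sees the effect:

```python
import nichestat as ns

cells, tx, polys, truth = ns.generate_tissue(ns.colocalisation_config(seed=0))
counts = ns.neighbour_counts(cells, radius=25.0)
sym = ns.symmetrize(ns.enrichment_matrix(counts))
print(sym.to_frame().round(2).loc[
    ["PT_inflammatory", "PT_injured"],
    ["Myofibroblast", "Monocyte", "Lymphocyte"],
])
```

prints

```
                 Myofibroblast  Monocyte  Lymphocyte
PT_inflammatory           1.26      1.15       -1.00
PT_injured               -1.00     -1.00       0.24
```

Inflammatory tubule cells are strongly enriched for adjacent
myofibroblasts and monocytes (e ≈ 1.2, i.e. far above the 0 null), while
injured tubule cells show total depletion (−1): the planted co-localisation
is recovered with the correct direction and the background lymphocytes sit
near the null.

The same analyses are available from the shell:

```
nichestat simulate tissue --seed 1 --out sim/
nichestat neighbourhood --cells sim/cells.csv --radius 25 --out enrich/
nichestat niche --cells sim/cells.csv --radius 75 --k 4 --seed 1 --out niches/
```

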