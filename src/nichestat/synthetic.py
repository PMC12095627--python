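"""Synthetic tissue and pooled-genotype data with planted ground truth.

The tissue generator emulates the geometry of an in situ single-cell
transcriptomics section of fibrotic kidney: epithelial cells arranged on
annular tubule cross-sections (each tubule in a healthy, injured or
inflammatory state), multicellular niches planted as discs with controlled
cell-type mixing proportions (e.g. inflammatory tubule cells co-placed with
myofibroblasts and monocytes), background cell types scattered outside the
niches, per-cell transcript clouds with Poisson molecule counts, and a
spatially uniform background of unassigned false transcript detections at a
configurable per-cell per-gene rate (default 0.09, the empirical noise
level of the 6,000-plex assay).

The pooled-genotype generator emulates donor-multiplexed multiome
libraries: donor dosage vectors drawn from population allele frequencies,
barcodes drawn from each library's donor pool with planted doublets, and
two independent per-modality donor calls with configurable unassignment and
mis-assignment rates.

Every generated object is accompanied by a :class:`GroundTruth` record, and
identical seed + config give bit-identical output. One global seed drives
per-component substreams so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import UNASSIGNED, regular_polygon

STATES = ("healthy", "injured", "inflammatory")


@dataclass
class TubuleSpec:
    """An annular tubule cross-section populated by epithelial cells."""

    center: tuple[float, float]
    radius: float = 40.0          # outer radius of the ring, µm
    thickness: float = 12.0       # ring thickness, µm
    state: str = "healthy"
    n_cells: int = 30
    cell_type: str | None = None  # defaults to "PT_<state>"

    def type_label(self) -> str:
        return self.cell_type or f"PT_{self.state}"


@dataclass
class NicheSpec:
    """A disc-shaped niche with target cell-type mixing proportions."""

    name: str
    center: tuple[float, float]
    radius: float = 150.0
    n_cells: int = 300
    mixing: dict[str, float] = dc_field(default_factory=dict)


@dataclass
class TissueConfig:
    field_size: tuple[float, float] = (1000.0, 1000.0)
    n_samples: int = 1
    background_cells: dict[str, int] = dc_field(default_factory=dict)
    tubules: list[TubuleSpec] = dc_field(default_factory=list)
    niches: list[NicheSpec] = dc_field(default_factory=list)
    #: mean molecule count per cell, keyed type_l2 -> {gene: mean}
    expression: dict[str, dict[str, float]] = dc_field(default_factory=dict)
    scatter_radius: float = 4.0        # molecule scatter disc around the centroid, µm
    background_noise_rate: float = 0.09  # stray molecules per cell per gene
    cell_polygon_radius: float = 5.0
    min_spacing: float = 2.0           # rough packing limit for feasibility
    seed: int = 0

    def total_cells(self) -> int:
        return (
            sum(self.background_cells.values())
            + sum(t.n_cells for t in self.tubules)
            + sum(n.n_cells for n in self.niches)
        )

    def validate(self) -> None:
        w, h = self.field_size
        if w <= 0 or h <= 0:
            raise ConfigurationError("field dimensions must be positive")
        if any(v < 0 for v in self.background_cells.values()):
            raise ConfigurationError("cell counts must be >= 0")
        if self.background_noise_rate < 0:
            raise ConfigurationError("background_noise_rate must be >= 0")
        for n in self.niches:
            if n.mixing:
                s = sum(n.mixing.values())
                if abs(s - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"niche {n.name!r} mixing proportions sum to {s}, not 1"
                    )
        if self.total_cells() * self.min_spacing**2 > w * h:
            raise ConfigurationError(
                "configured cells exceed field capacity at the minimum spacing"
            )


@dataclass
class GroundTruth:
    """Planted truth for generated cells, molecules and barcodes."""

    cells: pd.DataFrame | None = None      # cell_id, sample_id, true_niche, true_type, true_state
    molecules: pd.DataFrame | None = None  # row-aligned with the transcript table
    barcodes: pd.DataFrame | None = None   # barcode, library, true_donor, is_doublet


def _type_state(label: str) -> str:
    for s in STATES:
        if label.endswith(s):
            return s
    return "other"


def _sample_tissue(cfg: TissueConfig, sample_id: str, rng: np.random.Generator):
    w, h = cfg.field_size
    xs, ys, types, niche_lab, states = [], [], [], [], []

    def add(x, y, t, niche, state):
        xs.append(x); ys.append(y); types.append(t)
        niche_lab.append(niche); states.append(state)

    for tub in cfg.tubules:
        if tub.state not in STATES:
            raise ConfigurationError(f"unknown tubule state {tub.state!r}")
        r_out, r_in = tub.radius, max(tub.radius - tub.thickness, 0.0)
        # uniform over the annulus via inverse-CDF on r^2
        u = rng.uniform(r_in**2, r_out**2, size=tub.n_cells)
        theta = rng.uniform(0, 2 * math.pi, size=tub.n_cells)
        for r, th in zip(np.sqrt(u), theta):
            add(tub.center[0] + r * math.cos(th), tub.center[1] + r * math.sin(th),
                tub.type_label(), "none", tub.state)

    for nic in cfg.niches:
        labels = list(nic.mixing) or ["unspecified"]
        probs = np.array([nic.mixing[t] for t in labels]) if nic.mixing else np.ones(1)
        draws = rng.choice(len(labels), size=nic.n_cells, p=probs / probs.sum())
        u = rng.uniform(0, nic.radius**2, size=nic.n_cells)
        theta = rng.uniform(0, 2 * math.pi, size=nic.n_cells)
        for k, r, th in zip(draws, np.sqrt(u), theta):
            t = labels[k]
            add(nic.center[0] + r * math.cos(th), nic.center[1] + r * math.sin(th),
                t, nic.name, _type_state(t))

    # background cells land outside every planted niche disc so the planted
    # mixing proportions stay exact inside the discs
    centers = np.array([n.center for n in cfg.niches]) if cfg.niches else None
    radii = np.array([n.radius for n in cfg.niches]) if cfg.niches else None
    for t, count in cfg.background_cells.items():
        placed = 0
        while placed < count:
            x, y = rng.uniform(0, w), rng.uniform(0, h)
            if centers is not None:
                d2 = ((centers - [x, y]) ** 2).sum(axis=1)
                if (d2 < radii**2).any():
                    continue
            add(x, y, t, "none", _type_state(t))
            placed += 1

    cells = pd.DataFrame(
        {
            "cell_id": [f"{sample_id}_c{i}" for i in range(len(xs))],
            "sample_id": sample_id,
            "x": xs,
            "y": ys,
            "type_l1": [t.split("_")[0] for t in types],
            "type_l2": types,
            "state": states,
        }
    )
    truth_cells = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "sample_id": sample_id,
            "true_niche": niche_lab,
            "true_type": types,
            "true_state": states,
        }
    )
    return cells, truth_cells


def _sample_transcripts(cfg: TissueConfig, cells: pd.DataFrame,
                        rng: np.random.Generator):
    w, h = cfg.field_size
    rows, src = [], []
    sample_id = cells["sample_id"].iloc[0]
    genes = sorted({g for spec in cfg.expression.values() for g in spec})
    for cell in cells.itertuples():
        spec = cfg.expression.get(cell.type_l2, {})
        for gene, mean in spec.items():
            n = rng.poisson(mean)
            if n == 0:
                continue
            u = rng.uniform(0, cfg.scatter_radius**2, size=n)
            theta = rng.uniform(0, 2 * math.pi, size=n)
            for r, th in zip(np.sqrt(u), theta):
                rows.append((cell.x + r * math.cos(th), cell.y + r * math.sin(th),
                             gene, cell.cell_id, sample_id))
                src.append(("cell", cell.cell_id))
    n_cells = len(cells)
    for gene in genes:
        n = rng.poisson(cfg.background_noise_rate * n_cells)
        xy = rng.uniform(0, [w, h], size=(n, 2))
        for x, y in xy:
            rows.append((x, y, gene, UNASSIGNED, sample_id))
            src.append(("background", ""))
    tx = pd.DataFrame(rows, columns=["x", "y", "gene", "cell_id", "sample_id"])
    truth = pd.DataFrame(src, columns=["source", "source_cell_id"])
    truth["sample_id"] = sample_id
    return tx, truth


def generate_tissue(cfg: TissueConfig):
    """Generate (cells, transcripts, polygons, ground truth) for all samples.

    Deterministic for a given (seed, config); cell placement, transcript
    emission and polygon construction use independent substreams per sample.
    """
    cfg.validate()
    all_cells, all_tx, all_polys, truth_c, truth_m = [], [], [], [], []
    for s in range(cfg.n_samples):
        sid = f"sample_{s}"
        rng_cells = np.random.default_rng([cfg.seed, 0, s])
        rng_tx = np.random.default_rng([cfg.seed, 1, s])
        cells, tc = _sample_tissue(cfg, sid, rng_cells)
        tx, tm = _sample_transcripts(cfg, cells, rng_tx)
        polys = pd.DataFrame(
            {
                "object_id": cells["cell_id"],
                "sample_id": sid,
                "object_class": "cell",
                "polygon": [
                    regular_polygon(r.x, r.y, cfg.cell_polygon_radius)
                    for r in cells.itertuples()
                ],
            }
        )
        all_cells.append(cells); all_tx.append(tx); all_polys.append(polys)
        truth_c.append(tc); truth_m.append(tm)
    cells = pd.concat(all_cells, ignore_index=True)
    tx = pd.concat(all_tx, ignore_index=True)
    polys = pd.concat(all_polys, ignore_index=True)
    gt = GroundTruth(
        cells=pd.concat(truth_c, ignore_index=True),
        molecules=pd.concat(truth_m, ignore_index=True),
    )
    return cells, tx, polys, gt


def generate_csr_tissue(
    n_samples: int = 20,
    n_cells: int = 2000,
    field_size: tuple[float, float] = (1000.0, 1000.0),
    type_proportions: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Complete-spatial-randomness tissue: uniform positions, labels drawn
    independently of position. The null condition of the enrichment statistic."""
    if type_proportions is None:
        type_proportions = {f"type_{i}": p
                            for i, p in enumerate([0.30, 0.25, 0.15, 0.12, 0.10, 0.08])}
    labels = list(type_proportions)
    p = np.array([type_proportions[t] for t in labels], dtype=float)
    p = p / p.sum()
    frames = []
    for s in range(n_samples):
        rng = np.random.default_rng([seed, 2, s])
        xy = rng.uniform(0, field_size, size=(n_cells, 2))
        t = rng.choice(labels, size=n_cells, p=p)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"sample_{s}_c{i}" for i in range(n_cells)],
                    "sample_id": f"sample_{s}",
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                    "type_l2": t,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def default_tissue_config(seed: int = 0) -> TissueConfig:
    """Default fibrotic-kidney-like section: three well-separated niches
    (fibrotic, injury, healthy epithelium) plus diffuse background types."""
    return TissueConfig(
        field_size=(2000.0, 2000.0),
        n_samples=1,
        background_cells={"Lymphocyte": 400, "Vasa_recta": 400},
        niches=[
            NicheSpec(
                "fibrotic", (500.0, 500.0), 150.0, 300,
                {"PT_inflammatory": 0.4, "Myofibroblast": 0.3, "Monocyte": 0.3},
            ),
            NicheSpec(
                "injury", (1500.0, 500.0), 150.0, 300,
                {"PT_injured": 0.7, "Fibroblast": 0.3},
            ),
            NicheSpec(
                "healthy_epithelium", (1000.0, 1500.0), 150.0, 300,
                {"PT_healthy": 0.8, "Endothelium": 0.2},
            ),
        ],
        expression={
            "PT_inflammatory": {"CCL2": 6.0, "HAVCR1": 4.0},
            "PT_injured": {"HAVCR1": 4.0},
            "PT_healthy": {"LRP2": 5.0},
            "Myofibroblast": {"COL1A1": 8.0},
            "Monocyte": {"LYZ": 5.0},
        },
        seed=seed,
    )


def colocalisation_config(seed: int = 0) -> TissueConfig:
    """Tissue with a directed co-localisation effect planted: myofibroblasts
    and monocytes only around the inflammatory tubule, never the injured one."""
    return TissueConfig(
        field_size=(1000.0, 1000.0),
        n_samples=1,
        background_cells={"Lymphocyte": 150, "Endothelium": 150},
        tubules=[
            TubuleSpec((300.0, 300.0), radius=60.0, thickness=20.0,
                       state="inflammatory", n_cells=40),
            TubuleSpec((700.0, 700.0), radius=60.0, thickness=20.0,
                       state="injured", n_cells=40),
        ],
        niches=[
            NicheSpec("peritubular_fibrosis", (300.0, 300.0), 90.0, 60,
                      {"Myofibroblast": 0.6, "Monocyte": 0.4}),
        ],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# pooled genotypes


def default_pool_design(n_donors: int = 5, n_libraries: int = 3) -> dict[str, list[str]]:
    """Overlapping pooling pattern: consecutive donor windows per library so
    shared donors create the distinctive cross-library genotype signature."""
    donors = [f"donor_{i}" for i in range(n_donors)]
    per_lib = max(2, math.ceil(n_donors / n_libraries) + 1)
    design = {}
    for l in range(n_libraries):
        start = (l * (n_donors - per_lib)) // max(n_libraries - 1, 1)
        design[f"lib_{l}"] = donors[start:start + per_lib]
    # guarantee coverage of every donor
    covered = {d for v in design.values() for d in v}
    for d in donors:
        if d not in covered:
            design[f"lib_{n_libraries - 1}"].append(d)
    return design


@dataclass
class PoolConfig:
    n_donors: int = 5
    n_snps: int = 500
    pool_design: dict[str, list[str]] | None = None
    cells_per_library: int = 500
    doublet_rate: float = 0.05
    unassign_rate: float = 0.02
    misassign_rate: float = 0.02
    genotype_error_rate: float = 0.02   # per-site error in predicted genotypes
    genotype_missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps <= 0:
            raise ConfigurationError("n_snps must be positive")
        if self.n_donors <= 0:
            raise ConfigurationError("n_donors must be positive")
        for r in (self.doublet_rate, self.unassign_rate, self.misassign_rate,
                  self.genotype_error_rate, self.genotype_missing_rate):
            if not 0 <= r <= 1:
                raise ConfigurationError("rates must lie in [0, 1]")
        design = self.pool_design or default_pool_design(self.n_donors)
        donors = {f"donor_{i}" for i in range(self.n_donors)}
        for lib, members in design.items():
            if not members:
                raise ConfigurationError(f"pool design library {lib!r} has no donors")
        uncovered = donors - {d for v in design.values() for d in v}
        if uncovered:
            raise ConfigurationError(f"donors in no library: {sorted(uncovered)}")


def generate_pooled_genotypes(cfg: PoolConfig):
    """Generate (array genotypes, predicted genotypes, barcode calls, truth).

    * array genotypes — donors x sites truth dosages, Binomial(2, f) with
      per-SNP allele frequency f ~ Uniform(0.05, 0.95);
    * predicted genotypes — one row per (library, donor) pair, the truth
      with per-site call errors and missingness, as a donor-deconvolution
      model would emit per library;
    * barcode calls — per-barcode GEX and ATAC donor calls with planted
      doublets, unassignment and mis-assignment;
    * ground truth — true donor and doublet flag per barcode.
    """
    cfg.validate()
    design = cfg.pool_design or default_pool_design(cfg.n_donors)
    donors = [f"donor_{i}" for i in range(cfg.n_donors)]
    sites = [f"chr1:{1000 + 10 * j}:A:G" for j in range(cfg.n_snps)]

    rng_geno = np.random.default_rng([cfg.seed, 10])
    freqs = rng_geno.uniform(0.05, 0.95, size=cfg.n_snps)
    G = rng_geno.binomial(2, freqs, size=(cfg.n_donors, cfg.n_snps)).astype(float)
    array = pd.DataFrame(G, index=donors, columns=sites)

    rng_pred = np.random.default_rng([cfg.seed, 11])
    pred_rows, pred_index, pred_libs = [], [], {}
    for lib, members in design.items():
        for d in members:
            g = array.loc[d].to_numpy().copy()
            flip = rng_pred.random(cfg.n_snps) < cfg.genotype_error_rate
            g[flip] = (g[flip] + rng_pred.integers(1, 3, size=flip.sum())) % 3
            miss = rng_pred.random(cfg.n_snps) < cfg.genotype_missing_rate
            g[miss] = np.nan
            key = f"{lib}:{d}"
            pred_rows.append(g)
            pred_index.append(key)
            pred_libs[key] = lib
    predicted = pd.DataFrame(pred_rows, index=pred_index, columns=sites)
    predicted.attrs["libraries"] = pred_libs

    rng_bc = np.random.default_rng([cfg.seed, 12])
    records, truth_rows = [], []
    for lib, members in design.items():
        for b in range(cfg.cells_per_library):
            barcode = f"{lib}_bc{b}"
            is_doublet = bool(rng_bc.random() < cfg.doublet_rate) and len(members) > 1
            if is_doublet:
                d1, d2 = rng_bc.choice(members, size=2, replace=False)
            else:
                d1 = rng_bc.choice(members)
                d2 = ""
            calls = {}
            for modality in ("gex", "atac"):
                if is_doublet:
                    if rng_bc.random() < 1 - cfg.misassign_rate:
                        calls[modality] = "doublet"
                    else:
                        calls[modality] = str(rng_bc.choice([d1, d2]))
                elif rng_bc.random() < cfg.unassign_rate:
                    calls[modality] = "unassigned"
                elif rng_bc.random() < cfg.misassign_rate and len(members) > 1:
                    others = [d for d in members if d != d1]
                    calls[modality] = str(rng_bc.choice(others))
                else:
                    calls[modality] = str(d1)
            records.append((barcode, lib, calls["gex"], calls["atac"]))
            truth_rows.append((barcode, lib, str(d1), is_doublet, str(d2)))
    calls_df = pd.DataFrame(records,
                            columns=["barcode", "library", "gex_call", "atac_call"])
    truth = GroundTruth(
        barcodes=pd.DataFrame(
            truth_rows,
            columns=["barcode", "library", "true_donor", "is_doublet", "second_donor"],
        )
    )
    return array, predicted, calls_df, truth
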