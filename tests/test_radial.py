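import numpy as np
import pandas as pd
import pytest

import _oracles
from conftest import make_cells
from nichestat import (
    radial_density,
    radial_enrichment,
    reference_profile,
)
from nichestat.errors import ValidationError
from nichestat.radial import annulus_areas


def make_tx(rows, sample_id="s1"):
    """rows: list of (x, y, gene)."""
    df = pd.DataFrame(rows, columns=["x", "y", "gene"])
    df["cell_id"] = "unassigned"
    df["sample_id"] = sample_id
    return df


def test_single_cell_analytic_densities():
    cells = make_cells([("a", 0.0, 0.0, "PT")])
    tx = make_tx([(0.5, 0.0, "g"), (1.5, 0.0, "g")])
    prof = radial_density(cells, tx, ["g"], k_max=3)["g"]
    assert list(prof.counts) == [1, 1, 0]
    assert prof.density[0] == pytest.approx(1 / np.pi)
    assert prof.density[1] == pytest.approx(1 / (3 * np.pi))


def test_molecule_on_annulus_boundary_goes_outward():
    cells = make_cells([("a", 0.0, 0.0, "PT")])
    tx = make_tx([(1.0, 0.0, "g")])
    prof = radial_density(cells, tx, ["g"], k_max=3)["g"]
    assert list(prof.counts) == [0, 1, 0]


def test_coincident_cells_density_matches_single_cell():
    tx = make_tx([(0.5, 0.0, "g")])
    one = radial_density(make_cells([("a", 0, 0, "PT")]), tx, ["g"], k_max=2)["g"]
    two = radial_density(
        make_cells([("a", 0, 0, "PT"), ("b", 0, 0, "PT")]), tx, ["g"], k_max=2
    )["g"]
    assert two.counts[0] == 2 and two.n_cells == 2
    assert np.allclose(two.density, one.density)


def test_absent_gene_gives_zero_profile_not_error():
    cells = make_cells([("a", 0, 0, "PT")])
    tx = make_tx([(0.5, 0.0, "g")])
    prof = radial_density(cells, tx, ["missing"], k_max=5)["missing"]
    assert prof.counts.sum() == 0


def test_empty_cell_group_errors():
    with pytest.raises(ValidationError):
        radial_density(make_cells([]), make_tx([]), ["g"])


@pytest.mark.parametrize("seed", range(5))
def test_density_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n_cells, n_mols, k_max = 40, 300, 15
    cells = make_cells(
        [(f"c{i}", x, y, "PT") for i, (x, y) in
         enumerate(rng.uniform(0, 80, size=(n_cells, 2)))]
    )
    tx = make_tx([(x, y, "g") for x, y in rng.uniform(0, 80, size=(n_mols, 2))])
    prof = radial_density(cells, tx, ["g"], k_max=k_max)["g"]
    expected = _oracles.brute_radial_counts(
        cells[["x", "y"]].to_numpy(), tx[["x", "y"]].to_numpy(), k_max
    )
    assert (prof.counts == expected).all()


def test_reference_exhaustive_sample_equals_full_density():
    rng = np.random.default_rng(3)
    cells = make_cells(
        [(f"c{i}", x, y, "PT") for i, (x, y) in
         enumerate(rng.uniform(0, 50, size=(20, 2)))]
    )
    tx = make_tx([(x, y, "g") for x, y in rng.uniform(0, 50, size=(100, 2))])
    ref = reference_profile(cells, tx, ["g"], k_max=10, n_ref=10_000, seed=0)["g"]
    full = radial_density(cells, tx, ["g"], k_max=10)["g"]
    assert (ref.counts == full.counts).all()
    assert ref.n_cells == full.n_cells


def test_reference_deterministic_under_seed():
    rng = np.random.default_rng(4)
    cells = make_cells(
        [(f"c{i}", x, y, "PT") for i, (x, y) in
         enumerate(rng.uniform(0, 200, size=(60, 2)))]
    )
    tx = make_tx([(x, y, "g") for x, y in rng.uniform(0, 200, size=(200, 2))])
    p1 = reference_profile(cells, tx, ["g"], k_max=10, n_ref=20, seed=7)["g"]
    p2 = reference_profile(cells, tx, ["g"], k_max=10, n_ref=20, seed=7)["g"]
    assert (p1.counts == p2.counts).all()


def test_csr_reference_flat_in_k():
    """Uniform molecules on a large field give near-constant density over k."""
    rng = np.random.default_rng(5)
    field = 2000.0
    cells = make_cells(
        [(f"c{i}", x, y, "PT") for i, (x, y) in
         enumerate(rng.uniform(100, field - 100, size=(200, 2)))]
    )
    tx = make_tx([(x, y, "g") for x, y in rng.uniform(0, field, size=(40_000, 2))])
    prof = radial_density(cells, tx, ["g"], k_max=20)["g"]
    lam = 40_000 / field**2  # molecules per µm^2
    expected = lam * annulus_areas(20) * 200
    z = (prof.counts - expected) / np.sqrt(expected)
    assert np.abs(z).max() < 4.0  # Poisson fluctuation band


def test_enrichment_baselines():
    cells = make_cells([("a", 0, 0, "PT")])
    tx = make_tx([(0.5, 0.0, "g"), (1.5, 0.0, "g")])
    prof = radial_density(cells, tx, ["g"], k_max=3)["g"]
    E = radial_enrichment(prof, prof).E
    assert np.allclose(E[:2], 1.0)       # parity with reference -> 1
    assert np.isnan(E[2])                # reference density 0 -> masked
    # zero target density (cells far from every molecule) -> log2(1) = 0
    far = radial_density(make_cells([("z", 500.0, 500.0, "PT")]), tx, ["g"], k_max=3)["g"]
    E0 = radial_enrichment(far, prof).E
    assert np.allclose(E0[:2], 0.0)


def test_enrichment_threefold_is_two():
    cells = make_cells([("a", 0, 0, "PT")])
    target = radial_density(
        cells, make_tx([(0.5, 0, "g")] * 3), ["g"], k_max=1
    )["g"]
    ref = radial_density(cells, make_tx([(0.5, 0, "g")]), ["g"], k_max=1)["g"]
    assert radial_enrichment(target, ref).E[0] == pytest.approx(2.0)


def test_enrichment_gene_mismatch_errors():
    cells = make_cells([("a", 0, 0, "PT")])
    pa = radial_density(cells, make_tx([(0.5, 0, "a")]), ["a"], k_max=1)["a"]
    pb = radial_density(cells, make_tx([(0.5, 0, "b")]), ["b"], k_max=1)["b"]
    with pytest.raises(ValidationError):
        radial_enrichment(pa, pb)


def test_planted_cell_intrinsic_transcript_decays_with_radius():
    """A gene emitted only by inflammatory cells is enriched near their
    centroids (k <= scatter radius) and decays to baseline by k = 50, while
    around healthy cells it stays near baseline."""
    import nichestat as ns

    cfg = ns.TissueConfig(
        field_size=(1500.0, 1500.0),
        background_cells={"PT_healthy": 400, "PT_inflammatory": 400},
        expression={"PT_inflammatory": {"CCL2": 20.0}},
        scatter_radius=4.0,
        background_noise_rate=0.05,
        seed=42,
    )
    cells, tx, _, _ = ns.generate_tissue(cfg)
    ref = reference_profile(cells, tx, ["CCL2"], k_max=50, n_ref=10_000, seed=0)["CCL2"]
    target = radial_density(
        cells[cells["type_l2"] == "PT_inflammatory"], tx, ["CCL2"], k_max=50
    )["CCL2"]
    healthy = radial_density(
        cells[cells["type_l2"] == "PT_healthy"], tx, ["CCL2"], k_max=50
    )["CCL2"]
    E_t = radial_enrichment(target, ref).E
    E_h = radial_enrichment(healthy, ref).E
    assert np.nanargmax(E_t) <= 4          # peak within the scatter disc
    assert E_t[:4].mean() > E_t[40:].mean() + 0.5   # decays toward baseline by k=50
    # around healthy cells the gene shows no centroid peak: it is depleted
    # inside the boundary (the reference mixes in the emitting cells) and
    # returns to baseline far away
    assert np.nanmean(E_h[:4]) < np.nanmean(E_h[40:])
    assert E_t[:4].mean() > np.nanmean(E_h[:4]) + 1.0
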