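import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import _oracles
from conftest import make_cells
from nichestat import (
    fit_niche_model,
    merge_niches,
    neighbourhood_composition,
    niche_enrichment,
    propose_merges,
)
from nichestat.errors import ValidationError
from nichestat.niche import CompositionMatrix


def test_composition_simple_fractions():
    cells = make_cells(
        [("q", 0, 0, "Q"), ("x1", 1, 0, "X"), ("x2", 0, 1, "X"),
         ("y1", -1, 0, "Y"), ("y2", 0, -1, "Y")]
    )
    comp = neighbourhood_composition(cells, radius=5)
    row = comp.to_frame().loc["q", comp.types]
    assert row["X"] == pytest.approx(0.5)
    assert row["Y"] == pytest.approx(0.5)
    assert row["Q"] == 0.0


def test_isolated_cell_flagged_not_error():
    cells = make_cells([("a", 0, 0, "X"), ("b", 1000, 1000, "X")])
    comp = neighbourhood_composition(cells, radius=10)
    assert comp.flagged.all()


@pytest.mark.parametrize("seed", range(10))
def test_composition_matches_brute_force_oracle(random_cells, seed):
    cells = random_cells(150, seed=seed + 100)
    radius = 20.0 + 5 * seed
    comp = neighbourhood_composition(cells, radius=radius)
    expected, totals = _oracles.brute_composition(
        cells[["x", "y"]].to_numpy(), cells["type_l2"].to_numpy(), comp.types, radius
    )
    assert np.allclose(comp.comp, expected)
    assert (comp.n_neighbours == totals).all()


def test_composition_rows_sum_to_one(random_cells):
    cells = random_cells(400, seed=1, field=120.0)
    comp = neighbourhood_composition(cells, radius=30)
    sums = comp.comp[~comp.flagged].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_composition_neighbours_stay_within_sample(random_cells):
    a = random_cells(50, seed=2, field=50.0)
    b = random_cells(50, seed=3, field=50.0)
    b = b.assign(sample_id="s2", cell_id=b["cell_id"] + "_s2")
    both = pd.concat([a, b], ignore_index=True)
    comp_a = neighbourhood_composition(a, radius=20)
    comp_both = neighbourhood_composition(both, radius=20)
    assert np.allclose(comp_both.comp[:50], comp_a.comp)


def _comp_from_points(X):
    return CompositionMatrix(
        np.array([f"c{i}" for i in range(len(X))]),
        [f"d{j}" for j in range(X.shape[1])],
        X,
        np.full(len(X), 5),
    )


def test_two_point_masses_recovered_exactly():
    rng = np.random.default_rng(0)
    A = np.tile([0.9, 0.1, 0.0], (40, 1)) + rng.normal(0, 1e-3, (40, 3))
    B = np.tile([0.0, 0.2, 0.8], (40, 1)) + rng.normal(0, 1e-3, (40, 3))
    comp = _comp_from_points(np.vstack([A, B]))
    model = fit_niche_model(comp, K=2, seed=0, n_init=4)
    truth = np.repeat([0, 1], 40)
    assert adjusted_rand_score(truth, model.assignments) == 1.0


def test_single_component_closed_form():
    rng = np.random.default_rng(1)
    X = rng.dirichlet([2, 3, 4], size=200)
    comp = _comp_from_points(X)
    model = fit_niche_model(comp, K=1, seed=0, n_init=1)
    assert np.allclose(model.means[0], X.mean(axis=0), atol=1e-8)
    expected_s2 = ((X - X.mean(axis=0)) ** 2).sum() / (X.size)
    assert model.sigma2 == pytest.approx(expected_s2, rel=1e-6)
    assert model.weights[0] == pytest.approx(1.0)


def test_fit_deterministic_under_seed():
    rng = np.random.default_rng(2)
    X = rng.dirichlet([1, 1, 1], size=150)
    comp = _comp_from_points(X)
    m1 = fit_niche_model(comp, K=3, seed=9, n_init=3)
    m2 = fit_niche_model(comp, K=3, seed=9, n_init=3)
    assert np.array_equal(m1.assignments, m2.assignments)
    assert np.allclose(m1.means, m2.means)
    assert m1.sigma2 == m2.sigma2


def test_k_exceeding_rows_errors():
    comp = _comp_from_points(np.full((3, 2), 0.5))
    with pytest.raises(ValidationError):
        fit_niche_model(comp, K=10)


def test_shared_variance_agrees_with_spherical_gmm_on_separated_data():
    """On well-separated equal-variance blobs the shared-variance fit and
    scikit-learn's per-component spherical GMM find the same partition."""
    from sklearn.mixture import GaussianMixture

    rng = np.random.default_rng(3)
    centers = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
    X = np.vstack([c + rng.normal(0, 0.03, (60, 3)) for c in centers])
    comp = _comp_from_points(X)
    model = fit_niche_model(comp, K=3, seed=0, n_init=4)
    gmm = GaussianMixture(3, covariance_type="spherical", random_state=0,
                          n_init=4).fit(X)
    assert adjusted_rand_score(gmm.predict(X), model.assignments) == 1.0
    assert model.sigma2 == pytest.approx(gmm.covariances_.mean(), rel=0.1)


def test_merge_identity_and_collapse():
    rng = np.random.default_rng(4)
    X = rng.dirichlet([1, 1], size=60)
    comp = _comp_from_points(X)
    model = fit_niche_model(comp, K=3, seed=0, n_init=2)
    ident = merge_niches(model, {0: "0", 1: "1", 2: "2"})
    assert np.array_equal(
        ident.labels(), np.array([str(a) for a in model.assignments], dtype=object)
    )
    allone = merge_niches(model, {0: "all", 1: "all", 2: "all"})
    assert set(allone.labels()) == {"all"}
    assert allone.merged_weights["all"] == pytest.approx(1.0)


def test_merge_weight_additivity_and_unmapped_error():
    rng = np.random.default_rng(5)
    X = rng.dirichlet([1, 1], size=80)
    comp = _comp_from_points(X)
    model = fit_niche_model(comp, K=3, seed=1, n_init=2)
    merged = merge_niches(model, {0: "fibrotic", 1: "fibrotic", 2: "other"})
    assert merged.merged_weights["fibrotic"] == pytest.approx(
        model.weights[0] + model.weights[1]
    )
    with pytest.raises(ValidationError):
        merge_niches(model, {0: "a", 1: "b"})


def test_propose_merges_groups_identical_means():
    model_means = np.array([[1.0, 0.0], [1.0, 1e-9], [0.0, 1.0]])
    from nichestat.niche import NicheModel
    model = NicheModel(model_means, 0.1, np.array([0.4, 0.3, 0.3]),
                       np.zeros(3, dtype=int), np.array(["a", "b", "c"]), 0.0)
    groups = propose_merges(model, threshold=0.95)
    assert groups[0] == groups[1]
    assert groups[0] != groups[2]


def test_niche_enrichment_formula_values():
    # niche "m" holds 3 of type A and 1 of type B; overall proportions 0.5/0.5
    cells = make_cells(
        [("a1", 0, 0, "A"), ("a2", 0, 0, "A"), ("a3", 0, 0, "A"), ("b1", 0, 0, "B"),
         ("a4", 0, 0, "A"), ("b2", 0, 0, "B"), ("b3", 0, 0, "B"), ("b4", 0, 0, "B")]
    )
    labels = np.array(["m", "m", "m", "m", "n", "n", "n", "n"], dtype=object)
    enr = niche_enrichment(cells, labels)
    # obs(A in m) = 3, exp = 0.5 * 4 = 2 -> log2(2.5) - 1
    assert enr.loc["m", "A"] == pytest.approx(np.log2(2.5) - 1)
    # obs = 3*exp -> exactly 1
    labels2 = np.array(["m"] * 3 + ["n"] * 9, dtype=object)
    cells2 = make_cells(
        [(f"a{i}", 0, 0, "A") for i in range(3)]
        + [(f"b{i}", 0, 0, "B") for i in range(9)]
    )
    enr2 = niche_enrichment(cells2, labels2)
    # overall prop(A) = 0.25; niche m size 3 -> exp = 0.75; obs = 3 = 4*exp
    assert enr2.loc["m", "A"] == pytest.approx(np.log2(4 + 1) - 1)
    # obs = 0 -> -1
    assert enr2.loc["m", "B"] == pytest.approx(np.log2(0 / 2.25 + 1) - 1) == -1.0


def test_niche_enrichment_null_and_conservation(random_cells):
    cells = random_cells(300, seed=6)
    # composition identical to overall: random labels independent of type
    rng = np.random.default_rng(7)
    labels = rng.choice(["m", "n"], size=300)
    enr = niche_enrichment(cells, labels)
    tab = pd.crosstab(pd.Series(labels, name="niche"), cells["type_l2"])
    overall = tab.sum(axis=0) / tab.values.sum()
    exp = np.outer(tab.sum(axis=1), overall)
    # conservation: sum of obs equals sum of exp per type
    assert np.allclose(tab.values.sum(axis=0), exp.sum(axis=0))
    # and the size-weighted mean of obs/exp is 1 per type
    ratio = tab.values / exp
    w = exp / exp.sum(axis=0, keepdims=True)
    assert np.allclose((ratio * w).sum(axis=0), 1.0)
    assert enr.abs().to_numpy().max() < 0.5  # no strong spurious structure


def test_planted_niche_recovery_single_seed():
    import nichestat as ns

    cfg = ns.default_tissue_config(seed=123)
    cells, _, _, gt = ns.generate_tissue(cfg)
    comp = neighbourhood_composition(cells, radius=75)
    model = fit_niche_model(comp, K=4, seed=123, n_init=5)
    keep = ~comp.flagged
    ari = adjusted_rand_score(
        gt.cells["true_niche"].to_numpy()[keep], model.assignments[keep]
    )
    assert ari >= 0.9
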