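"""Tissue niche detection from neighbourhood composition vectors.

Each cell is described by the fractions of its neighbours (within a 75 µm
radius by default) belonging to each cell type. These composition vectors
are clustered with a Gaussian mixture in the EII parameterisation — equal
mixing-volume, spherical components sharing a single variance sigma^2 — fit
by EM from k-means starts. Hard niche assignments are the maximum-posterior
component; similar components can then be merged into named niches, and
cell-type enrichment per niche is summarised as the centred log2 ratio of
observed to expected cell counts, log2(obs/exp + 1) - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .errors import ValidationError

UNASSIGNED = "unassigned"


@dataclass
class CompositionMatrix:
    """Per-cell neighbour-type fractions; zero-neighbour cells are flagged."""

    cell_ids: np.ndarray
    types: list[str]
    comp: np.ndarray            # n_cells x n_types, rows sum to 1 where defined
    n_neighbours: np.ndarray

    @property
    def flagged(self) -> np.ndarray:
        """True for cells with no neighbours (excluded from model fitting)."""
        return self.n_neighbours == 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.comp, index=self.cell_ids, columns=self.types)
        df["n_neighbours"] = self.n_neighbours
        return df


@dataclass
class NicheModel:
    """Fitted EII mixture over composition space with per-cell assignments."""

    means: np.ndarray           # K x d component means
    sigma2: float               # single shared spherical variance
    weights: np.ndarray         # K mixing weights
    assignments: np.ndarray     # component index per cell; -1 for flagged cells
    cell_ids: np.ndarray
    log_likelihood: float
    loglik_trace: list[float] = field(default_factory=list)
    niche_labels: np.ndarray | None = None   # set by merge_niches

    @property
    def K(self) -> int:
        return len(self.weights)

    def labels(self) -> np.ndarray:
        """Niche names per cell: merged labels if set, else component indices."""
        if self.niche_labels is not None:
            return self.niche_labels
        return np.array(
            [UNASSIGNED if a < 0 else str(a) for a in self.assignments], dtype=object
        )


def neighbourhood_composition(
    cells: pd.DataFrame,
    radius: float = 75.0,
    type_col: str = "type_l2",
    types: list[str] | None = None,
) -> CompositionMatrix:
    """Fraction of each cell's neighbours of each type, within radius.

    Neighbours are counted within sample (self excluded, inclusive
    threshold) and each row divided by its neighbour count, so rows sum to 1
    for every cell with at least one neighbour; isolated cells are flagged.
    """
    if radius <= 0:
        raise ValidationError("radius must be positive")
    labels = cells[type_col].astype(str).to_numpy()
    if types is None:
        types = sorted(set(labels))
    index = {t: k for k, t in enumerate(types)}
    codes = np.array([index[t] for t in labels])
    counts = np.zeros((len(cells), len(types)), dtype=np.int64)
    xy_all = cells[["x", "y"]].to_numpy(float)
    groups = cells.reset_index(drop=True).groupby("sample_id", sort=False).indices
    for s, rows in groups.items():
        xy = xy_all[rows]
        tree = cKDTree(xy)
        pairs = tree.query_pairs(r=radius, output_type="ndarray")
        if len(pairs):
            gi, gj = rows[pairs[:, 0]], rows[pairs[:, 1]]
            np.add.at(counts, (gi, codes[gj]), 1)
            np.add.at(counts, (gj, codes[gi]), 1)
    n_nb = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = counts / n_nb[:, np.newaxis]
    comp[n_nb == 0] = 0.0
    return CompositionMatrix(
        cells["cell_id"].to_numpy(), list(types), comp, n_nb
    )


def _eii_em(
    X: np.ndarray, K: int, rng: np.random.Generator, tol: float, max_iter: int
) -> tuple[np.ndarray, float, np.ndarray, float, list[float]]:
    """One EM run for the shared-variance spherical mixture from a k-means start."""
    n, d = X.shape
    km = KMeans(n_clusters=K, n_init=1, random_state=int(rng.integers(2**31)))
    hard = km.fit_predict(X)
    means = km.cluster_centers_.copy()
    weights = np.bincount(hard, minlength=K) / n
    sigma2 = max(np.mean((X - means[hard]) ** 2), 1e-10)
    trace: list[float] = []
    ll_old = -np.inf
    for _ in range(max_iter):
        # E-step: spherical Gaussian log densities with shared sigma2
        sq = ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        log_prob = -0.5 * (d * np.log(2 * np.pi * sigma2) + sq / sigma2)
        log_joint = log_prob + np.log(np.maximum(weights, 1e-300))
        ll = float(logsumexp(log_joint, axis=1).sum())
        trace.append(ll)
        resp = np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))
        # M-step
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp.T @ X) / np.maximum(nk, 1e-300)[:, None]
        sq = ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        sigma2 = max(float((resp * sq).sum() / (n * d)), 1e-12)
        if ll - ll_old < tol * max(abs(ll), 1.0) and ll >= ll_old:
            break
        ll_old = ll
    return means, sigma2, weights, trace[-1], trace


def fit_niche_model(
    comp: CompositionMatrix,
    K: int = 20,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> NicheModel:
    """Fit the EII Gaussian mixture to non-flagged composition rows.

    Runs ``n_init`` EM restarts from k-means initialisations and keeps the
    best log-likelihood. Hard assignments are maximum posterior (ties to the
    lowest component index); flagged cells get assignment -1.
    """
    keep = ~comp.flagged
    X = comp.comp[keep]
    if len(X) < K:
        raise ValidationError(f"K={K} exceeds the {len(X)} usable cells")
    rng = np.random.default_rng(seed)
    best = None
    errors = []
    for _ in range(n_init):
        try:
            result = _eii_em(X, K, rng, tol, max_iter)
        except (FloatingPointError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            errors.append(exc)
            continue
        if best is None or result[3] > best[3]:
            best = result
    if best is None:  # pragma: no cover
        raise ValidationError(f"EM failed in all restarts: {errors}")
    means, sigma2, weights, ll, trace = best
    d = X.shape[1]
    sq = ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
    log_joint = -0.5 * (d * np.log(2 * np.pi * sigma2) + sq / sigma2) + np.log(weights)
    hard = np.argmax(log_joint, axis=1)  # argmax takes the lowest index on ties
    assignments = np.full(len(comp.comp), -1, dtype=int)
    assignments[keep] = hard
    return NicheModel(
        means, sigma2, weights, assignments, comp.cell_ids, ll, trace
    )


def merge_niches(model: NicheModel, merge_map: dict[int, str]) -> NicheModel:
    """Collapse mixture components into named niches.

    ``merge_map`` must cover every component; weights of merged components
    add and assignments are relabelled. Flagged cells stay "unassigned".
    """
    missing = set(range(model.K)) - set(merge_map)
    if missing:
        raise ValidationError(f"merge_map leaves components unmapped: {sorted(missing)}")
    labels = np.array(
        [UNASSIGNED if a < 0 else merge_map[a] for a in model.assignments],
        dtype=object,
    )
    merged_weights = pd.Series(model.weights).groupby(
        pd.Series([merge_map[k] for k in range(model.K)])
    ).sum()
    out = NicheModel(
        model.means, model.sigma2, model.weights, model.assignments,
        model.cell_ids, model.log_likelihood, model.loglik_trace,
    )
    out.niche_labels = labels
    out.merged_weights = merged_weights  # type: ignore[attr-defined]
    return out


def propose_merges(model: NicheModel, threshold: float = 0.95) -> dict[int, str]:
    """Suggest a merge map by cosine similarity of component means.

    Components whose means have cosine similarity above ``threshold`` join
    the same group (single linkage). This is a helper; published niche
    labels were curated by eye, so the default workflow is an explicit map.
    """
    norms = np.linalg.norm(model.means, axis=1)
    cos = (model.means @ model.means.T) / np.outer(
        np.maximum(norms, 1e-300), np.maximum(norms, 1e-300)
    )
    parent = list(range(model.K))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(model.K):
        for j in range(i + 1, model.K):
            if cos[i, j] > threshold:
                parent[find(i)] = find(j)
    return {k: f"niche_{find(k)}" for k in range(model.K)}


def niche_enrichment(
    cells: pd.DataFrame,
    labels: np.ndarray,
    type_col: str = "type_l2",
) -> pd.DataFrame:
    """Centred log2 enrichment of each cell type within each niche.

    For niche m and type t: obs = cells of t in m; exp = overall dataset
    proportion of t times the niche size; value = log2(obs/exp + 1) - 1.
    Cells labelled "unassigned" are excluded. NaN where exp = 0.
    """
    keep = np.asarray(labels) != UNASSIGNED
    sub = cells.loc[keep]
    lab = np.asarray(labels)[keep]
    tab = pd.crosstab(pd.Series(lab, name="niche"), sub[type_col])
    overall = tab.sum(axis=0) / tab.values.sum()
    exp = np.outer(tab.sum(axis=1), overall)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log2(tab.values / exp + 1.0) - 1.0
    vals[exp == 0] = np.nan
    return pd.DataFrame(vals, index=tab.index, columns=tab.columns)
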