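"""Cell-type co-localisation enrichment within a fixed search radius.

The statistic asks, for every ordered (query, neighbour) cell-type pair,
whether neighbour-type cells are found near query-type cells more or less
often than expected under random tissue architecture. For each sample:

* ``C[q, n]`` — number of ordered cell pairs (i, j), i != j, with type(i)=q,
  type(j)=n and centroid distance <= R (default 25 µm, inclusive, no edge
  correction).
* expected count ``X_exp[q, n] = (N_n / N_total) * T_q`` where ``T_q`` is the
  total number of neighbours encountered by q-type cells and ``N_n`` the
  abundance of type n in the sample.
* centred log2 enrichment ``e[q, n] = log2(C/X_exp + 1) - 1``, which is 0
  when observed equals expected, -1 at total depletion, and unbounded above.

Per-sample matrices are pooled by a query-type-abundance-weighted mean and
directed pairs are compared across samples with a paired t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .errors import ValidationError


@dataclass
class NeighbourCounts:
    """Per-sample neighbour encounter counts at a fixed radius."""

    sample_id: str
    types: list[str]
    C: np.ndarray          # query x neighbour encounter counts
    N: np.ndarray          # per-type cell counts
    radius: float

    @property
    def T(self) -> np.ndarray:
        """Total neighbours encountered per query type (row sums of C)."""
        return self.C.sum(axis=1)

    @property
    def N_total(self) -> int:
        return int(self.N.sum())


@dataclass
class EnrichmentMatrix:
    """Centred log2 enrichment values; NaN marks undefined pairs."""

    sample_id: str
    types: list[str]
    E: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.E, index=self.types, columns=self.types)

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.E)


def neighbour_counts(
    cells: pd.DataFrame,
    radius: float = 25.0,
    type_col: str = "type_l2",
    types: list[str] | None = None,
) -> NeighbourCounts:
    """Count neighbour encounters of every type around every type.

    ``cells`` must hold a single sample. The query cell itself is excluded;
    the distance threshold is inclusive. ``types`` fixes the label universe
    (defaults to the sorted labels present).
    """
    if len(cells) == 0:
        raise ValidationError("neighbour_counts requires a non-empty cell table")
    samples = cells["sample_id"].unique()
    if len(samples) > 1:
        raise ValidationError(f"expected one sample per call, got {list(samples)}")
    if radius <= 0:
        raise ValidationError("radius must be positive")
    labels = cells[type_col].astype(str).to_numpy()
    if types is None:
        types = sorted(set(labels))
    index = {t: k for k, t in enumerate(types)}
    codes = np.array([index[t] for t in labels])
    K = len(types)
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    C = np.zeros((K, K), dtype=np.int64)
    if len(pairs):
        a, b = codes[pairs[:, 0]], codes[pairs[:, 1]]
        np.add.at(C, (a, b), 1)
        np.add.at(C, (b, a), 1)
    N = np.bincount(codes, minlength=K)
    return NeighbourCounts(str(samples[0]), list(types), C, N, float(radius))


def enrichment_matrix(counts: NeighbourCounts, literal_fobs: bool = False) -> EnrichmentMatrix:
    """Centred log2 enrichment from neighbour counts.

    With ``literal_fobs`` the observed count is additionally divided by the
    neighbour-type abundance before forming the ratio; this variant is not
    0-centred under spatial randomness and exists for sensitivity analysis.
    """
    C = counts.C.astype(float)
    N = counts.N.astype(float)
    T = counts.T.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        X_exp = np.outer(T, N) / counts.N_total
        obs = C / N[np.newaxis, :] if literal_fobs else C
        exp = X_exp / N[np.newaxis, :] if literal_fobs else X_exp
        ratio = obs / exp
        E = np.log2(ratio + 1.0) - 1.0
    undefined = (X_exp <= 0) | (N[:, np.newaxis] == 0)
    E[undefined] = np.nan
    return EnrichmentMatrix(counts.sample_id, counts.types, E)


def symmetrize(enrich: EnrichmentMatrix) -> EnrichmentMatrix:
    """Symmetric pair enrichment: mean of the two directed centred values.

    Equivalent to the log2 geometric mean of the two shifted observed/expected
    ratios minus 1, so the null stays at 0. A pair is missing if either
    direction is missing.
    """
    E = (enrich.E + enrich.E.T) / 2.0
    return EnrichmentMatrix(enrich.sample_id, enrich.types, E)


def pooled_enrichment(
    per_sample: list[EnrichmentMatrix],
    weights: list[np.ndarray | dict],
) -> EnrichmentMatrix:
    """Pool per-sample matrices with query-type abundance weights.

    ``weights[s]`` gives the per-query-type cell counts of sample ``s``
    (array aligned with the type list, or a type->count mapping). Pairs
    defined in no sample stay masked.
    """
    if not per_sample:
        raise ValidationError("pooled_enrichment requires at least one sample")
    types = per_sample[0].types
    for m in per_sample[1:]:
        if m.types != types:
            raise ValidationError("all samples must share a common type set")
    num = np.zeros((len(types), len(types)))
    den = np.zeros_like(num)
    for m, w in zip(per_sample, weights):
        wq = np.asarray([w[t] for t in types], dtype=float) if isinstance(w, dict) \
            else np.asarray(w, dtype=float)
        ok = ~np.isnan(m.E)
        W = np.broadcast_to(wq[:, np.newaxis], m.E.shape)
        num[ok] += (W * np.nan_to_num(m.E))[ok]
        den[ok] += W[ok]
    with np.errstate(invalid="ignore"):
        E = num / den
    E[den == 0] = np.nan
    return EnrichmentMatrix("pooled", types, E)


def pair_enrichment_test(
    per_sample: list[EnrichmentMatrix],
    pair_a: tuple[str, str],
    pair_b: tuple[str, str],
) -> tuple[float, float, pd.DataFrame]:
    """Paired two-sample t test between two directed type pairs across samples.

    Returns (t, two-sided p, per-sample value table). With zero-variance
    differences the result is reported degenerately: t=0, p=1 when all
    differences are 0, otherwise t=±inf, p=0.
    """
    rows = []
    for m in per_sample:
        ia, ja = m.types.index(pair_a[0]), m.types.index(pair_a[1])
        ib, jb = m.types.index(pair_b[0]), m.types.index(pair_b[1])
        va, vb = m.E[ia, ja], m.E[ib, jb]
        if not (np.isnan(va) or np.isnan(vb)):
            rows.append((m.sample_id, va, vb))
    table = pd.DataFrame(rows, columns=["sample_id", "value_a", "value_b"])
    if len(table) < 2:
        raise ValidationError("pair_enrichment_test needs the pairs defined in >=2 samples")
    d = table["value_a"].to_numpy() - table["value_b"].to_numpy()
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0, table
        return float(np.sign(d.mean()) * np.inf), 0.0, table
    t, p = stats.ttest_rel(table["value_a"], table["value_b"])
    return float(t), float(p), table
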