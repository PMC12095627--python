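"""Pooled-donor demultiplexing arithmetic.

Nuclei from several donors are pooled per library and each barcode is
assigned a donor independently from the RNA (GEX) and chromatin (ATAC)
reads of the same nucleus. This module implements the deterministic
bookkeeping around those per-modality calls:

* cross-modality reconciliation — doublet in either modality or unassigned
  in both removes the barcode; a single unassigned modality defers to the
  other; conflicting donors remove the barcode;
* genotype distance — mean per-site distance between dosage vectors on the
  0/1/2 scale over the shared, non-missing SNP sites;
* donor-to-sample matching — one-to-one assignment of predicted
  donor-library pairs to physical samples minimising total genotype
  distance, restricted to pairings consistent with the pooling design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError

DOUBLET = "doublet"
UNASSIGNED = "unassigned"
REMOVED = "removed"


def reconcile_assignments(calls: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Resolve per-barcode GEX and ATAC donor calls into a single assignment.

    ``calls`` needs columns barcode, gex_call, atac_call where each call is
    a donor id, "doublet" or "unassigned". Returns the table with
    ``resolved`` and ``removal_reason`` columns plus category tallies
    (fractions of total for removal/rescue, and the matching/conflicting
    split as fractions of barcodes surviving the doublet/unassigned filter).
    """
    for col in ("barcode", "gex_call", "atac_call"):
        if col not in calls.columns:
            raise ValidationError(f"calls table is missing column {col!r}")
    out = calls.copy()
    gex = out["gex_call"].astype(str)
    atac = out["atac_call"].astype(str)

    doublet = (gex == DOUBLET) | (atac == DOUBLET)
    both_unassigned = (gex == UNASSIGNED) & (atac == UNASSIGNED)
    one_unassigned = ((gex == UNASSIGNED) ^ (atac == UNASSIGNED)) & ~doublet
    both_called = ~doublet & ~(gex == UNASSIGNED) & ~(atac == UNASSIGNED)
    conflict = both_called & (gex != atac)
    matching = both_called & (gex == atac)

    resolved = np.where(matching, gex,
                np.where(one_unassigned, np.where(gex == UNASSIGNED, atac, gex),
                         REMOVED))
    reason = np.select(
        [doublet, both_unassigned & ~doublet, conflict],
        ["doublet", "both_unassigned", "conflict"],
        default="none",
    )
    out["resolved"] = resolved
    out["removal_reason"] = reason
    n = len(out)
    n_survive_i = int((~(doublet | both_unassigned)).sum())
    tallies = {
        "n_total": n,
        "frac_removed_doublet_or_both_unassigned":
            float((doublet | both_unassigned).sum() / n) if n else 0.0,
        "frac_rescued_single_modality": float(one_unassigned.sum() / n) if n else 0.0,
        "frac_matching_of_remaining":
            float(matching.sum() / n_survive_i) if n_survive_i else 0.0,
        "frac_conflicting_of_remaining":
            float(conflict.sum() / n_survive_i) if n_survive_i else 0.0,
        "n_resolved": int((out["resolved"] != REMOVED).sum()),
        "n_removed": int((out["resolved"] == REMOVED).sum()),
    }
    return out, tallies


def genotype_distance(
    A: pd.DataFrame, B: pd.DataFrame, method: str = "dosage"
) -> pd.DataFrame:
    """Mean per-site genotype distance between every row of A and of B.

    Rows are donors (or donor-library pairs), columns SNP site identifiers,
    entries dosages in {0, 1, 2} with NaN for missing calls. Sites are
    intersected between A and B; a missing call at a site excludes that site
    for that pair only. ``method="dosage"`` uses |g_a - g_b| on the dosage
    scale; ``method="mismatch"`` the 0/1 disagreement indicator.
    """
    shared = A.columns.intersection(B.columns)
    if len(shared) == 0:
        raise ValidationError("no shared SNP sites between genotype matrices")
    a = A[shared].to_numpy(float)
    b = B[shared].to_numpy(float)
    ok = (~np.isnan(a))[:, None, :] & (~np.isnan(b))[None, :, :]
    diff = np.abs(a[:, None, :] - b[None, :, :])
    if method == "mismatch":
        diff = (diff > 0).astype(float)
    elif method != "dosage":
        raise ValidationError(f"unknown distance method {method!r}")
    diff = np.where(ok, np.nan_to_num(diff), 0.0)
    n_ok = ok.sum(axis=2)
    with np.errstate(invalid="ignore"):
        D = diff.sum(axis=2) / n_ok
    return pd.DataFrame(D, index=A.index, columns=B.index)


@dataclass
class DonorMatch:
    predicted: str
    sample: str
    distance: float
    margin: float      # second-best feasible distance minus the chosen one


def match_donors(
    D: pd.DataFrame,
    pool_design: dict[str, list[str]] | None = None,
    libraries: pd.Series | None = None,
) -> list[DonorMatch]:
    """One-to-one matching of predicted donors (rows) to samples (columns).

    Minimises the total genotype distance with the Hungarian algorithm,
    restricted to design-consistent pairs: a donor predicted in library L
    may only match samples pooled in L (``pool_design`` maps library ->
    samples; ``libraries`` gives each row's library). Each match reports the
    margin to the second-best feasible sample of that row; a zero margin
    flags ambiguity (e.g. identical genotype columns).
    """
    cost = D.to_numpy(float).copy()
    feasible = np.ones_like(cost, dtype=bool)
    if pool_design is not None:
        if libraries is None:
            raise ValidationError("pool_design given without per-row libraries")
        for i, row in enumerate(D.index):
            lib = libraries[row] if not isinstance(libraries, pd.Series) \
                else libraries.loc[row]
            if lib not in pool_design:
                raise ValidationError(f"library {lib!r} absent from pool design")
            allowed = set(pool_design[lib])
            feasible[i] = [s in allowed for s in D.columns]
            if not feasible[i].any():
                raise ValidationError(
                    f"no design-consistent sample for row {row!r} (library {lib!r})"
                )
    big = np.nanmax(cost[np.isfinite(cost)]) + 1.0 if np.isfinite(cost).any() else 1.0
    penal = cost.copy()
    penal[~feasible] = big * 1e6
    rows, cols = linear_sum_assignment(penal)
    matches = []
    for i, j in zip(rows, cols):
        if not feasible[i, j]:
            raise ValidationError(
                f"assignment infeasible for row {D.index[i]!r} under the pool design"
            )
        others = [cost[i, jj] for jj in range(cost.shape[1]) if jj != j and feasible[i, jj]]
        margin = float(min(others) - cost[i, j]) if others else float("inf")
        matches.append(DonorMatch(str(D.index[i]), str(D.columns[j]),
                                  float(cost[i, j]), margin))
    return matches


GT_CODES = {(0, 0): 0.0, (0, 1): 1.0, (1, 0): 1.0, (1, 1): 2.0}


def read_vcf_genotypes(path) -> pd.DataFrame:
    """Read a VCF into a samples x sites dosage matrix (NaN = missing).

    Sites are keyed chrom:pos:ref:alt; multi-allelic records are skipped
    with a warning. GT fields map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2,
    ./. -> NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites, columns = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic site {var.CHROM}:{var.POS}", stacklevel=2
            )
            continue
        key = f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        col = np.full(len(samples), np.nan)
        for i, gt in enumerate(var.genotypes):
            alleles = tuple(gt[:2])
            if -1 not in alleles:
                col[i] = GT_CODES.get(alleles, np.nan)
        sites.append(key)
        columns.append(col)
    data = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return pd.DataFrame(data, index=samples, columns=sites)
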