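"""Tubule classification by staining intensity and buffer-ring coverage.

Replicates a 5-plex immunofluorescence workflow on segmentation polygons:
tubules (PanCK+ objects) are classified from log2(x+1)-transformed mean
channel intensities into VCAM1-, VCAM1+ICAM1- and VCAM1+ICAM1+ classes
(objects with high CD68 or FAP are excluded as mis-segmentations), and the
percentage of a 25 µm buffer ring outside each tubule boundary covered by
FAP+ (myofibroblast) or CD68+ (macrophage) objects is quantified and
compared between classes with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.ops import unary_union

from .errors import ValidationError

#: Intensity thresholds on the log2(x+1) scale, as strict inequalities.
DEFAULT_THRESHOLDS = {
    "cd68_max": 0.6,     # excluded if mean CD68 above this
    "fap_max": 1.8,      # excluded if mean FAP above this
    "vcam1_min": 2.0,
    "panck_min": 4.8,    # PanCK gate attached to the VCAM1+ call
    "panck_max": 7.0,
    "icam1_min": 0.6,
}

REQUIRED_CHANNELS = ("PanCK", "VCAM1", "ICAM1", "CD68", "FAP")

CLASS_EXCLUDED = "excluded"
CLASS_VCAM1_NEG = "VCAM1-"
CLASS_VCAM1_POS = "VCAM1+ICAM1-"
CLASS_DOUBLE_POS = "VCAM1+ICAM1+"


def classify_tubules(
    intensities: pd.DataFrame,
    thresholds: dict | None = None,
    apply_log: bool = False,
) -> pd.DataFrame:
    """Assign each tubule a class from mean channel intensities.

    ``intensities`` is indexed by (or carries) object_id with one column per
    channel. Intensities are expected on the log2(x+1) scale already;
    ``apply_log`` applies the transform to raw values first.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    df = intensities.copy()
    if "object_id" in df.columns:
        df = df.set_index("object_id")
    for ch in REQUIRED_CHANNELS:
        if ch not in df.columns:
            raise ValidationError(f"missing required intensity channel {ch!r}")
    if apply_log:
        df[list(REQUIRED_CHANNELS)] = np.log2(df[list(REQUIRED_CHANNELS)] + 1.0)
    excluded = (df["CD68"] > th["cd68_max"]) | (df["FAP"] > th["fap_max"])
    vcam1_pos = (
        (df["VCAM1"] > th["vcam1_min"])
        & (df["PanCK"] > th["panck_min"])
        & (df["PanCK"] < th["panck_max"])
    )
    icam1_pos = df["ICAM1"] > th["icam1_min"]
    cls = np.where(
        excluded,
        CLASS_EXCLUDED,
        np.where(
            vcam1_pos,
            np.where(icam1_pos, CLASS_DOUBLE_POS, CLASS_VCAM1_POS),
            CLASS_VCAM1_NEG,
        ),
    )
    out = df.copy()
    out["tubule_class"] = cls
    return out.reset_index()


@dataclass
class BufferCoverage:
    object_id: str
    ring_area: float
    coverage_pct: dict[str, float]   # marker class -> % of ring covered
    degenerate: bool = False


def buffer_coverage(
    tubules: pd.DataFrame,
    markers: pd.DataFrame,
    buffer: float = 25.0,
    quad_segs: int = 16,
    include_interior: bool = False,
) -> list[BufferCoverage]:
    """Percentage of each tubule's buffer ring covered by marker objects.

    The ring is the tubule polygon dilated by ``buffer`` µm minus the
    polygon itself (``include_interior`` keeps the interior for sensitivity
    analysis). Marker polygons are unioned per object_class before
    intersecting so overlapping objects are not double-counted. Circular
    dilation uses ``quad_segs`` segments per quadrant (64-gon by default).
    """
    if buffer <= 0:
        raise ValidationError("buffer must be positive")
    unions = {
        cls: unary_union(list(sub["polygon"]))
        for cls, sub in markers.groupby("object_class")
    }
    out = []
    for row in tubules.itertuples():
        dilated = row.polygon.buffer(buffer, quad_segs=quad_segs)
        ring = dilated if include_interior else dilated.difference(row.polygon)
        if ring.area <= 0:
            out.append(BufferCoverage(row.object_id, 0.0, {c: np.nan for c in unions},
                                      degenerate=True))
            continue
        pct = {
            cls: 100.0 * ring.intersection(u).area / ring.area
            for cls, u in unions.items()
        }
        out.append(BufferCoverage(row.object_id, ring.area, pct))
    return out


def coverage_table(records: list[BufferCoverage]) -> pd.DataFrame:
    rows = [
        {"object_id": r.object_id, "ring_area": r.ring_area,
         "degenerate": r.degenerate, **r.coverage_pct}
        for r in records
    ]
    return pd.DataFrame(rows)


def compare_coverage(
    coverage: pd.DataFrame,
    classes: pd.Series | pd.DataFrame,
    class_a: str,
    class_b: str,
    channel: str,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of coverage between tubule classes.

    Coverage percentages are log2(x+1)-transformed before ranking (rank
    statistics are invariant to this monotone transform, so it only matters
    for any downstream plotting of the same values). Exact null
    distribution for small untied samples, normal approximation otherwise.
    Returns (U statistic for class_a, two-sided p).
    """
    if isinstance(classes, pd.DataFrame):
        classes = classes.set_index("object_id")["tubule_class"]
    cov = coverage.set_index("object_id") if "object_id" in coverage.columns else coverage
    merged = cov.join(classes.rename("tubule_class"), how="inner")
    a = merged.loc[merged["tubule_class"] == class_a, channel].dropna()
    b = merged.loc[merged["tubule_class"] == class_b, channel].dropna()
    if len(a) == 0 or len(b) == 0:
        raise ValidationError(f"empty tubule class among {class_a!r}, {class_b!r}")
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    small = len(a) <= 20 and len(b) <= 20
    ties = len(np.unique(np.concatenate([la, lb]))) < len(la) + len(lb)
    method = "exact" if small and not ties else "asymptotic"
    res = stats.mannwhitneyu(la, lb, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
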