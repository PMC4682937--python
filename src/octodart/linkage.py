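"""Two-point linkage statistics, LOD grouping and genetic-map summaries.

Markers here are dominant 0/1 columns over F1 progeny.  For two testcross
markers from the same parent the recombination fraction is estimated
directly from mismatching progeny (coupling) or matching progeny
(repulsion); grouping uses the G-statistic "independence LOD" on the 2x2
progeny table, which applies to any marker pair, followed by
single-linkage transitive closure above a LOD threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TwoPointResult",
    "two_point",
    "independence_lod",
    "pairwise_lod",
    "group_markers",
    "map_stats",
    "haldane",
    "haldane_inverse",
]

MIN_OVERLAP = 20  # jointly scored progeny below which pairwise stats are unstable


def haldane(rf: float) -> float:
    """Map distance in cM under Haldane (no interference): -50 ln(1-2r)."""
    if not (0.0 <= rf < 0.5):
        raise ValueError(f"recombination fraction must lie in [0, 0.5); got {rf}")
    return -50.0 * math.log1p(-2.0 * rf)


def haldane_inverse(cm: float) -> float:
    """Recombination fraction for a Haldane distance in cM."""
    if cm < 0:
        raise ValueError("map distance must be nonnegative")
    return 0.5 * (1.0 - math.exp(-cm / 50.0))


@dataclass
class TwoPointResult:
    marker_1: str
    marker_2: str
    rf: float
    phase: str  # coupling | repulsion
    lod: float
    n_informative: int
    computed: bool = True


def _xlog10(k: float, v: float) -> float:
    # convention 0 * log10(0) = 0
    return 0.0 if k == 0 else k * math.log10(v)


def two_point(
    m1: pd.Series, m2: pd.Series, min_overlap: int = MIN_OVERLAP
) -> TwoPointResult:
    """Recombination fraction, phase and LOD for two same-parent testcross
    columns.  With d mismatching of n jointly scored progeny, r = min(d, n-d)/n;
    coupling when mismatches are the minority."""
    x, y = np.asarray(m1, float), np.asarray(m2, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    name1 = str(getattr(m1, "name", "m1"))
    name2 = str(getattr(m2, "name", "m2"))
    if n < min_overlap:
        return TwoPointResult(name1, name2, math.nan, "unknown", math.nan, n, computed=False)
    d = int((x[ok] != y[ok]).sum())
    k = min(d, n - d)  # recombinants under the chosen phase
    phase = "coupling" if d <= n - d else "repulsion"
    rf = k / n
    lod = _xlog10(k, 2.0 * rf) + _xlog10(n - k, 2.0 * (1.0 - rf))
    return TwoPointResult(name1, name2, rf, phase, lod, n)


def independence_lod(
    m1: pd.Series, m2: pd.Series, min_overlap: int = MIN_OVERLAP
) -> float:
    """G-statistic LOD of independence on the 2x2 progeny table:
    LOD = G^2 / (2 ln 10), with 0 ln 0 = 0.  Degenerate margins give 0."""
    x, y = np.asarray(m1, float), np.asarray(m2, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < min_overlap:
        return math.nan
    x, y = x[ok], y[ok]
    table = np.array(
        [
            [(x == a).astype(float) @ (y == b).astype(float) for b in (0.0, 1.0)]
            for a in (0.0, 1.0)
        ]
    )
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return 0.0
    expected = np.outer(row, col) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    g2 = 2.0 * terms.sum()
    return max(0.0, g2) / (2.0 * math.log(10.0))


def pairwise_lod(
    scores: pd.DataFrame, min_overlap: int = MIN_OVERLAP
) -> pd.DataFrame:
    """Independence LOD for every marker pair of a progeny x marker frame.

    Vectorised over the four cell counts of the 2x2 table; pairs with fewer
    than ``min_overlap`` jointly scored progeny get NaN.
    """
    vals = scores.to_numpy(dtype=float)
    present = np.nan_to_num(vals, nan=0.0)
    absent = np.nan_to_num(1.0 - vals, nan=0.0)
    n11 = present.T @ present
    n10 = present.T @ absent
    n01 = absent.T @ present
    n00 = absent.T @ absent
    n = n11 + n10 + n01 + n00
    with np.errstate(divide="ignore", invalid="ignore"):
        g2 = np.zeros_like(n)
        for tab, r, c in (
            (n00, n00 + n01, n00 + n10),
            (n01, n00 + n01, n01 + n11),
            (n10, n10 + n11, n00 + n10),
            (n11, n10 + n11, n01 + n11),
        ):
            term = tab * np.log((tab * n) / (r * c))
            g2 += np.where(tab > 0, np.nan_to_num(term), 0.0)
    lod = np.maximum(0.0, 2.0 * g2) / (2.0 * math.log(10.0))
    lod[n < min_overlap] = np.nan
    markers = list(scores.columns)
    rows = []
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            rows.append((markers[i], markers[j], lod[i, j], int(n[i, j])))
    return pd.DataFrame(rows, columns=["marker_1", "marker_2", "lod", "n"])


def group_markers(
    pairs: pd.DataFrame, lod_threshold: float = 5.0, markers: list[str] | None = None
) -> pd.DataFrame:
    """Single-linkage transitive closure over pairs with LOD above threshold.

    Groups are numbered 1.. by decreasing size, ties by lexicographically
    smallest member; singletons are retained.  Returns marker -> group.
    """
    if markers is None:
        markers = sorted(set(pairs["marker_1"]) | set(pairs["marker_2"]))
    parent = {m: m for m in markers}

    def find(m: str) -> str:
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    linked = pairs[pairs["lod"] > lod_threshold]
    for a, b in zip(linked["marker_1"], linked["marker_2"]):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    clusters: dict[str, list[str]] = {}
    for m in markers:
        clusters.setdefault(find(m), []).append(m)
    ordered = sorted(clusters.values(), key=lambda ms: (-len(ms), min(ms)))
    rows = [(m, gi + 1) for gi, ms in enumerate(ordered) for m in sorted(ms)]
    return pd.DataFrame(rows, columns=["marker", "group"])


def map_stats(genetic_map: pd.DataFrame, gap_threshold: float = 8.0) -> dict:
    """Summaries of a (marker, lg, cm) map: per-LG span, spacing and gaps.

    Reports total length as the sum of per-LG spans, the count of adjacent
    gaps larger than ``gap_threshold`` cM, and two common per-marker density
    figures: length divided by marker count, and the mean adjacent interval.
    """
    per_lg = []
    gaps = []
    spacings = []
    for lg, sub in genetic_map.groupby("lg"):
        pos = np.sort(sub["cm"].to_numpy(dtype=float))
        length = float(pos[-1] - pos[0]) if len(pos) > 1 else 0.0
        diffs = np.diff(pos)
        spacings.extend(diffs.tolist())
        for left, width in zip(pos[:-1], diffs):
            if width > gap_threshold:
                gaps.append({"lg": lg, "start_cm": float(left), "size_cm": float(width)})
        per_lg.append({"lg": lg, "n_markers": int(len(pos)), "length_cm": length})
    per_lg_df = pd.DataFrame(per_lg)
    total_len = float(per_lg_df["length_cm"].sum()) if len(per_lg_df) else 0.0
    n_markers = int(len(genetic_map))
    return {
        "per_lg": per_lg_df,
        "n_linkage_groups": int(len(per_lg_df)),
        "n_markers": n_markers,
        "total_length_cm": total_len,
        "mean_spacing_cm": float(np.mean(spacings)) if spacings else math.nan,
        "length_per_marker_cm": total_len / n_markers if n_markers else math.nan,
        "gaps": pd.DataFrame(gaps, columns=["lg", "start_cm", "size_cm"]),
        "n_gaps_over_threshold": len(gaps),
        "largest_gap_cm": max((g["size_cm"] for g in gaps), default=0.0),
    }
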