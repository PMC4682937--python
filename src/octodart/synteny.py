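"""Genetic-map vs physical-map comparison for an octoploid against a
diploid reference.

Linkage groups are named with a Roman homoeology-group prefix (e.g. "II-3"
is the third homoeologue of chromosome 2); each homoeologue is expected to
anchor on the reference pseudochromosome of its prefix.  Marker-order
comparison uses the longest increasing (or decreasing) subsequence of
physical positions taken in genetic order as the colinear backbone;
markers off the backbone are rearrangement candidates, and monotone runs of
them in the reverse orientation are flagged as inverted blocks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "expected_chromosome",
    "chromosome_concordance",
    "scale_physical",
    "longest_increasing_subsequence",
    "detect_rearrangements",
]

_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6, "VII": 7}


def expected_chromosome(lg: str) -> int:
    """Reference pseudochromosome expected for a linkage-group name with a
    Roman homoeology prefix ("II-2" -> 2)."""
    m = re.match(r"^([IVX]+)\b", str(lg).strip())
    if not m or m.group(1) not in _ROMAN:
        raise ValueError(f"cannot parse homoeology-group prefix from LG name {lg!r}")
    return _ROMAN[m.group(1)]


def chromosome_concordance(anchors: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Flag each anchored marker as concordant/discordant with the
    chromosome expected from its LG prefix.

    ``anchors`` needs columns marker, lg, chrom; rows with a missing
    physical chromosome are excluded from the denominator and counted
    separately.  The summary percentage is rounded to 1 decimal.
    """
    df = anchors.copy()
    has_phys = df["chrom"].notna()
    df["expected_chrom"] = df["lg"].map(expected_chromosome)
    df["concordant"] = np.where(
        has_phys, df["chrom"].astype(float) == df["expected_chrom"], np.nan
    )
    anchored = df[has_phys]
    n_anchored = int(len(anchored))
    n_discordant = int((anchored["concordant"] == 0).sum())
    summary = {
        "n_anchored": n_anchored,
        "n_unanchored": int((~has_phys).sum()),
        "n_discordant": n_discordant,
        "percent_discordant": round(100.0 * n_discordant / n_anchored, 1)
        if n_anchored
        else float("nan"),
    }
    return df, summary


def scale_physical(anchors: pd.DataFrame, factor: float = 4.0) -> pd.Series:
    """Physical positions in Mbp scaled for co-plotting against cM:
    (bp / 1e6) * factor.  The published co-plots use factor 4."""
    return anchors["bp"].astype(float) / 1e6 * factor


def longest_increasing_subsequence(
    values: np.ndarray, strict: bool = True
) -> list[int]:
    """Indices of one longest increasing subsequence (O(n^2) DP).

    Deterministic: among equally long solutions it prefers the
    lexicographically smallest index sequence.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n == 0:
        return []
    best_len = np.ones(n, dtype=int)
    prev = np.full(n, -1, dtype=int)
    for i in range(n):
        for j in range(i):
            ok = x[j] < x[i] if strict else x[j] <= x[i]
            if ok and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = int(np.argmax(best_len))  # first maximum -> smallest tail index chain
    seq = []
    while end != -1:
        seq.append(end)
        end = prev[end]
    return seq[::-1]


@dataclass
class LGRearrangements:
    lg: str
    orientation: str  # "forward" | "reverse"
    backbone: list[str]
    candidates: list[str]
    inverted_blocks: list[list[str]]
    kendall_tau: float


def _monotone_runs(
    order: list[int], candidate: np.ndarray, pos: np.ndarray, sign: int, min_run: int = 3
) -> list[list[int]]:
    """Maximal runs of adjacent markers, containing >= min_run candidates,
    that are monotone with the given sign (opposite to the backbone)."""
    blocks = []
    n = len(order)
    i = 0
    while i < n:
        if not candidate[i]:
            i += 1
            continue
        # grow a monotone run around the candidate stretch
        j = i
        while j + 1 < n and candidate[j + 1] and sign * (pos[j + 1] - pos[j]) < 0:
            j += 1
        if sum(candidate[i : j + 1]) >= min_run and all(
            sign * (pos[k + 1] - pos[k]) < 0 for k in range(i, j)
        ):
            lo, hi = i, j
            while lo - 1 >= 0 and sign * (pos[lo] - pos[lo - 1]) < 0:
                lo -= 1
            while hi + 1 < n and sign * (pos[hi + 1] - pos[hi]) < 0:
                hi += 1
            blocks.append(list(range(lo, hi + 1)))
        i = j + 1
    return blocks


def detect_rearrangements(
    anchors: pd.DataFrame, min_markers: int = 5
) -> list[LGRearrangements]:
    """Per-LG colinearity analysis of physical order against genetic order.

    Markers are sorted by cM (ties broken by bp then marker id); the longer
    of the longest increasing and longest decreasing subsequences of bp is
    the colinear backbone (fixing the LG's orientation); off-backbone
    markers are rearrangement candidates, and adjacent runs containing at
    least three candidates that are monotone against the backbone
    orientation are reported as inverted blocks (extended over neighbouring
    backbone markers while the reversed order continues).  LGs with fewer
    than ``min_markers`` anchored markers are skipped.
    """
    out = []
    for lg, sub in anchors.dropna(subset=["chrom", "bp"]).groupby("lg", sort=True):
        sub = sub.sort_values(["cm", "bp", "marker"], kind="stable").reset_index(drop=True)
        if len(sub) < min_markers:
            continue
        pos = sub["bp"].to_numpy(dtype=float)
        inc = longest_increasing_subsequence(pos, strict=True)
        dec = longest_increasing_subsequence(-pos, strict=True)
        if len(inc) >= len(dec):
            orientation, backbone_idx, sign = "forward", inc, 1
        else:
            orientation, backbone_idx, sign = "reverse", dec, -1
        on_backbone = np.zeros(len(sub), dtype=bool)
        on_backbone[backbone_idx] = True
        candidate = ~on_backbone
        blocks_idx = _monotone_runs(
            list(range(len(sub))), candidate, pos, sign=sign
        )
        tau = stats.kendalltau(np.arange(len(sub)), pos).statistic
        markers = sub["marker"].tolist()
        out.append(
            LGRearrangements(
                lg=str(lg),
                orientation=orientation,
                backbone=[markers[i] for i in backbone_idx],
                candidates=[markers[i] for i in range(len(sub)) if candidate[i]],
                inverted_blocks=[[markers[i] for i in blk] for blk in blocks_idx],
                kendall_tau=float(tau),
            )
        )
    return out
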