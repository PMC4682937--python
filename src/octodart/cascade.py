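"""The DArTseq allele filtering and segregation-classification cascade.

SNPs from a presence/absence genotyping-by-sequencing platform are handled
as pairs of binary allele scorings (reference vs SNP allele) to avoid
conflating octoploid sub-genomes.  The cascade removes monomorphic and
missing-heavy alleles, classifies the rest against the disomic segregation
ratios of a pseudo-testcross F1 (simplex 1:1 or 3:1; multiplex 3:1 duplex,
7:1 triplex, ...), drops distorted alleles, keeps only deep-coverage
intercross alleles (row sum >= 600), and finally collapses near-identical
(>0.99 similarity) or complementary allele columns.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MarkerMatrix, RunConfig, SNPAlleleTable
from .simulate import F1Population

__all__ = [
    "SegClass",
    "ChiSquareResult",
    "CascadeReport",
    "expand_alleles",
    "filter_monomorphic",
    "filter_missing",
    "chi_square_gof",
    "classify_segregation",
    "filter_rowsum",
    "collapse_redundant",
    "run_cascade",
]


class SegClass(str, enum.Enum):
    MONOMORPHIC = "monomorphic"
    EXCLUDED_MISSING = "excluded_missing"
    SIMPLEX_TESTCROSS_P1 = "simplex_testcross_P1"
    SIMPLEX_TESTCROSS_P2 = "simplex_testcross_P2"
    SIMPLEX_INTERCROSS = "simplex_intercross"
    MULTIPLEX = "multiplex"
    DISTORTED = "distorted"
    EXCLUDED_ROWSUM = "excluded_rowsum"
    EXCLUDED_REDUNDANT = "excluded_redundant"


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    tested_ratio: tuple[int, int]


# Disomic presence:absence ratios for multiplex dosages, by parental pattern.
# One-parent patterns: duplex 3:1, triplex 7:1. Both-parent patterns combine
# doses across the two parents: 7:1, 13:3, 15:1.
MULTIPLEX_RATIOS_ONE_PARENT: tuple[tuple[int, int], ...] = ((3, 1), (7, 1))
MULTIPLEX_RATIOS_BOTH_PARENTS: tuple[tuple[int, int], ...] = ((7, 1), (13, 3), (15, 1))


@dataclass
class CascadeReport:
    """Stage-by-stage allele counts; derived stages and percentages follow
    the partition arithmetic of the filtering cascade."""

    total_alleles: int
    monomorphic: int
    excluded_missing: int
    multiplex: int
    distorted: int
    testcross_p1: int
    testcross_p2: int
    intercross_total: int
    intercross_excluded_rowsum: int
    redundant_removed: int = 0

    @property
    def remaining_after_missing(self) -> int:
        return self.total_alleles - self.monomorphic - self.excluded_missing

    @property
    def simplex_total(self) -> int:
        return self.remaining_after_missing - self.multiplex - self.distorted

    @property
    def testcross_total(self) -> int:
        return self.testcross_p1 + self.testcross_p2

    @property
    def intercross_kept(self) -> int:
        return self.intercross_total - self.intercross_excluded_rowsum

    @property
    def final_selected(self) -> int:
        return self.testcross_total + self.intercross_kept

    @property
    def mapping_set(self) -> int:
        return self.final_selected - self.redundant_removed

    @property
    def total_snps(self) -> int:
        return self.total_alleles // 2

    @staticmethod
    def percent(count: int, denominator: int) -> float:
        """Percentage rounded to 1 decimal, as printed in cascade reports."""
        return round(100.0 * count / denominator, 1)

    def check_partitions(self) -> None:
        if self.simplex_total != self.testcross_total + self.intercross_total:
            raise ValueError("simplex partition does not reconcile")
        if self.intercross_excluded_rowsum > self.intercross_total:
            raise ValueError("row-sum exclusions exceed intercross count")

    def to_frame(self) -> pd.DataFrame:
        t = self.total_alleles
        rows = [
            ("total_alleles", self.total_alleles, 100.0),
            ("monomorphic", self.monomorphic, self.percent(self.monomorphic, t)),
            ("excluded_missing", self.excluded_missing, self.percent(self.excluded_missing, t)),
            ("remaining", self.remaining_after_missing, self.percent(self.remaining_after_missing, t)),
            ("multiplex", self.multiplex, self.percent(self.multiplex, self.remaining_after_missing)),
            ("distorted", self.distorted, self.percent(self.distorted, self.remaining_after_missing)),
            ("simplex_total", self.simplex_total, self.percent(self.simplex_total, self.remaining_after_missing)),
            ("testcross_total", self.testcross_total, self.percent(self.testcross_total, self.simplex_total)),
            ("testcross_P1", self.testcross_p1, self.percent(self.testcross_p1, self.simplex_total)),
            ("testcross_P2", self.testcross_p2, self.percent(self.testcross_p2, self.simplex_total)),
            ("intercross_total", self.intercross_total, self.percent(self.intercross_total, self.simplex_total)),
            ("intercross_excluded_rowsum", self.intercross_excluded_rowsum, math.nan),
            ("intercross_kept", self.intercross_kept, math.nan),
            ("final_selected", self.final_selected, self.percent(self.final_selected, self.total_snps) if self.total_snps else math.nan),
            ("redundant_removed", self.redundant_removed, math.nan),
            ("mapping_set", self.mapping_set, math.nan),
        ]
        return pd.DataFrame(rows, columns=["stage", "count", "percent"])


def expand_alleles(snps: SNPAlleleTable) -> MarkerMatrix:
    """Expand a two-row-per-SNP table into an accessions x alleles matrix;
    allele ids are the SNP id with ``_ref`` / ``_snp`` suffixes."""
    if len(snps.rows) != 2 * len(snps.snp_ids):
        raise ValueError("allele-row count must be exactly 2 x SNP count")
    new_ids = []
    for sid in snps.snp_ids:
        new_ids.extend((f"{sid}_ref", f"{sid}_snp"))
    frame = snps.rows.copy()
    frame.index = pd.Index(new_ids)
    return MarkerMatrix(frame.T)


def _progeny_vals(pop: F1Population) -> np.ndarray:
    return pop.progeny.scores.to_numpy(dtype=float)


def filter_monomorphic(pop: F1Population) -> tuple[list[str], list[str]]:
    """Split marker ids into (kept, monomorphic).  Monomorphic = all
    non-missing progeny calls equal; all-missing columns are left to the
    missing filter."""
    vals = _progeny_vals(pop)
    markers = pop.progeny.marker_ids
    with np.errstate(invalid="ignore"):
        mn = np.nanmin(np.where(np.isnan(vals), np.inf, vals), axis=0)
        mx = np.nanmax(np.where(np.isnan(vals), -np.inf, vals), axis=0)
    any_call = ~np.isnan(vals).all(axis=0)
    mono = any_call & (mn == mx)
    kept = [m for m, is_mono in zip(markers, mono) if not is_mono]
    removed = [m for m, is_mono in zip(markers, mono) if is_mono]
    return kept, removed


def filter_missing(
    pop: F1Population,
    marker_ids: list[str] | None = None,
    max_missing_fraction: float = 0.10,
) -> tuple[list[str], list[str]]:
    """Exclude alleles with missing calls in more than ``max_missing_fraction``
    of progeny (strictly more than floor(f*n)), missing in either parent, or
    scored 0 in both parents."""
    markers = marker_ids if marker_ids is not None else pop.progeny.marker_ids
    sub = pop.progeny.scores.loc[:, markers]
    n = pop.n_progeny
    allowed = math.floor(max_missing_fraction * n)
    n_missing = sub.isna().sum(axis=0)
    p1 = pop.parents.loc["P1", markers]
    p2 = pop.parents.loc["P2", markers]
    bad = (
        (n_missing > allowed)
        | p1.isna()
        | p2.isna()
        | ((p1 == 0.0) & (p2 == 0.0))
    )
    kept = [m for m in markers if not bad[m]]
    removed = [m for m in markers if bad[m]]
    return kept, removed


def chi_square_gof(present: int, absent: int, ratio: tuple[int, int]) -> ChiSquareResult:
    """One-df goodness of fit of observed (present, absent) counts to an
    expected presence:absence ratio a:b."""
    a, b = ratio
    if a <= 0 or b <= 0:
        raise ValueError("ratio terms must be positive")
    n = present + absent
    if n == 0:
        raise ValueError("no scored progeny: present + absent = 0")
    exp_present = n * a / (a + b)
    exp_absent = n * b / (a + b)
    statistic = (present - exp_present) ** 2 / exp_present + (
        absent - exp_absent
    ) ** 2 / exp_absent
    p = float(stats.chi2.sf(statistic, df=1))
    return ChiSquareResult(statistic=float(statistic), df=1, p_value=p, tested_ratio=(a, b))


def _parent_pattern(pop: F1Population, marker: str) -> tuple[int, int]:
    p1 = pop.parents.at["P1", marker]
    p2 = pop.parents.at["P2", marker]
    if math.isnan(p1) or math.isnan(p2):
        raise RuntimeError(
            f"marker {marker!r} reached classification with a missing parent call"
        )
    return int(p1), int(p2)


def classify_segregation(
    pop: F1Population,
    marker_ids: list[str] | None = None,
    alpha_simplex: float = 0.001,
    alpha_multiplex: float = 0.01,
    multiplex_ratios_one_parent: tuple[tuple[int, int], ...] = MULTIPLEX_RATIOS_ONE_PARENT,
    multiplex_ratios_both_parents: tuple[tuple[int, int], ...] = MULTIPLEX_RATIOS_BOTH_PARENTS,
) -> pd.DataFrame:
    """Classify each allele as simplex (testcross/intercross), multiplex or
    distorted.

    The expected simplex ratio follows the parental pattern -- (1,0)/(0,1)
    segregate 1:1, (1,1) segregates 3:1.  An allele is simplex when the
    chi-square test does not reject that ratio at ``alpha_simplex``;
    otherwise it is multiplex when any pattern-consistent multiplex ratio is
    not rejected at ``alpha_multiplex``; otherwise distorted.

    Returns a frame: marker, seg_class, statistic, p_value, tested_ratio.
    """
    markers = marker_ids if marker_ids is not None else pop.progeny.marker_ids
    sub = pop.progeny.scores.loc[:, markers]
    present_counts = (sub == 1.0).sum(axis=0)
    absent_counts = (sub == 0.0).sum(axis=0)
    rows = []
    for m in markers:
        pat = _parent_pattern(pop, m)
        if pat == (0, 0):
            raise RuntimeError(
                f"marker {m!r} has parental pattern (0,0); the missing filter "
                "must run before classification"
            )
        present, absent = int(present_counts[m]), int(absent_counts[m])
        if pat == (1, 1):
            simplex_ratio = (3, 1)
            simplex_class = SegClass.SIMPLEX_INTERCROSS
            multiplex_set = multiplex_ratios_both_parents
        else:
            simplex_ratio = (1, 1)
            simplex_class = (
                SegClass.SIMPLEX_TESTCROSS_P1 if pat == (1, 0) else SegClass.SIMPLEX_TESTCROSS_P2
            )
            multiplex_set = multiplex_ratios_one_parent
        res = chi_square_gof(present, absent, simplex_ratio)
        if res.p_value >= alpha_simplex:
            rows.append((m, simplex_class.value, res.statistic, res.p_value, f"{simplex_ratio[0]}:{simplex_ratio[1]}"))
            continue
        best: ChiSquareResult | None = None
        for ratio in multiplex_set:
            cand = chi_square_gof(present, absent, ratio)
            if best is None or cand.p_value > best.p_value:
                best = cand
        if best is not None and best.p_value >= alpha_multiplex:
            rows.append((m, SegClass.MULTIPLEX.value, best.statistic, best.p_value, f"{best.tested_ratio[0]}:{best.tested_ratio[1]}"))
        else:
            rows.append((m, SegClass.DISTORTED.value, res.statistic, res.p_value, f"{simplex_ratio[0]}:{simplex_ratio[1]}"))
    return pd.DataFrame(
        rows, columns=["marker", "seg_class", "statistic", "p_value", "tested_ratio"]
    )


def filter_rowsum(
    pop: F1Population, intercross_ids: list[str], min_row_sum: float = 600
) -> tuple[list[str], list[str]]:
    """Keep intercross alleles with row sum (read depth) >= ``min_row_sum``."""
    missing = [m for m in intercross_ids if m not in pop.row_sum.index or pd.isna(pop.row_sum[m])]
    if missing:
        raise ValueError(f"no row_sum for allele(s): {missing[:5]}")
    kept = [m for m in intercross_ids if pop.row_sum[m] >= min_row_sum]
    removed = [m for m in intercross_ids if pop.row_sum[m] < min_row_sum]
    return kept, removed


def _snp_stem(marker: str) -> str:
    return marker.rsplit("_", 1)[0]


def collapse_redundant(
    pop: F1Population,
    marker_ids: list[str],
    similarity_threshold: float = 0.99,
    min_overlap: int = 20,
) -> tuple[list[str], list[str]]:
    """Collapse near-identical allele columns to one representative.

    Similarity is the fraction of jointly scored progeny with equal calls;
    pairs above the threshold collapse, as do exactly complementary columns
    of the two alleles of one SNP (the same locus scored from both sides).
    The representative is the allele with fewest missing calls, ties broken
    by lexicographically smaller id.  Pairs with fewer than ``min_overlap``
    jointly scored progeny are skipped as unreliable.
    """
    if not marker_ids:
        return [], []
    sub = pop.progeny.scores.loc[:, marker_ids]
    vals = sub.to_numpy(dtype=float)
    pres = np.nan_to_num(vals, nan=0.0)
    absn = np.nan_to_num(1.0 - vals, nan=0.0)
    called = (~np.isnan(vals)).astype(float)
    eq = pres.T @ pres + absn.T @ absn
    comp = pres.T @ absn + absn.T @ pres
    tot = called.T @ called
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = eq / tot
        comp_sim = comp / tot

    m = len(marker_ids)
    parent = list(range(m))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    stems = [_snp_stem(x) for x in marker_ids]
    for i in range(m):
        for j in range(i + 1, m):
            if tot[i, j] < min_overlap:
                continue
            same_snp_complement = stems[i] == stems[j] and comp_sim[i, j] == 1.0
            if sim[i, j] > similarity_threshold or same_snp_complement:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    n_missing = np.isnan(vals).sum(axis=0)
    clusters: dict[int, list[int]] = {}
    for i in range(m):
        clusters.setdefault(find(i), []).append(i)
    kept, removed = [], []
    for members in clusters.values():
        rep = min(members, key=lambda i: (n_missing[i], marker_ids[i]))
        kept.append(marker_ids[rep])
        removed.extend(marker_ids[i] for i in members if i != rep)
    order = {mk: k for k, mk in enumerate(marker_ids)}
    kept.sort(key=order.__getitem__)
    removed.sort(key=order.__getitem__)
    return kept, removed


def run_cascade(
    pop: F1Population, config: RunConfig | None = None
) -> tuple[CascadeReport, MarkerMatrix, pd.DataFrame]:
    """Run the full filtering cascade in protocol order.

    Stages: monomorphic -> missing -> segregation classification ->
    row-sum filter on intercross alleles -> redundancy collapse of the
    selected set.  Returns the stage report, the selected (post-redundancy)
    progeny matrix, and the per-allele classification table covering every
    input allele.
    """
    cfg = config or RunConfig()
    all_markers = pop.progeny.marker_ids

    kept, mono = filter_monomorphic(pop)
    kept, missing_excl = filter_missing(
        pop, kept, max_missing_fraction=cfg.max_missing_fraction
    )
    classified = classify_segregation(
        pop, kept, alpha_simplex=cfg.alpha_simplex, alpha_multiplex=cfg.alpha_multiplex
    )
    by_class: dict[str, list[str]] = {
        cls: classified.loc[classified["seg_class"] == cls, "marker"].tolist()
        for cls in classified["seg_class"].unique()
    }
    tc1 = by_class.get(SegClass.SIMPLEX_TESTCROSS_P1.value, [])
    tc2 = by_class.get(SegClass.SIMPLEX_TESTCROSS_P2.value, [])
    inter = by_class.get(SegClass.SIMPLEX_INTERCROSS.value, [])
    multiplex = by_class.get(SegClass.MULTIPLEX.value, [])
    distorted = by_class.get(SegClass.DISTORTED.value, [])

    inter_kept, inter_rowsum = filter_rowsum(pop, inter, min_row_sum=cfg.min_row_sum)
    selected = tc1 + tc2 + inter_kept
    final_kept, redundant = collapse_redundant(
        pop, selected, similarity_threshold=cfg.similarity_threshold
    )

    report = CascadeReport(
        total_alleles=len(all_markers),
        monomorphic=len(mono),
        excluded_missing=len(missing_excl),
        multiplex=len(multiplex),
        distorted=len(distorted),
        testcross_p1=len(tc1),
        testcross_p2=len(tc2),
        intercross_total=len(inter),
        intercross_excluded_rowsum=len(inter_rowsum),
        redundant_removed=len(redundant),
    )
    report.check_partitions()

    status = {}
    for m in mono:
        status[m] = SegClass.MONOMORPHIC.value
    for m in missing_excl:
        status[m] = SegClass.EXCLUDED_MISSING.value
    class_map = dict(zip(classified["marker"], classified["seg_class"]))
    for m in class_map:
        status[m] = class_map[m]
    for m in inter_rowsum:
        status[m] = SegClass.EXCLUDED_ROWSUM.value
    for m in redundant:
        status[m] = SegClass.EXCLUDED_REDUNDANT.value
    full = pd.DataFrame({"marker": all_markers})
    full["final_class"] = full["marker"].map(status)
    full["selected"] = full["marker"].isin(final_kept)
    full = full.merge(classified, on="marker", how="left")

    return report, pop.progeny.select_markers(final_kept), full
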