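"""Dominant-marker diversity and structure statistics.

Covers the polymorphism information content of dominant 0/1 markers, panel
quality metrics, the restriction-fragment distance of Nei & Li in
Felsenstein's formulation (solved for per-site divergence from the shared
band fraction), neighbor-joining with column-bootstrap supports, classical
principal coordinates analysis, and the Evanno second-order ΔK statistic
for choosing the number of subpopulations from replicate log-probability
curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io import MarkerMatrix, tree_bipartitions

__all__ = [
    "DistanceMatrix",
    "pic_dominant",
    "pic_summary",
    "quality_metrics",
    "nei_li_distance",
    "neighbor_joining",
    "bootstrap_support",
    "pcoa",
    "delta_k",
]


@dataclass
class DistanceMatrix:
    """Pairwise distances with the audit trail of the fragment model:
    shared-band fraction F and solved retention G per pair; ``saturated``
    flags pairs with no shared bands (F = 0)."""

    labels: list[str]
    values: np.ndarray
    shared_fraction: np.ndarray | None = None
    retention: np.ndarray | None = None
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if np.nanmax(np.abs(np.diag(d))) > 0:
            raise ValueError("distance matrix diagonal must be zero")
        self.values = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pic_dominant(band_frequency):
    """PIC of a dominant biallelic marker at band frequency f: 1 - f^2 - (1-f)^2
    = 2 f (1-f), maximal at 0.5 when f = 1/2."""
    f = np.asarray(band_frequency, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("band frequency must lie in [0, 1]")
    out = 2.0 * f * (1.0 - f)
    return float(out) if np.isscalar(band_frequency) else out


PIC_BINS = ((0.0, 0.10), (0.10, 0.30), (0.30, 0.40), (0.40, 0.50))


def pic_summary(matrix: MarkerMatrix) -> dict:
    """Per-marker PIC over non-missing calls, the panel mean and the
    fraction of markers per conventional PIC band.  Markers with all calls
    missing get NaN and do not enter the summary."""
    freq = matrix.scores.mean(axis=0, skipna=True)  # NaN when all missing
    pic = pd.Series(np.where(freq.isna(), np.nan, 2.0 * freq * (1.0 - freq)),
                    index=freq.index, name="pic")
    valid = pic.dropna()
    bins = {}
    for lo, hi in PIC_BINS:
        label = f"{lo:.2f}-{hi:.2f}"
        if hi == 0.50:
            frac = float(((valid >= lo) & (valid <= hi)).mean())
        else:
            frac = float(((valid >= lo) & (valid < hi)).mean())
        bins[label] = round(100.0 * frac, 1)
    return {
        "per_marker": pd.DataFrame({"band_frequency": freq, "pic": pic}),
        "mean_pic": float(valid.mean()),
        "bins_percent": bins,
    }


def quality_metrics(
    matrix: MarkerMatrix, replicate_pairs: list[tuple[str, str]] | None = None
) -> dict:
    """Per-marker call rate (non-missing fraction) and, when technical
    replicate pairs are provided, per-marker scoring reproducibility (the
    fraction of replicate comparisons with both sides scored that agree)."""
    call_rate = 1.0 - matrix.scores.isna().mean(axis=0)
    out = {
        "call_rate": call_rate,
        "mean_call_rate": float(call_rate.mean()),
        "reproducibility": None,
        "mean_reproducibility": None,
    }
    if not replicate_pairs:
        return out
    known = set(matrix.accession_ids)
    for a, b in replicate_pairs:
        if a not in known or b not in known:
            raise ValueError(f"replicate pair ({a!r}, {b!r}) references unknown accession")
    agree = np.zeros(matrix.n_markers)
    compared = np.zeros(matrix.n_markers)
    for a, b in replicate_pairs:
        x = matrix.scores.loc[a].to_numpy(dtype=float)
        y = matrix.scores.loc[b].to_numpy(dtype=float)
        both = ~(np.isnan(x) | np.isnan(y))
        compared += both
        agree += both & (x == y)
    with np.errstate(invalid="ignore"):
        repro = np.where(compared > 0, agree / compared, np.nan)
    repro = pd.Series(repro, index=matrix.marker_ids, name="reproducibility")
    out["reproducibility"] = repro
    out["mean_reproducibility"] = float(np.nansum(agree) / np.nansum(compared))
    return out


def solve_retention(f: float, tol: float = 1e-12, max_iter: int = 10_000) -> float:
    """Solve the fragment relation F = G^4 / (3 - 2G) for the per-site
    retention G by damped fixed-point iteration G <- [F (3 - 2G)]^(1/4)."""
    if not (0.0 < f <= 1.0):
        raise ValueError("shared fraction must lie in (0, 1] to solve for G")
    g = f ** 0.25
    for _ in range(max_iter):
        g_new = (f * (3.0 - 2.0 * g)) ** 0.25
        g_new = 0.5 * (g + g_new)  # damping keeps the iteration contractive
        if abs(g_new - g) < tol:
            return g_new
        g = g_new
    raise RuntimeError(f"retention iteration failed to converge for F={f}")


def nei_li_distance(
    matrix: MarkerMatrix, r: int = 6, saturation_cap: float = math.inf
) -> DistanceMatrix:
    """Fragment-mode Nei-Li distance between accessions.

    For each pair, over markers non-missing in both: F = 2 n_xy / (n_x + n_y)
    with n_x, n_y the band counts and n_xy the shared bands; the retention G
    solves F = G^4/(3 - 2G); D = -(2/r) ln G with r the recognition-site
    length of the rare cutter (default 6, PstI).  Pairs with no bands at all
    are NaN; pairs with F = 0 are flagged saturated and capped.
    """
    labels = matrix.accession_ids
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 accessions")
    vals = matrix.scores.to_numpy(dtype=float)
    D = np.zeros((n, n))
    F = np.full((n, n), np.nan)
    G = np.full((n, n), np.nan)
    sat = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(F, 1.0)
    np.fill_diagonal(G, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(np.isnan(vals[i]) | np.isnan(vals[j]))
            x, y = vals[i, both], vals[j, both]
            n_x, n_y = float(x.sum()), float(y.sum())
            n_xy = float((x * y).sum())
            if n_x + n_y == 0:
                D[i, j] = D[j, i] = np.nan
                continue
            f = 2.0 * n_xy / (n_x + n_y)
            F[i, j] = F[j, i] = f
            if f == 0.0:
                sat[i, j] = sat[j, i] = True
                D[i, j] = D[j, i] = saturation_cap
                continue
            g = solve_retention(f)
            G[i, j] = G[j, i] = g
            d = -(2.0 / r) * math.log(g)
            D[i, j] = D[j, i] = max(0.0, d)
    return DistanceMatrix(labels=labels, values=D, shared_fraction=F, retention=G, saturated=sat)


def _nj_tie_pair(q: np.ndarray, labels: list[str]) -> tuple[int, int]:
    """Index pair minimising Q, ties broken by the smallest sorted label pair."""
    qmin = q.min()
    best = None
    for i, j in zip(*np.where(np.isclose(q, qmin, rtol=0.0, atol=1e-12))):
        if i >= j:
            continue
        key = tuple(sorted((labels[i], labels[j])))
        if best is None or key < best[0]:
            best = (key, (int(i), int(j)))
    assert best is not None
    return best[1]


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with the Q criterion.

    Exactly additive matrices are recovered with their generating topology
    and branch lengths; negative length estimates are clamped to zero in the
    output (the raw estimate is kept in ``edge.head_node.raw_length``).
    Ties in Q are resolved toward the smallest joined label pair.
    """
    D = np.array(dm.values, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError(
            "distance matrix contains non-finite entries (saturated or "
            "undefined pairs); cap them or drop the accessions first"
        )
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 accessions for a phylogram")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nd.raw_length = None
        nodes.append(nd)
    # cluster label used only for deterministic tie-breaking
    tags = list(labels)

    def set_len(nd: dendropy.Node, v: float) -> None:
        nd.raw_length = float(v)
        nd.edge.length = max(0.0, float(v))

    while len(nodes) > 3:
        m = len(nodes)
        row = D.sum(axis=1)
        Q = (m - 2) * D - row[:, None] - row[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = _nj_tie_pair(Q, tags)
        li = 0.5 * D[i, j] + (row[i] - row[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        new = dendropy.Node()
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        set_len(nodes[i], li)
        set_len(nodes[j], lj)
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], d_new[keep][None, :]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        tags = [tags[k] for k in keep] + [min(tags[i], tags[j])]

    root = dendropy.Node()
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        lens = (
            0.5 * (d01 + d02 - d12),
            0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01),
        )
        for nd, v in zip(nodes, lens):
            root.add_child(nd)
            set_len(nd, v)
    else:  # 2 remaining clusters (possible when start n == 3 never loops)
        for nd, v in zip(nodes, (D[0, 1] / 2, D[0, 1] / 2)):
            root.add_child(nd)
            set_len(nd, v)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def root_at_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root a phylogram at the named accession (midpoint if absent)."""
    taxon = tree.taxon_namespace.get_taxon(outgroup)
    if taxon is None:
        tree.reroot_at_midpoint(update_bipartitions=False)
        return tree
    node = tree.find_node_with_taxon_label(outgroup)
    tree.reroot_at_edge(node.edge, update_bipartitions=False)
    return tree


def bootstrap_support(
    matrix: MarkerMatrix,
    b: int = 1000,
    seed: int = 0,
    r: int = 6,
    saturation_cap: float = math.inf,
) -> tuple[dendropy.Tree, int]:
    """NJ tree with bootstrap supports from resampling marker columns.

    Each of ``b`` replicates resamples markers with replacement, recomputes
    the fragment distance and NJ tree, and scores the original internal
    bipartitions; supports are percentages over the replicates that yielded
    a usable (finite-distance) tree.  Returns (tree, effective_b).
    """
    rng = np.random.default_rng(seed)
    dm = nei_li_distance(matrix, r=r, saturation_cap=saturation_cap)
    tree = neighbor_joining(dm)
    if b == 0:
        return tree, 0
    original = {}
    all_leaves = frozenset(matrix.accession_ids)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) >= 2 and len(all_leaves - side) >= 2:
            original[node] = frozenset({side, all_leaves - side})
    counts = {node: 0 for node in original}
    effective = 0
    m = matrix.n_markers
    for _ in range(b):
        cols = rng.integers(0, m, size=m)
        resampled = MarkerMatrix(matrix.scores.iloc[:, cols].set_axis(
            [f"bs_{k}" for k in range(m)], axis=1))
        try:
            rep_dm = nei_li_distance(resampled, r=r, saturation_cap=saturation_cap)
            rep_tree = neighbor_joining(rep_dm)
        except ValueError:
            continue  # degenerate replicate (saturated distances): drop
        effective += 1
        rep_bip = tree_bipartitions(rep_tree)
        for node, bip in original.items():
            if bip in rep_bip:
                counts[node] += 1
    for node, c in counts.items():
        node.label = str(round(100.0 * c / effective)) if effective else None
    return tree, effective


def pcoa(dm: DistanceMatrix) -> dict:
    """Classical principal coordinates analysis (Gower).

    Double-centers -D^2/2, eigendecomposes, and embeds on the positive
    eigenvalues; percent variance per axis is its eigenvalue over the sum of
    positive eigenvalues.  Negative eigenvalues are reported but excluded
    from both the embedding and the denominator.
    """
    D = np.asarray(dm.values, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("PCoA needs finite distances")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10 * max(1.0, abs(eigval[0]))
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    percent = 100.0 * eigval[pos] / eigval[pos].sum()
    axes = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return {
        "coordinates": pd.DataFrame(coords, index=dm.labels, columns=axes),
        "percent_variance": percent,
        "eigenvalues": eigval,
        "negative_eigenvalues": eigval[eigval < 0],
    }


def delta_k(runs: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Evanno ΔK from replicate log-probabilities.

    ``runs`` has columns k and loglik (one row per replicate run).  For each
    interior K of a contiguous range,
    ΔK = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)) with the
    sample standard deviation; returns the table and the argmax K.
    """
    if not {"k", "loglik"} <= set(runs.columns):
        raise ValueError("runs must have columns k and loglik")
    grouped = runs.groupby("k")["loglik"]
    ks = sorted(grouped.groups)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    counts = grouped.count()
    if (counts < 2).any():
        raise ValueError("need at least 2 replicates per K")
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    rows = []
    for k in ks[1:-1]:
        if sd[k] == 0:
            raise ZeroDivisionError(
                f"sd of L(K) is zero at K={k}; ΔK divisor degenerate"
            )
        dk = abs(mean[k + 1] - 2.0 * mean[k] + mean[k - 1]) / sd[k]
        rows.append((k, float(dk)))
    table = pd.DataFrame(rows, columns=["k", "delta_k"])
    best = int(table.loc[table["delta_k"].idxmax(), "k"])
    return table, best
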