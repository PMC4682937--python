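"""Synthetic octoploid crosses, diversity panels and model-selection curves.

The cross generator emulates a pseudo-testcross F1 family from two
heterozygous octoploid parents under strictly disomic inheritance: every
marker dose sits on one homologous chromosome pair of one sub-genome, so a
simplex (single-dose) marker segregates 1:1 when only one parent carries it
(testcross) and 3:1 when both do (intercross); a duplex parent (two
independent doses) transmits presence at 3/4 and a triplex parent at 7/8.
Simplex-class markers are placed on linkage groups and recombine under the
Haldane map function; genotyping error (symmetric 0<->1 flips), missing
calls and a lognormal per-allele read depth ("row sum") are layered on last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MarkerMatrix
from .linkage import haldane_inverse

__all__ = [
    "CrossSimConfig",
    "PanelSimConfig",
    "F1Population",
    "simulate_octoploid_cross",
    "simulate_diversity_panel",
    "simulate_loglik_curves",
]

# Dosage-class labels used in truth tables and by the classifier tests.
SIMPLEX_P1 = "simplex_testcross_P1"
SIMPLEX_P2 = "simplex_testcross_P2"
INTERCROSS = "simplex_intercross"
DUPLEX = "duplex"
TRIPLEX = "triplex"


@dataclass
class CrossSimConfig:
    """Study-scale defaults: 94 progeny; marker-class counts ~1/10 of the
    observed post-filter composition; 7 linkage groups of 75 cM (the study's
    mean LG length); 10% missing calls, 1% flip errors; lognormal depth with
    median ~400 reads."""

    n_progeny: int = 94
    n_simplex_p1: int = 184
    n_simplex_p2: int = 153
    n_intercross: int = 340
    n_duplex: int = 200
    n_triplex: int = 100
    n_linkage_groups: int = 7
    map_length_cm: float = 75.0
    missing_rate: float = 0.10
    error_rate: float = 0.01
    depth_log_mean: float = 6.0
    depth_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for key in ("missing_rate", "error_rate"):
            v = getattr(self, key)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{key} must lie in [0, 1); got {v}")
        if self.map_length_cm <= 0:
            raise ValueError("map_length_cm must be positive")
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")
        if self.total_markers == 0:
            raise ValueError("dosage-class marker counts sum to 0")

    @property
    def total_markers(self) -> int:
        return (
            self.n_simplex_p1
            + self.n_simplex_p2
            + self.n_intercross
            + self.n_duplex
            + self.n_triplex
        )


@dataclass
class PanelSimConfig:
    """Diversity-panel generator defaults mirror the 62-cultivar / 603-marker
    study panel with its strongest structural level (K=2)."""

    n_accessions: int = 62
    n_markers: int = 603
    k: int = 2
    divergence: float = 0.15  # Balding-Nichols F_ST-like drift per subpopulation
    admixture: float = 0.10
    freq_low: float = 0.05
    freq_high: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > self.n_accessions:
            raise ValueError("k subpopulations exceed the number of accessions")
        if not (0.0 < self.divergence < 1.0):
            raise ValueError("divergence must lie in (0, 1)")
        if not (0.0 <= self.admixture <= 1.0):
            raise ValueError("admixture must lie in [0, 1]")
        if not (0.0 <= self.freq_low <= self.freq_high <= 1.0):
            raise ValueError("ancestral band-frequency bounds out of order")


@dataclass
class F1Population:
    """An F1 family: parental scorings, progeny matrix, per-allele depth and
    the generating truth (class, phase, linkage group, cM)."""

    parents: pd.DataFrame  # rows P1, P2 x markers
    progeny: MarkerMatrix
    row_sum: pd.Series
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.parents.index) != ["P1", "P2"]:
            raise ValueError("parents must have rows P1 and P2")
        if list(self.parents.columns) != self.progeny.marker_ids:
            raise ValueError("parent and progeny marker ids differ")
        if (self.row_sum.reindex(self.progeny.marker_ids) < 0).any():
            raise ValueError("row_sum must be nonnegative")
        if self.truth is not None and set(self.truth["marker"]) != set(
            self.progeny.marker_ids
        ):
            raise ValueError("truth table must cover every marker")

    @property
    def n_progeny(self) -> int:
        return self.progeny.n_accessions


def _meiosis_paths(
    rng: np.random.Generator, n_progeny: int, positions: np.ndarray
) -> np.ndarray:
    """Inheritance indicator (which homolog, 0/1) along one chromosome pair
    at the given sorted cM positions, for each progeny; adjacent positions
    recombine with the Haldane fraction of their distance."""
    m = len(positions)
    h = np.empty((n_progeny, m), dtype=np.int8)
    h[:, 0] = rng.integers(0, 2, size=n_progeny)
    for j in range(1, m):
        r = haldane_inverse(positions[j] - positions[j - 1])
        flip = rng.random(n_progeny) < r
        h[:, j] = np.where(flip, 1 - h[:, j - 1], h[:, j - 1])
    return h


def simulate_octoploid_cross(config: CrossSimConfig) -> F1Population:
    """Simulate an octoploid F1 mapping family under disomic inheritance."""
    rng = np.random.default_rng(config.seed)
    n = config.n_progeny

    records = []  # (marker, class, phase_label, lg, cm)
    # --- simplex-class markers: placed on linkage groups -------------------
    simplex_specs = (
        [(SIMPLEX_P1, i) for i in range(config.n_simplex_p1)]
        + [(SIMPLEX_P2, i) for i in range(config.n_simplex_p2)]
        + [(INTERCROSS, i) for i in range(config.n_intercross)]
    )
    n_simplex = len(simplex_specs)
    lgs = rng.integers(1, config.n_linkage_groups + 1, size=n_simplex)
    cms = rng.uniform(0.0, config.map_length_cm, size=n_simplex)
    phases_p1 = rng.integers(0, 2, size=n_simplex)
    phases_p2 = rng.integers(0, 2, size=n_simplex)

    marker_ids = []
    columns = {}
    class_counter: dict[str, int] = {}

    def next_id(cls: str) -> str:
        class_counter[cls] = class_counter.get(cls, 0) + 1
        return f"{cls}_{class_counter[cls]:04d}"

    simplex_ids = [next_id(cls) for cls, _ in simplex_specs]

    # one meiosis path set per parent per linkage group, shared by all
    # markers on that group so linkage is real
    inherit = {}
    for parent in ("P1", "P2"):
        for lg in range(1, config.n_linkage_groups + 1):
            sel = np.where(lgs == lg)[0]
            if len(sel) == 0:
                continue
            order = sel[np.argsort(cms[sel], kind="stable")]
            paths = _meiosis_paths(rng, n, cms[order])
            for col, idx in enumerate(order):
                inherit[(parent, idx)] = paths[:, col]

    for pos, (cls, _) in enumerate(simplex_specs):
        mid = simplex_ids[pos]
        from_p1 = inherit[("P1", pos)] == phases_p1[pos]
        from_p2 = inherit[("P2", pos)] == phases_p2[pos]
        if cls == SIMPLEX_P1:
            present = from_p1
        elif cls == SIMPLEX_P2:
            present = from_p2
        else:  # heterozygous in both parents -> 3:1
            present = from_p1 | from_p2
        columns[mid] = present.astype(float)
        marker_ids.append(mid)
        records.append((mid, cls, int(phases_p1[pos]), int(lgs[pos]), float(cms[pos])))

    # --- multiplex markers: independent unlinked doses ---------------------
    parent_rows = {
        mid: pair
        for mid, pair in zip(
            marker_ids,
            [
                (1, 0) if cls == SIMPLEX_P1 else (0, 1) if cls == SIMPLEX_P2 else (1, 1)
                for cls, _ in simplex_specs
            ],
        )
    }
    for cls, count, doses in ((DUPLEX, config.n_duplex, 2), (TRIPLEX, config.n_triplex, 3)):
        for _ in range(count):
            mid = next_id(cls)
            carrier = "P1" if rng.random() < 0.5 else "P2"
            present = np.zeros(n, dtype=bool)
            for _d in range(doses):
                present |= rng.integers(0, 2, size=n).astype(bool)
            columns[mid] = present.astype(float)
            marker_ids.append(mid)
            parent_rows[mid] = (1, 0) if carrier == "P1" else (0, 1)
            records.append((mid, cls, -1, -1, float("nan")))

    progeny = pd.DataFrame(
        columns, index=[f"F1_{i + 1:03d}" for i in range(n)], columns=marker_ids
    )

    # --- noise: symmetric flips then missing calls (progeny only) ----------
    vals = progeny.to_numpy()
    if config.error_rate > 0:
        flips = rng.random(vals.shape) < config.error_rate
        vals = np.where(flips, 1.0 - vals, vals)
    if config.missing_rate > 0:
        vals = np.where(rng.random(vals.shape) < config.missing_rate, np.nan, vals)
    progeny = pd.DataFrame(vals, index=progeny.index, columns=progeny.columns)

    parents = pd.DataFrame(
        [[float(parent_rows[m][0]) for m in marker_ids],
         [float(parent_rows[m][1]) for m in marker_ids]],
        index=["P1", "P2"],
        columns=marker_ids,
    )
    row_sum = pd.Series(
        np.round(rng.lognormal(config.depth_log_mean, config.depth_log_sd, len(marker_ids))),
        index=marker_ids,
        name="row_sum",
    )
    truth = pd.DataFrame(
        records, columns=["marker", "dosage_class", "phase", "lg", "cm"]
    )
    return F1Population(
        parents=parents, progeny=MarkerMatrix(progeny), row_sum=row_sum, truth=truth
    )


def simulate_diversity_panel(
    config: PanelSimConfig,
) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Structured dominant-marker panel with known memberships.

    Band frequencies follow a hierarchical Balding-Nichols-style model: an
    ancestral frequency per marker, subpopulation frequencies drifted around
    it by ``divergence``, and per-accession presence drawn from the mixture
    implied by its membership vector.  Returns the 0/1 matrix and a truth
    table of membership vectors (columns pop_1..pop_K).
    """
    rng = np.random.default_rng(config.seed)
    k, n, m = config.k, config.n_accessions, config.n_markers

    p_anc = rng.uniform(config.freq_low, config.freq_high, size=m)
    f = config.divergence
    a = p_anc * (1 - f) / f
    b = (1 - p_anc) * (1 - f) / f
    subpop_freq = np.vstack([rng.beta(a, b) for _ in range(k)])  # k x m

    base = np.tile(np.arange(k), n // k + 1)[:n]
    memberships = np.zeros((n, k))
    memberships[np.arange(n), base] = 1.0
    if config.admixture > 0 and k > 1:
        mix = rng.dirichlet(np.ones(k), size=n)
        memberships = (1 - config.admixture) * memberships + config.admixture * mix

    freqs = memberships @ subpop_freq  # n x m
    scores = (rng.random((n, m)) < freqs).astype(float)

    acc_ids = [f"acc_{i + 1:03d}" for i in range(n)]
    marker_ids = [f"dart_{j + 1:04d}" for j in range(m)]
    matrix = MarkerMatrix(pd.DataFrame(scores, index=acc_ids, columns=marker_ids))
    truth = pd.DataFrame(
        memberships, index=acc_ids, columns=[f"pop_{i + 1}" for i in range(k)]
    )
    truth.insert(0, "main_pop", truth.to_numpy().argmax(axis=1) + 1)
    return matrix, truth


def simulate_loglik_curves(
    true_k: int,
    k_range: range,
    replicates: int = 20,
    noise_sd: float = 10.0,
    seed: int = 0,
    steep_slope: float = 100.0,
    plateau_slope: float = 5.0,
    base: float = -5000.0,
) -> pd.DataFrame:
    """Replicate log-probability curves L(K) with a knee at ``true_k``.

    The mean is piecewise linear -- rising by ``steep_slope`` per K up to the
    true number of subpopulations, then by ``plateau_slope`` -- with Gaussian
    replicate noise, the canonical shape the Evanno second-order statistic
    is designed to detect.  Columns: k, run, loglik.
    """
    ks = list(k_range)
    if true_k not in ks[1:-1]:
        raise ValueError("true_k must lie strictly inside k_range")
    if replicates < 2:
        raise ValueError("need >= 2 replicates per K for a defined sd")
    rng = np.random.default_rng(seed)
    rows = []
    for k in ks:
        mean = base + steep_slope * min(k, true_k) + plateau_slope * max(0, k - true_k)
        for rep in range(replicates):
            rows.append((k, rep + 1, mean + rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows, columns=["k", "run", "loglik"])
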