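import numpy as np
import pandas as pd
import pytest

from octodart import (
    CrossSimConfig,
    F1Population,
    MarkerMatrix,
    simulate_octoploid_cross,
)


@pytest.fixture(scope="session")
def clean_cross() -> "F1Population":
    """A noise-free simulated octoploid F1 family (n=94) used by the
    classification-recovery and linkage tests."""
    cfg = CrossSimConfig(
        n_progeny=94,
        n_simplex_p1=300,
        n_simplex_p2=300,
        n_intercross=300,
        n_duplex=300,
        n_triplex=300,
        missing_rate=0.0,
        error_rate=0.0,
        seed=11,
    )
    return simulate_octoploid_cross(cfg)


def make_population(
    parents: dict[str, tuple[float, float]],
    progeny: dict[str, list[float]],
    row_sum: dict[str, float] | None = None,
) -> F1Population:
    """Hand-build a tiny F1 population for unit tests."""
    markers = list(progeny)
    n = len(next(iter(progeny.values())))
    prog = pd.DataFrame(
        {m: progeny[m] for m in markers},
        index=[f"F1_{i + 1:03d}" for i in range(n)],
        dtype=float,
    )
    par = pd.DataFrame(
        [[float(parents[m][0]) for m in markers], [float(parents[m][1]) for m in markers]],
        index=["P1", "P2"],
        columns=markers,
    )
    rs = pd.Series(
        {m: (row_sum or {}).get(m, 1000.0) for m in markers}, name="row_sum"
    )
    return F1Population(parents=par, progeny=MarkerMatrix(prog), row_sum=rs)


def presence_column(n_present: int, n_absent: int, n_missing: int = 0) -> list[float]:
    return [1.0] * n_present + [0.0] * n_absent + [np.nan] * n_missing
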