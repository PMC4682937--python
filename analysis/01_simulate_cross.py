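#!/usr/bin/env python
"""Simulate the octoploid F1 mapping family.

Generates a 94-progeny pseudo-testcross family under disomic inheritance
with simplex, intercross, duplex and triplex dosage classes, ~10% missing
calls, 1% scoring errors and lognormal per-allele read depth, and writes
the parental/progeny scorings, depths and generating truth to results/.
"""

from pathlib import Path

from octodart import CrossSimConfig, simulate_octoploid_cross, write_marker_matrix

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240915


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = CrossSimConfig(seed=SEED)
    pop = simulate_octoploid_cross(cfg)

    write_marker_matrix(pop.progeny, OUT / "cross_progeny.tsv")
    pop.parents.to_csv(OUT / "cross_parents.tsv", sep="\t")
    pop.row_sum.to_csv(OUT / "cross_row_sums.tsv", sep="\t")
    pop.truth.to_csv(OUT / "cross_truth.tsv", sep="\t", index=False)

    comp = pop.truth["dosage_class"].value_counts()
    print(f"simulated {pop.progeny.n_markers} allele scorings x {pop.n_progeny} progeny")
    print("dosage-class composition:")
    print(comp.to_string())
    print(f"wrote progeny/parents/depths/truth to {OUT}")


if __name__ == "__main__":
    main()
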