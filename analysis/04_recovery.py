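#!/usr/bin/env python
"""Planted-variant recovery of the heteroplasmy caller on simulated reads.

Sweeps heteroplasmy frequency x coverage over a toy circular genome with the
default filter cascade (Q30 gates, >=20x, >=2 alt reads on both strands,
read-end and neighborhood filters) and reports sensitivity, false positives
and allele-fraction accuracy per cell. Writes results/recovery.tsv.
"""

from pathlib import Path

from mitoasym.simulate import recovery_experiment

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 7


def main() -> None:
    OUT.mkdir(exist_ok=True)
    df = recovery_experiment(
        frequencies=[0.01, 0.05, 0.10, 0.30],
        coverages=[30, 100],
        replicates=5,
        seed=SEED,
    )
    df.to_csv(OUT / "recovery.tsv", sep="\t", index=False)
    cell = df.groupby(["frequency", "coverage"]).agg(
        sensitivity=("sensitivity", "mean"),
        false_positives=("false_positives", "sum"),
        af_error=("mean_af_error", "mean"),
    )
    print(cell.to_string(float_format=lambda x: f"{x:.3f}"))
    print("\nNote: at frequency x coverage below ~2 expected supporting reads the "
          "two-read minimum is unreachable and sensitivity collapses to zero.")


if __name__ == "__main__":
    main()
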