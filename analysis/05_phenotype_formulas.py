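#!/usr/bin/env python
"""Worked examples of the closed-form phenotype readouts.

Applies the three Methods formulas to representative inputs: percentage
growth inhibition by a gas atmosphere (negative = stimulation), the
siderophore halo statistic from a chelating-dye plate, and the
phosphorylated fraction of a response regulator from band intensities.
Writes results/phenotype/phenotype_examples.tsv.
"""

from tfactivity.io import write_table
from tfactivity.phenotype import GrowthPair, arcap_fraction, halo_statistic, percent_inhibition

from _paths import RESULTS


def main() -> None:
    out = RESULTS / "phenotype"
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "quantity": "percent_inhibition(x=0.5, y=1.0)",
            "value": percent_inhibition(GrowthPair(0.5, 1.0)),
            "units": "%",
        },
        {
            # growth 33% above the matched no-CO control: stimulation
            "quantity": "percent_inhibition(x=1.33, y=1.0)",
            "value": percent_inhibition(GrowthPair(1.33, 1.0)),
            "units": "%",
        },
        {
            "quantity": "halo_statistic(halo=14, colony=10)",
            "value": halo_statistic(14.0, 10.0),
            "units": "mm",
        },
        {
            "quantity": "arcap_fraction(P=5, U=5)",
            "value": arcap_fraction(5.0, 5.0),
            "units": "%",
        },
        {
            "quantity": "arcap_fraction(P=3, U=1)",
            "value": arcap_fraction(3.0, 1.0),
            "units": "%",
        },
    ]
    write_table(rows, out / "phenotype_examples.tsv")
    for r in rows:
        print(f"{r['quantity']} = {r['value']:g} {r['units']}")
    print(f"wrote phenotype_examples.tsv -> {out}")


if __name__ == "__main__":
    main()
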