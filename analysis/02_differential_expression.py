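#!/usr/bin/env python
"""Fold-change analysis of the synthetic time course.

Classifies every gene at every sampling point as up- / down-regulated
(>= 2-fold, <= 0.5-fold, boundaries inclusive) or unchanged, and reports
the fraction of measured genes changing at each sampling point per
condition — the genome-fraction-changed summary.  Reads the tables written
by 01_simulate.py and writes calls and fractions under results/diffexpr/.
"""

from tfactivity.diffexpr import classify_regulation, fraction_changed
from tfactivity.io import read_expression_table, write_table

from _paths import RESULTS


def main() -> None:
    out = RESULTS / "diffexpr"
    out.mkdir(parents=True, exist_ok=True)
    for label in ("A", "B"):
        expr = read_expression_table(RESULTS / "synthetic" / f"expr{label}.tsv", label)
        calls = classify_regulation(expr)
        write_table(calls.to_frame().to_dict("records"), out / f"calls_{label}.tsv")
        rows = [
            {"minute": t, "fraction_changed": fraction_changed(calls, t)}
            for t in calls.timepoints_min
        ]
        write_table(rows, out / f"fractions_{label}.tsv")
        peak = max(rows, key=lambda r: r["fraction_changed"])
        print(
            f"condition {label}: fraction changed peaks at {peak['minute']:g} min "
            f"({100 * peak['fraction_changed']:.0f}% of measured genes)"
        )
    print(f"wrote calls_*.tsv and fractions_*.tsv -> {out}")


if __name__ == "__main__":
    main()
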