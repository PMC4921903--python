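#!/usr/bin/env python
"""Generate the default two-condition synthetic dataset.

Emulates the study design downstream stages expect: 200 genes, 10 TFs with
overlapping regulons (~20 targets each, half the edges with a declared
sign), activities following pulse/rise/decline templates that differ
between the two conditions, additive noise sd 0.3 on the log2 scale, on
the 0-80 minute grid.  Writes the expression tables, the regulon table and
the ground-truth activities under results/synthetic/.
"""

import numpy as np

from tfactivity.io import write_table
from tfactivity.pipeline import _write_expression
from tfactivity.synthetic import GeneratorConfig, generate_dataset

from _paths import RESULTS

SEED = 11


def main() -> None:
    out = RESULTS / "synthetic"
    out.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(seed=SEED)
    exprs, network, truth = generate_dataset(cfg)

    for label, expr in exprs.items():
        _write_expression(expr, out / f"expr{label}.tsv")
    write_table(
        [
            {"tf": tf, "gene": g, "sign": {1: "+", -1: "-", None: "?"}[s]}
            for (tf, g), s in sorted(network.edges.items())
        ],
        out / "regulon.tsv",
        seed=SEED,
    )
    write_table(
        [
            {"condition": cond, "tf": tf, "minute": float(t), "activity": float(a)}
            for cond, C in sorted(truth.activities.items())
            for m, tf in enumerate(truth.tf_ids)
            for t, a in zip(cfg.timepoints, C[m])
        ],
        out / "truth.tsv",
        seed=SEED,
    )

    n_edges = len(network)
    sizes = [len(network.targets(tf)) for tf in network.tf_ids]
    print(f"seed {SEED}: {cfg.n_genes} genes x {len(cfg.timepoints)} timepoints, 2 conditions")
    print(f"regulon: {n_edges} edges over {cfg.n_tfs} TFs "
          f"(regulon sizes {min(sizes)}-{max(sizes)}, mean {np.mean(sizes):.1f})")
    print(f"wrote exprA.tsv, exprB.tsv, regulon.tsv, truth.tsv -> {out}")


if __name__ == "__main__":
    main()
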