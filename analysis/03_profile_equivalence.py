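#!/usr/bin/env python
"""Compare every product's release profile to the reference product (on!).

Builds mean percent-of-total-release curves from the synthetic replicates,
computes f1/f2 for each product against on!, applies the f1<=15 / f2>=50
rule, and cross-checks the decision rule against the published f1/f2 pairs
from the experimental study (whose raw replicate curves are unpublished).
"""

from _common import RESULTS, ensure_inputs
from pouchchar.equivalence import assess_equivalence
from pouchchar.pipeline import equivalence_matrix
from pouchchar.study import F1F2_EXPERIMENTAL
from pouchchar.synthetic import read_dissolution_csv


def main():
    config = ensure_inputs()
    profiles = read_dissolution_csv(config.dissolution_csv)
    table = equivalence_matrix(profiles, "on!")
    out = RESULTS / "table_equivalence.csv"
    table.to_csv(out, index=False)
    print("synthetic mean-curve equivalence vs on!:")
    print(table.to_string(index=False))

    print("\ndecision rule on the published experimental f1/f2 pairs:")
    for p, (f1, f2) in F1F2_EXPERIMENTAL.items():
        eq = assess_equivalence(f1, f2).equivalent
        print(f"  on! vs {p:<6} f1={f1:>5} f2={f2:>5} -> {'Yes' if eq else 'No'}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
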