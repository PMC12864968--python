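#!/usr/bin/env python
"""Physicochemical panel: solubility, oven volatiles, pH, water activity,
and extract viscosity summaries.

Runs the solubility mass balance and OV mass-loss computation on the
synthetic per-product records (the unfiltrable product propagates as N/A,
never 0), and summarizes each product's flow curve as mean viscosity plus
power-law flow index.
"""

import pandas as pd

from _common import RESULTS, ensure_inputs
from pouchchar.pipeline import _stage_physchem


def main():
    config = ensure_inputs()
    table = _stage_physchem(config)
    out = RESULTS / "table_physchem.csv"
    table.to_csv(out, index=False)
    print(table.to_string(index=False))
    most_viscous = table.loc[table["mean_viscosity_cP"].idxmax(), "product"]
    print(f"\nhighest mean extract viscosity: {most_viscous}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
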