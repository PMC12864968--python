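#!/usr/bin/env python
"""Generate the full synthetic input set emulating the seven-product study.

Writes dissolution, particle, density, physchem, and flow-curve CSVs under
scratch/study_inputs/ (12 replicates per product at the reference (M0, k),
lognormal particle populations, tap/pycnometer series, solubility records)
and echoes where they landed. All later stages read these files.
"""

import sys

from _common import INPUT_DIR, SEED, ensure_inputs


def main(seed: int = SEED):
    config = ensure_inputs(seed)
    print(f"synthetic study inputs written under {INPUT_DIR} (seed={seed})")
    print(f"  dissolution: {config.dissolution_csv}")
    print(f"  density:     {config.density_csv}")
    print(f"  physchem:    {config.physchem_csv}")
    print(f"  particles:   {len(config.particles_csv)} products")
    print(f"  flow curves: {len(config.flow_curve_csv)} products")
    return config


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else SEED)
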