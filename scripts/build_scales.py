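"""Regenerate the shipped hydrodiffusivity scale files.

Derives the M (extended capped monopeptide) and D (ideal-helix capped
decapeptide) variants from the shipped peptide diffusion table and the
internal SESA engine, and writes them to src/ride/data/.  Run from the
repository root:

    python scripts/build_scales.py
"""

import pathlib
import sys
import time

from ride.constants import ETA_TIP3P_310, T_PHYS
from ride.hydro_scale import (NMA_D0, DiffusionEstimate, build_scale,
                              load_peptide_table)
from ride.sesa import DEFAULT_RADIUS_SET, assign_radii, compute_sesa

OUT_DIR = pathlib.Path(__file__).resolve().parents[1] / "src" / "ride" / "data"


def main():
    table = load_peptide_table()
    nma_d = DiffusionEstimate(NMA_D0, T_PHYS, ETA_TIP3P_310)
    provider = lambda s: compute_sesa(assign_radii(s, DEFAULT_RADIUS_SET))
    for variant, column in (("M", "d0_mono"), ("D", "d0_deca")):
        t0 = time.time()
        d_table = {aa: DiffusionEstimate(row[column], T_PHYS, ETA_TIP3P_310)
                   for aa, row in table.items()}
        scale = build_scale(d_table, nma_d, provider, variant=variant,
                            radius_set_name=DEFAULT_RADIUS_SET.name)
        out = OUT_DIR / f"hydro_scale_{variant}.tsv"
        scale.save(out)
        print(f"variant {variant}: wrote {out} in {time.time() - t0:.0f} s",
              file=sys.stderr)


if __name__ == "__main__":
    main()
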