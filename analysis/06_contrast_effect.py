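#!/usr/bin/env python
"""Quantify the contrast shielding effect on the stomach wall for the
right-lateral duodenal field (field 6, normal series): dose coefficients
with and without 100% barium suspension in the stomach contents.

Writes results/contrast_effect_6N.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ugidose.phantom import apply_contrast, build_phantom
from ugidose.protocols import load_protocol
from ugidose.spectra import match_hvl
from ugidose.transport import TransportConfig, kap_per_history, run_transport

OUT = Path(__file__).resolve().parents[1] / "results"
ORGANS = ("stomach_wall", "stomach_contents", "si_wall", "spleen", "liver",
          "kidneys", "colon")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--histories", type=int, default=400_000)
    ap.add_argument("--voxel-mm", type=float, default=2.0)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    protocol = load_protocol("newborn", "normal")
    f6 = {f.field_id: f for f in protocol.fields}["6N"]
    phantom = build_phantom("newborn", args.voxel_mm)
    with_ba = apply_contrast(phantom, protocol.contrast_distribution(), "6N")
    beam = protocol.beam_for_field(phantom, f6)
    spectrum = match_hvl(65.0, 4.41)

    cfg0 = TransportConfig(histories=args.histories, batches=20,
                           seed=args.seed)
    cfg1 = TransportConfig(histories=args.histories, batches=20,
                           seed=args.seed + 49_000)
    r0 = run_transport(phantom, beam, spectrum, cfg0)
    r1 = run_transport(with_ba, beam, spectrum, cfg1)
    kap, _ = kap_per_history(beam, spectrum, cfg0)

    rows = []
    for organ in ORGANS:
        d0, d1 = r0.dose[organ], r1.dose[organ]
        e0, e1 = r0.relative_error[organ], r1.relative_error[organ]
        z = (d1 - d0) / np.hypot(d0 * e0, d1 * e1) if d0 > 0 else np.nan
        rows.append({"organ": organ,
                     "dc_no_contrast_mgy_per_gycm2": 1e3 * d0 / kap,
                     "dc_with_barium_mgy_per_gycm2": 1e3 * d1 / kap,
                     "ratio": d1 / d0 if d0 > 0 else np.nan,
                     "z_score": z})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "contrast_effect_6N.csv", index=False,
              float_format="%.4g")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    sw = df[df.organ == "stomach_wall"].iloc[0]
    print(f"\nstomach-wall dose ratio with barium: {sw.ratio:.2f} "
          f"(z = {sw.z_score:.1f}); the contents region itself rises "
          f"because the suspension absorbs the beam selectively.")
    print(f"wrote {OUT / 'contrast_effect_6N.csv'}")


if __name__ == "__main__":
    main()
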