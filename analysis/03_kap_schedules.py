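#!/usr/bin/env python
"""Solve the kerma-area-product scaling model and emit the per-field KAP
schedules for all four reference examinations.

Writes results/kap_schedule_<age>_<diagnosis>.csv.
"""

from pathlib import Path

import pandas as pd

from ugidose.dosimetry import kap_schedule, solve_pulse_kap
from ugidose.protocols import TOTAL_FLUORO_SECONDS, load_protocol

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    model = solve_pulse_kap()
    print(f"per-pulse KAP:  {model.p_pulse_mgy_cm2:.4f} mGy cm^2")
    print(f"per-frame KAP:  {model.p_frame_mgy_cm2:.3f} mGy cm^2 "
          f"({model.pulses_per_film:g} pulse-equivalents)")
    for age, diag in TOTAL_FLUORO_SECONDS:
        protocol = load_protocol(age, diag)
        sched = kap_schedule(protocol, model)
        df = pd.DataFrame({
            "field": sched.field_ids,
            "fluoro_seconds": [f.fluoro_seconds for f in protocol.fields],
            "fluoro_kap_gy_cm2": sched.fluoro_gy_cm2,
            "spot_film_kap_gy_cm2": sched.rad_gy_cm2,
        })
        path = OUT / f"kap_schedule_{age}_{diag}.csv"
        df.to_csv(path, index=False, float_format="%.4g")
        print(f"{age:9s} {diag:9s}: {len(sched.field_ids)} fields, "
              f"total {sched.total:.4g} Gy cm^2 -> {path.name}")


if __name__ == "__main__":
    main()
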