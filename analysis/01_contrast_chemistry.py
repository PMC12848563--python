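#!/usr/bin/env python
"""Characterise the two contrast agents: solution fractions, molecular
weights, and transport-ready elemental compositions.

Writes results/contrast_agents.csv.
"""

from pathlib import Path

import pandas as pd

from ugidose.materials import (EZ_PAQUE, OMNIPAQUE_140, agent_composition,
                               molecular_weight, parse_molecular_formula,
                               solution_mass_fractions)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for agent in (EZ_PAQUE, OMNIPAQUE_140):
        fractions = solution_mass_fractions(agent)
        comp = agent_composition(agent)
        for formula, frac in fractions.items():
            mw = molecular_weight(parse_molecular_formula(formula))
            rows.append({"agent": agent.name, "compound": formula,
                         "molecular_weight_g_mol": round(mw, 4),
                         "mass_fraction": round(frac, 6),
                         "solution_density_g_ml": agent.density})
        heavy = {s: round(w, 4) for s, w in comp.fractions.items()
                 if s in ("Ba", "I")}
        print(f"{agent.name}: density {agent.density} g/mL, "
              f"heavy-element mass fractions {heavy}")
    OUT.mkdir(exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "contrast_agents.csv", index=False)
    print(f"barium sulfate suspension fraction: "
          f"{solution_mass_fractions(EZ_PAQUE)['BaSO4']:.4f} (sheet: 0.4098)")
    print(f"iohexol solution fraction:          "
          f"{solution_mass_fractions(OMNIPAQUE_140)['C19H26I3N3O9']:.4f} "
          f"(sheet: 0.2595)")
    print(f"wrote {OUT / 'contrast_agents.csv'}")


if __name__ == "__main__":
    main()
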