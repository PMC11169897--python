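"""Light attenuation between the illuminated face and the cathode array.

Tabulates the two Beer-Lambert channels (A-AgNP molar absorption, decadic;
host-layer absorption, natural) versus filling fraction at the 453 nm
design wavelength.  Expected outcome: the nanoparticle channel loses more
light as f_s grows (94.6% transmitted at f_s = 10%) while the layer channel
gains slightly (volume displacement), leaving the total transmittance T_r
nearly constant at ~0.55 - the number that scales the cathode term of the
photocurrent.
"""

from pathlib import Path

import pandas as pd

from plasmopv.attenuation import total_transmittance
from plasmopv.materials import DeviceScenario

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for f_s in (0.0, 0.05, 0.075, 0.10):
        scn = DeviceScenario(fill_fraction=f_s) if f_s else (
            DeviceScenario(fill_fraction=0.0, include_k_term=False,
                           include_a_term=False))
        res = total_transmittance(scn)
        rows.append({
            "fill_fraction": f_s,
            "t_nanoparticles_pct": res.t_nanoparticles * 100,
            "t_layer_pct": res.t_layer * 100,
            "t_total": res.t_total,
            "molar_absorptivity_l_mol_cm": res.molar_absorptivity_l_mol_cm,
            "concentration_mol_l": res.concentration_mol_l,
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "attenuation_vs_fill_fraction.csv", index=False)
    print(table.to_string(index=False))
    print("\nNanoparticle transmittance falls with loading while the layer "
          "channel rises slightly; their product T_r stays near 0.55. A "
          "single exponential channel cannot also reproduce the published "
          "99/97% values at the two lighter loadings (see docs/methods.md).")


if __name__ == "__main__":
    main()
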