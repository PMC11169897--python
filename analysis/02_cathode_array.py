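"""Far-field optics of the cathode nanoparticle monolayer.

Writes (a) the packaged reference anchors (printed absorptance peaks
68/65/58/50% for gaps 1/1.5/2.5/5 nm and the 1500 nm^2 per-particle
cross-section of the design array at 453 nm) and (b) full coupled-dipole
spectra as the computable substitute.  Expected outcome: the collective
resonance blue-shifts as the gap widens and denser arrays absorb more; the
dipole model underestimates the absolute absorptance at nm gaps (no
multipolar gap hot-spots), which is why the pipeline's default absorptance
source is the reference table.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from plasmopv.karray import (ArraySpec, array_resonance_nm,
                             coupled_dipole_spectra, default_karray_grid,
                             reference_spectra)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    grid = default_karray_grid()
    rows = []
    for gap in (1.0, 1.5, 2.5, 5.0):
        spec = ArraySpec(gap_nm=gap)
        cd = coupled_dipole_spectra(spec, grid)
        cd.to_csv(RESULTS / f"karray_cd_gap{gap:g}.csv")
        ref = reference_spectra(spec)
        i453 = np.isclose(ref.wavelengths_nm, 453.0)
        rows.append({
            "gap_nm": gap,
            "printed_peak_absorptance": np.nanmax(ref.absorptance),
            "reference_a_b_453": float(ref.absorptance[i453][0]),
            "cd_resonance_nm": array_resonance_nm(spec, grid),
            "cd_peak_absorptance": float(np.max(cd.absorptance)),
            "cd_energy_closure": float(np.max(np.abs(
                cd.absorptance + cd.reflectance + cd.transmittance - 1.0))),
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "karray_summary.csv", index=False)
    print(table.to_string(index=False))
    print("\nCollective resonance blue-shifts and peak absorption falls as "
          "the gap widens; the design array (gap 1.5 nm) is anchored at "
          "453 nm with A_b = 0.65 and 1500 nm^2 per particle.")


if __name__ == "__main__":
    main()
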