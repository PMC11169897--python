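"""Plate-electrode field and axon activation threshold.

Solves the equipotential-plate current distribution in retinal-tissue
conductivity, samples the current density along the axon line at the 5 um
standoff, and bisects the Hodgkin-Huxley cable threshold for a 1 ms
cathodic pulse.  Expected outcome: the current-density profile is
edge-peaked with a central plateau and its footprint mean at the -0.11 V
design voltage is of the 25 A/m^2 activation order; the cable fires
all-or-none with a finite sub-volt threshold that falls for longer pulses
and rises with electrode-axon distance.  The membrane model is a
qualitative substitute, so thresholds are orders-of-magnitude, not
device-exact.
"""

from pathlib import Path

import numpy as np

from plasmopv.neurostim import (AxonSpec, ElectrodeSpec, StimulusPulse,
                                axon_field_profile, plate_current_profile,
                                simulate_membrane, threshold_search)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    electrode, axon = ElectrodeSpec(), AxonSpec()

    x, j = plate_current_profile(electrode, -0.11)
    np.savetxt(RESULTS / "plate_current_profile.csv",
               np.column_stack([x, j]), delimiter=",", comments="",
               header="x_um,j_a_m2", fmt="%.8g")
    mask = np.abs(x) <= 88.5
    print(f"mean |J| over the effective footprint at -0.11 V: "
          f"{np.mean(np.abs(j[mask])):.1f} A/m^2 "
          f"(edge peak {np.max(np.abs(j)):.1f}, "
          f"centre {np.abs(j[len(j)//2]):.1f})")

    threshold = threshold_search(electrode, axon)
    print(f"threshold electrode voltage (1 ms cathodic): -{threshold:.3f} V")
    for duration in (0.5, 2.0):
        th = threshold_search(electrode, axon, pulse_duration_ms=duration,
                              t_total_ms=4.0 + duration)
        print(f"  duration {duration} ms -> -{th:.3f} V")

    for factor, label in ((0.95, "sub"), (1.05, "supra")):
        amp = factor * threshold
        trace = simulate_membrane(
            axon, axon_field_profile(electrode, axon, -amp),
            StimulusPulse(-amp))
        centre = trace.v_mv[:, len(axon.positions_um()) // 2]
        np.savetxt(RESULTS / f"membrane_{label}threshold.csv",
                   np.column_stack([trace.times_ms, centre]),
                   delimiter=",", comments="", header="t_ms,v_mv",
                   fmt="%.6g")
        print(f"{label}threshold ({factor:.2f}x): peak membrane potential "
              f"{trace.peak_mv:.1f} mV -> "
              f"{'action potential' if trace.spiked() else 'silent'}")


if __name__ == "__main__":
    main()
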