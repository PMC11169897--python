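"""Regenerate the packaged fixtures and frozen calibration constants.

Writes silver/water/active_blend optical-constant CSVs, the cathode-array
reference table, the device performance reference and calibration.json into
src/plasmopv/data.  Run from the repository root:

    python scripts/build_fixtures.py
"""

from pathlib import Path

from plasmopv.calibrate import write_all


def main() -> None:
    data_dir = Path(__file__).resolve().parents[1] / "src" / "plasmopv" / "data"
    calib = write_all(data_dir)
    print(f"fixtures written to {data_dir}")
    for key, value in calib.items():
        if key != "anchors":
            print(f"  {key:28s} {value:.6g}")


if __name__ == "__main__":
    main()
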