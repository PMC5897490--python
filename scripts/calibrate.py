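"""Regenerate the calibrated entries of src/anophys/data/param_sets.json.

Run from the repository root:

    python scripts/calibrate.py [--n-cells 400]

Rewrites the bundled parameter file in place: conductance scales,
detection offsets, the amplitude-calibrated anion permeability, and the
scrambling latency location / onset-delay correction.
"""

import argparse
from pathlib import Path

from anophys.pipeline import calibrate_defaults

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-cells", type=int, default=400)
    ap.add_argument(
        "--out",
        default=Path(__file__).resolve().parents[1]
        / "src" / "anophys" / "data" / "param_sets.json",
    )
    args = ap.parse_args()
    calibrate_defaults(out_path=args.out, n_cells=args.n_cells, verbose=True)
    print(f"wrote {args.out}")
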