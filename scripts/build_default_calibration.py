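"""Regenerate the default calibration bundle shipped with the package.

Run from the repository root:

    python scripts/build_default_calibration.py

Writes src/zipfent/data/default_calibration.json.  The protocol per
family (grid, trial count, samples per trial, fit form, seed) is fixed
here and recorded in each model's metadata.
"""

import json
import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from zipfent.calibration import SimulationConfig, calibrate, log_grid

OUT = Path(__file__).resolve().parents[1] / "src" / "zipfent" / "data" / "default_calibration.json"

GRID = log_grid(8, 160, 40)

PROTOCOLS = {
    # family: (ranks, samples, trials, form)
    "zml": ((1, 2, 3), 1_000_000, 50, "polynomial"),
    "equiprobable": ((1,), 1_000_000, 50, "power"),
    "czml1": ((1,), 200_000, 50, "polynomial"),
    "czml2": ((1,), 200_000, 50, "polynomial"),
}


def main() -> None:
    bundle = {}
    for family, (ranks, samples, trials, form) in PROTOCOLS.items():
        t0 = time.time()
        config = SimulationConfig(
            seed=1, trials=trials, samples=samples, M_grid=GRID
        )
        model = calibrate(family, config, ranks=ranks, form=form)
        bundle[family] = json.loads(model.to_json())
        print(
            f"{family}: {len(GRID)} grid points, ranks {ranks}, "
            f"max rel residual {model.metadata['max_relative_residual']} "
            f"({time.time() - t0:.1f}s)"
        )
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(bundle, indent=1, sort_keys=True) + "\n",
                   encoding="utf-8")
    print(f"wrote {OUT} ({OUT.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
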