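"""Generate the two study scenes (inland and coastal synthetic cities).

Writes every layer as GeoTIFF under scratch/scenes/<name>/ and prints
what the scenes contain.  Downstream drivers load the scenes from there.
"""

from pathlib import Path

import numpy as np

import heatrisk as hr
from heatrisk.synthetic import save_scene

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "scenes"
SEEDS = {"inland": 1, "coastal": 2}


def main() -> None:
    for preset, seed in SEEDS.items():
        spec = hr.default_spec(preset, seed=seed)
        scene = hr.generate_scene(spec)
        out = save_scene(scene, SCRATCH / scene.name)
        pop = np.nansum(scene.population_total.values)
        water_pct = 100.0 * (scene.land_cover.codes == 210).mean()
        classes = sorted(set(scene.land_cover.labels) - {210})
        print(f"{scene.name}: 30 km x 30 km, classes {classes}, "
              f"water {water_pct:.0f}%, population {pop:,.0f}, "
              f"elderly fractions {sorted(scene.elderly_fractions.values())}")
        print(f"  -> {out}")


if __name__ == "__main__":
    main()
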