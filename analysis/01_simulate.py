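"""Generate the synthetic pharmacy world at study scale.

Writes the five tables (catalog, packs, dispensing, raw shortage reports,
latent truth) to scratch and a small summary of the world to results.
"""

import json

from common import RESULTS, SCRATCH, STUDY_CONFIG, ensure_dirs
from shortcast import simulate_world


def main() -> None:
    ensure_dirs()
    world = simulate_world(STUDY_CONFIG)
    world.write(SCRATCH / "data")

    summary = {
        "n_igs": int(world.catalog["ig_code"].nunique()),
        "n_dins": int(world.catalog["din"].nunique()),
        "n_pack_listings": len(world.packs),
        "n_months": len(STUDY_CONFIG.month_index),
        "n_shortage_events": len(world.latent),
        "n_raw_reports": len(world.reports),
        "months": list(STUDY_CONFIG.months),
    }
    (RESULTS / "world_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print("Synthetic world:", json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
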