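"""Shared setup for the numbered analysis drivers.

The world is defined once in ``analysis/config.yaml`` and regenerated
deterministically from its seed by every script, so no gridded rasters
need to be written to disk; tabular intermediates flow through
``results/``.
"""

from pathlib import Path

import yaml

from petreldsm import synthetic as syn

HERE = Path(__file__).resolve().parent
ROOT = HERE.parent
RESULTS = ROOT / "results"


def load_config() -> dict:
    with open(HERE / "config.yaml") as fh:
        return yaml.safe_load(fh)


def build_world(cfg: dict):
    """(env, colonies, truth, design) for the configured world."""
    w = cfg["world"]
    config = syn.WorldConfig(
        extent=tuple(w["extent"]), cell_km=w["cell_km"],
        land=syn.LandSpec(cx=w["land"]["cx"], cy=w["land"]["cy"],
                          rx=w["land"]["rx"], ry=w["land"]["ry"],
                          islets=tuple(tuple(i) for i in w["land"]["islets"])),
        seed=w["seed"])
    env = syn.gen_environment(config)
    colonies = syn.gen_colonies(env, n=cfg["colonies"]["n"],
                                total_pairs=cfg["colonies"]["total_pairs"],
                                seed=w["seed"] + 1)
    truth = syn.gen_truth(env, target_total=cfg["truth"]["target_total"],
                          theta=cfg["truth"]["theta"])
    d = cfg["transects"]
    design = syn.TransectDesign(broad_spacing_km=d["broad_spacing_km"],
                                fine_spacing_km=d["fine_spacing_km"],
                                fine_region=tuple(d["fine_region"]))
    return env, colonies, truth, design
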