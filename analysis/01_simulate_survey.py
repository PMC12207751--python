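"""Generate the synthetic study: world, colonies, true density surface,
strip transects and detection-thinned sightings.

Writes transect segments, sightings and colonies to results/sim/ together
with a truth summary, and prints the survey's vital statistics.
"""

import json

import numpy as np

from common import RESULTS, build_world, load_config
from petreldsm import synthetic as syn

cfg = load_config()
env, colonies, truth, design = build_world(cfg)
seed = cfg["world"]["seed"]

segs = syn.gen_transects(env, design, seed=seed + 2)
sightings = syn.gen_sightings(truth, segs, seed=seed + 3)

out = RESULTS / "sim"
out.mkdir(parents=True, exist_ok=True)
segs.to_csv(out / "transect_segments.csv", index=False)
sightings.to_csv(out / "sightings.csv", index=False)
colonies.to_csv(out / "colonies.csv", index=False)

on = segs[segs["effort"]]
seg_len = np.hypot(on["x1"] - on["x0"], on["y1"] - on["y0"])
summary = {
    "sea_cells": int((~env.land_mask).sum()),
    "true_total_abundance": truth.total,
    "true_intercept": truth.intercept,
    "dispersion_theta": truth.dispersion_theta,
    "n_transects": int(segs["transect_id"].nunique()),
    "trackline_km": syn.total_trackline_km(segs),
    "on_effort_km": float(seg_len.sum()),
    "pct_effort_seastate_le3": float(100 * seg_len[on["sea_state"] <= 3].sum()
                                     / seg_len.sum()),
    "n_sightings": int(len(sightings)),
    "n_individuals": int(sightings["group_size"].sum()),
    "pct_single_sightings": float(100 * (sightings["group_size"] == 1).mean()),
}
(out / "summary.json").write_text(json.dumps(summary, indent=2))

print(f"world: {summary['sea_cells']} sea cells; "
      f"true total {truth.total:.0f} birds")
print(f"survey: {summary['n_transects']} transects, "
      f"{summary['trackline_km']:.0f} km trackline "
      f"({summary['pct_effort_seastate_le3']:.1f}% of effort at sea state <= 3)")
print(f"sightings: {summary['n_sightings']} groups, "
      f"{summary['n_individuals']} individuals "
      f"({summary['pct_single_sightings']:.1f}% singletons)")
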