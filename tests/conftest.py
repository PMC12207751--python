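"""Shared fixtures: a small synthetic world exercised by several modules."""

import pytest

from petreldsm import gridding as gr
from petreldsm import studies as st
from petreldsm import synthetic as syn


@pytest.fixture(scope="session")
def small_world():
    """A compact world: ~1800 sea cells, island on the east, one islet."""
    config = syn.WorldConfig(
        extent=(0.0, 160.0, 0.0, 200.0), cell_km=4.0,
        land=syn.LandSpec(cx=145.0, cy=100.0, rx=18.0, ry=55.0,
                          islets=((120.0, 40.0, 5.0),)),
        seed=7,
    )
    env = syn.gen_environment(config)
    colonies = syn.gen_colonies(env, n=3, total_pairs=20_000, seed=8)
    truth = syn.gen_truth(env, target_total=12_000)
    return env, colonies, truth


@pytest.fixture(scope="session")
def small_survey(small_world):
    """Transects, sightings and gridded records for the small world."""
    env, colonies, truth = small_world
    design = syn.TransectDesign(broad_spacing_km=12.0,
                                fine_region=(60.0, 125.0, 30.0, 110.0))
    segs = syn.gen_transects(env, design, seed=9)
    sightings = syn.gen_sightings(truth, segs, seed=10)
    effort = gr.effort_per_cell(env.grid, segs)
    records = gr.aggregate_counts(env.grid, sightings, effort)
    return segs, sightings, effort, records


@pytest.fixture(scope="session")
def cell_records():
    """Factory for fast cell-level survey records (no strip geometry)."""
    return st.simulate_cell_survey
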