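# Desk-scale synthetic study area: ~113,000 km^2 (a quarter of the full
# 450,000 km^2 default world), 4 km grid, island coast on the east with a
# fine-scale survey block off its south-west shore.  All randomness flows
# from world.seed.
world:
  extent: [0.0, 300.0, 0.0, 376.0]
  cell_km: 4.0
  seed: 11
  land:
    cx: 270.0
    cy: 190.0
    rx: 28.0
    ry: 85.0
    islets: [[235.0, 70.0, 5.0]]

colonies:
  n: 6
  total_pairs: 25000

truth:
  target_total: 75000.0     # birds; mean density ~0.33 birds/km^2 at sea
  theta: 2.0

transects:
  broad_spacing_km: 10.0
  fine_spacing_km: 3.704    # two nautical miles
  fine_region: [150.0, 245.0, 40.0, 140.0]

# covariates offered to the habitat models (exhaustive AIC subset search
# runs over the concurvity-linked members of this list)
model_covariates: [dist_coast, dist_shelf, depth, chl_a, sst, sss,
                   grad_sst, colony_score, julian_day]
boxcox_candidates: [dist_coast, dist_shelf, chl_a, sss, grad_chl,
                    grad_sst, grad_sss, colony_score, slope]

bootstrap_B: 300
validation_iterations: 100
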