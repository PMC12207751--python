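"""Engineer the per-cell covariates (distances, depth/slope, gradients,
land-avoiding colony proximity score), Box-Cox transform the skewed ones,
and attach everything to the survey records.
"""

import json

import pandas as pd

from common import RESULTS, build_world, load_config
from petreldsm import covariates as cov

cfg = load_config()
env, colonies, _, _ = build_world(cfg)

records = pd.read_csv(RESULTS / "records.csv")
dual = pd.read_csv(RESULTS / "dual_records.csv")

table = cov.covariate_table(env.grid, env.land_mask, env.fields, colonies)
table_t, transforms = cov.boxcox_where_required(table, cfg["boxcox_candidates"])

records = cov.attach_covariates(records, table_t)
dual = cov.attach_covariates(dual, table_t)

table_t.to_csv(RESULTS / "covariate_table.csv", index=False)
records.to_csv(RESULTS / "records_covariates.csv", index=False)
dual.to_csv(RESULTS / "dual_records_covariates.csv", index=False)
(RESULTS / "boxcox.json").write_text(json.dumps(
    {k: {"lambda": t.lmbda, "shift": t.shift} for k, t in transforms.items()},
    indent=2))

print(f"covariate table: {len(table_t)} sea cells x "
      f"{len(table_t.columns) - 4} covariates")
print("Box-Cox transformed (|skewness| > 1):",
      {k: round(t.lmbda, 2) for k, t in transforms.items()})
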