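"""80/20 train/test validation of the selected distribution model:
100 random splits, each refitted and scored by total predicted versus
observed abundance on the held-out rows.
"""

import json
import warnings

import pandas as pd

from common import RESULTS, load_config
from petreldsm import abundance as ab
from petreldsm.nbgam import term_from_dict

cfg = load_config()
records = pd.read_csv(RESULTS / "records_covariates.csv")
structure = json.loads((RESULTS / "distribution_summary.json").read_text())
terms = [term_from_dict(d) for d in structure["final_structure"]]

with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    rep = ab.validate_split(records, terms,
                            n_iter=cfg["validation_iterations"],
                            seed=cfg["world"]["seed"] + 10,
                            theta=structure["theta"])

rep.results.to_csv(RESULTS / "validation.csv", index=False)
summary = {
    "share_within_5pct": rep.share_within_5pct,
    "share_within_10pct": rep.share_within_10pct,
    "median_abs_rel_error": rep.median_abs_rel_error,
    "mean_rel_error": rep.mean_rel_error,
    "n_failed": rep.n_failed,
}
(RESULTS / "validation_summary.json").write_text(json.dumps(summary, indent=2))

print(f"{rep.n_iterations} iterations ({rep.n_failed} failed)")
print(f"{100 * rep.share_within_5pct:.0f}% of test predictions within 5% "
      f"of observed; {100 * rep.share_within_10pct:.0f}% within 10%")
print(f"median |relative error| {100 * rep.median_abs_rel_error:.1f}%; "
      f"mean signed error {100 * rep.mean_rel_error:+.1f}% "
      f"(negative = underestimation)")
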