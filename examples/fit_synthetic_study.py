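"""Generate a synthetic 82-patient trial and recover the parameters.

Builds one replicate of the study design (sparse paired plasma/CSF sampling
after the fourth dose, truncated-normal drainage volumes), fits it with the
naive-pooled ML estimator and with the iterated two-stage estimator, and
compares both against the generating typical values.
"""

import pandas as pd

from meropk import (PopulationSpec, StudyDesign, fit_pooled, fit_two_stage,
                    generate_study)

spec = PopulationSpec()
dataset = generate_study(StudyDesign(), spec, seed=7)
print(f"dataset: {len(dataset.subjects)} subjects, "
      f"{dataset.n_observations(1)} plasma + "
      f"{dataset.n_observations(2)} CSF observations")

pooled = fit_pooled(dataset, n_starts=1)
two_stage = fit_two_stage(dataset)

truth = {"v1_l": 17.9, "v3_l": 3.84, "cl1_l_per_h": 22.2,
         "q1_l_per_h": 0.010, "q2_l_per_h": 1.79, "pc": 0.172,
         "residual_cv_pct": 34.9}
table = pd.DataFrame({
    "truth": truth,
    "pooled": {k: pooled.estimates()[k] for k in truth},
    "two_stage": {k: two_stage.estimates()[k] for k in truth},
})
print(table.round(4).to_string())
print()
print("The pooled estimator flattens the log-normal parameter mixture, so "
      "its residual CV absorbs the between-subject variability; the "
      "two-stage estimator targets the typical (median) values and its "
      "residual CV stays near the generating 34.9%.")
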