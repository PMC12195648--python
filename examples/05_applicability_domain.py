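"""Standardization applicability domain in PLS latent-score space.

A prediction is only trustworthy for compounds resembling the training
set.  Each latent-score coordinate is standardized against the training
distribution; compounds within 3 sd on every axis are inside the domain,
and borderline cases are decided by S_new = mean + 1.28 sd of their
deviates.
"""

import numpy as np

from fieldqsar import ad_assess, ad_report
from fieldqsar.synth import recovery_run

run = recovery_run(seed=1, n_compounds=20)
fit = run["fit"]
train_scores = fit.x_scores()
rep = ad_report(train_scores, train_scores,
                [f"cpd_{i + 1:03d}" for i in range(len(train_scores))])
print(rep.head(8).to_string(index=False))
print(f"{(rep.verdict == 'inside').sum()} of {len(rep)} training compounds "
      "inside their own domain")

# the intermediate hand case: one large deviate among small ones
v = ad_assess(np.array([0.5, 4.0]))
print(f"S = (0.5, 4.0): S_new = {v.s_new:.3f} -> "
      f"{'inside' if v.inside else 'outside'}")
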