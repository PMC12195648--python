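"""One-call pipeline run: synthetic inputs to the full report set.

Writes the model-search table, validation report, predictions with
outlier flags, AD report, contour grids and an archived configuration
into a run directory, then re-scores the training molecules with the
stored model artifact.
"""

import json
from pathlib import Path
from tempfile import mkdtemp

from fieldqsar import RunConfig, run
from fieldqsar.pipeline import predict

out = run(RunConfig(synthetic=True,
                    synthetic_spec={"n_compounds": 20, "seed": 7},
                    randomization_iterations=10),
          Path(mkdtemp()) / "demo_run")
print("artifacts:", sorted(p.name for p in out.iterdir()))

report = json.loads((out / "validation.json").read_text())
print(f"best model {report['best_model']}: q2 = {report['q2']:.3f}, "
      f"r2_ncv = {report['r2_ncv']:.3f}, SEE = {report['see']:.3f}")
print(f"external verdict: {report['external']['conditions']['verdict']}")

scored = predict(out / "model.joblib", out / "molecules.sdf")
print(scored.head(5).to_string(index=False))
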