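"""Score a cohort with the published 20-term signature.

The published signature combines 18 proteins and 2 sex hormones
(testosterone, SHBG) with fixed weights; the score is their weighted sum on
standardized levels.  Here a small synthetic cohort is standardized to its
own scale and scored.
"""

import numpy as np
import pandas as pd

from trialmr import published_signature, score, standardize

model = published_signature()
print(f"{len(model.names)} terms; reported LOO-CV AUC {model.cv_auc}")
print("largest positive / negative weights:",
      max(zip(model.weights, model.names)), min(zip(model.weights, model.names)))

rng = np.random.default_rng(0)
cohort = pd.DataFrame(rng.normal(5, 2, size=(5, 20)), columns=model.names)
z, scaler = standardize(cohort)
print("\nper-subject signature scores:")
print(score(model, z).round(3).to_string())
# One unit of standardized testosterone contributes +0.21; one unit of
# standardized PRSS2 contributes -0.35: a high score means a
# treatment-like biomarker profile.
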