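"""Parameter recovery from a synthetic noisy study.

Generates 30 virtual children with a mix of mild and severe CKD, simulates
their true concentration profiles, corrupts them with 20% log-normal residual
error, and checks how well NCA on the noisy data recovers the true exposure
and clearance — the calibration that justifies trusting the same NCA on real
sparse profiles.
"""

import numpy as np

from captoped import nca
from captoped.synthdata import SyntheticStudySpec, generate_study

spec = SyntheticStudySpec(
    n_subjects=30,
    ckd_stages={"mild": 0.5, "severe": 0.5},
    dose_mg_per_kg=1.5,
    residual_error=0.2,
    seed=21,
)
subjects, observed_profiles, truth = generate_study(spec)

est_clf = np.array([nca.nca(p).cl_f for p in observed_profiles])
true_clf = truth["cl_f"].to_numpy()
ratios = est_clf / true_clf

print(f"{len(subjects)} subjects, residual log-normal sd {spec.residual_error}")
print(f"mean CL/F recovery ratio (estimated/true): {ratios.mean():.3f}")
print(f"between-subject sd of the ratio:           {ratios.std(ddof=1):.3f}")
by_stage = truth.groupby("ckd_stage")["cl_f"].mean()
print("\ntrue mean CL/F by stage (L/h):")
for stage, value in by_stage.items():
    print(f"  {stage:8s} {value:6.2f}")
print("\nA recovery ratio near 1 shows the NCA is unbiased under this noise")
print("model; the stage contrast reflects the GFR-linked clearance reduction.")
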