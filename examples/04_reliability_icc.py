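"""Measurement reliability with the intraclass correlation coefficient.

Emulates an intra-observer reliability study: two measurement sessions
of LCEA on the same ten synthetic hips, with small session-specific
noise, assessed with ICC(2,1) (two-way random effects, absolute
agreement, single measures).
"""

import numpy as np

from hipmorph import SyntheticHipParams, generate_hip, icc_reliability, measure_lcea

rng = np.random.default_rng(7)
true_lcea = []
for i in range(10):
    params = SyntheticHipParams(
        rim_colatitude_deg=float(rng.normal(40.0, 3.0)),  # between-subject spread
        seed=int(rng.integers(2**31)),
    )
    model, _ = generate_hip(params)
    true_lcea.append(measure_lcea(model))
true_lcea = np.asarray(true_lcea)

# two rating sessions: remeasurement noise of 0.5 deg SD
sessions = np.column_stack([true_lcea + 0.5 * rng.standard_normal(10) for _ in range(2)])
res = icc_reliability(sessions)

print("session means:", np.round(sessions.mean(axis=0), 2))
print(f"{res.model_label}")
print(f"ICC = {res.icc:.3f}")
print(
    "\nValues near 1 mean between-hip differences dwarf remeasurement "
    "noise; published 3D CEA protocols report ICCs of 0.97-0.99."
)
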