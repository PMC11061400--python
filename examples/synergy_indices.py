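"""From raw simulated sEMG to per-arm muscle-synergy indices.

Runs the full preprocessing chain (20-450 Hz band-pass, rectification, 5 Hz
envelope, force-gated lift segmentation with the 3 s / 15% exclusion rules,
block min-max + time normalization), decomposes each lift with MCR-ALS, and
reports SSI, C_V and C_T against a healthy-control baseline.
"""

import numpy as np

import strokesyn as ss
from strokesyn.cohort import V_HEALTHY
from strokesyn.synergy import compute_baseline

config = ss.SimulationConfig(n_patients=1, n_controls=2, seed=3,
                             trials_per_block=2)
profiles, truths = ss.generate_cohort(config)

# control-group baseline for the non-dominant hand (matched to affected arm)
control_models = {}
for p in profiles:
    if p.group != "control":
        continue
    ses = ss.simulate_emg_session(p, "affected", config, truths[p.subject_id])
    lifts, _ = ss.preprocess_session(ses)
    control_models[p.subject_id] = [ss.mcr_als_decompose(s.X, 1) for s in lifts]
baseline = compute_baseline(control_models, hand="non-dominant")
print("baseline V_B (DA DP BI TI BIO):", np.round(baseline.V_B, 3))
print("cosine to canonical healthy pattern:",
      round(float(baseline.V_B @ V_HEALTHY), 4))

patient = profiles[0]
for arm in ("affected", "unaffected"):
    ses = ss.simulate_emg_session(patient, arm, config, truths[patient.subject_id])
    lifts, excl = ss.preprocess_session(ses)
    models = [ss.mcr_als_decompose(s.X, 1) for s in lifts]
    agg = ss.aggregate_indices([m.V[:, 0] for m in models],
                               [m.T[0, :] for m in models],
                               baseline.V_B, baseline.T_B, arm=arm)
    print(f"\n{arm} arm: {len(lifts)} lifts retained, {len(excl)} excluded")
    print(f"  SSI={agg.ssi:.3f}  C_V={agg.c_v:.3f}  C_T={agg.c_t:.3f}")

print(f"\npatient severity {patient.severity:.2f}: the affected arm shows a"
      "\nless stable (SSI) and less healthy-like (C_V) synergy than the"
      "\nunaffected arm; C_T stays high because timing is less affected.")
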