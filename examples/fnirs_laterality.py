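"""From raw dual-wavelength fNIRS intensity to laterality indices.

The processing chain: optical density -> kurtosis-gated wavelet despiking
(k = 3.3) -> 0.01-0.08 Hz band-pass -> modified Beer-Lambert conversion ->
per-channel GLM beta -> lesion-orientation normalization -> per-region
laterality index LI = (mean beta contra - ipsi) / (contra + ipsi).
"""

import strokesyn as ss
from strokesyn.laterality import RegionMap

config = ss.SimulationConfig(n_patients=1, n_controls=0, seed=5,
                             trials_per_block=4)
profiles, truths = ss.generate_cohort(config)
patient = profiles[0]
truth = truths[patient.subject_id]
region_map = RegionMap.default()

print(f"patient severity {patient.severity:.2f}, lesion {patient.lesion_side}")
for arm in ("affected", "unaffected"):
    session = ss.simulate_fnirs_session(patient, arm, config, truth)
    beta, _ = ss.process_session(session)
    beta = ss.normalize_lesion_orientation(beta, patient.lesion_side, region_map)
    li = ss.laterality_index(beta, region_map, moving_arm=arm)
    truth_li = {r: (truth.betas[arm][r][0] - truth.betas[arm][r][1])
                / (truth.betas[arm][r][0] + truth.betas[arm][r][1])
                for r in ("PMC", "M1", "S1")}
    print(f"\n{arm} arm movement:")
    for region, value in li.as_dict().items():
        print(f"  LI_{region}: estimated {value:+.3f}  (planted {truth_li[region]:+.3f})")

print("\nEstimated LI tracks the planted interhemispheric asymmetry: the"
      "\naffected-arm block shows the weakest contralateral dominance, the"
      "\npattern the laterality index is designed to quantify.")
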