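"""Generate a synthetic stroke/control cohort and inspect its ground truth.

Each patient gets a latent severity in (0, 1) that drives every planted
quantity: synergy distortion, hemispheric activation asymmetry, MVC force
loss, and through them the true Fugl-Meyer upper-limb score (10-66).
"""

import strokesyn as ss

config = ss.SimulationConfig(n_patients=5, n_controls=3, seed=1)
profiles, truths = ss.generate_cohort(config)

print(f"{'subject':8s} {'group':8s} {'severity':>8s} {'FMul':>5s} "
      f"{'C_V_af':>7s} {'LI_PMC_un':>9s} {'F_r':>6s}")
for p in profiles:
    t = truths[p.subject_id]
    fmul = "-" if p.fmul_true is None else str(p.fmul_true)
    print(f"{p.subject_id:8s} {p.group:8s} {p.severity:8.2f} {fmul:>5s} "
          f"{t.implied['C_V_af']:7.3f} {t.implied['LI_PMC_un']:9.3f} "
          f"{t.implied['F_r']:6.3f}")

print("\nHigher severity -> lower closeness-to-healthy (C_V_af), lower")
print("unaffected-arm premotor laterality (LI_PMC_un), larger inter-arm")
print("force ratio (F_r), and a lower true FMul score.")
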