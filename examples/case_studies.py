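"""Run the three bundled supervision case studies.

Each case's observed population means (participation, compliance, strict
supervision) seed the replicator system as initial conditions, with the
case-reported exposure rate, medical risk and penalty intensity merged into
the reference parameter set.
"""

from trigame import CASE_NAMES, compare_cases, detect_convergence, load_case, simulate_case

cases = [load_case(name) for name in CASE_NAMES]
for case in cases:
    traj = simulate_case(case)
    final = traj.final_state()
    print(f"{case.name:>20}: start {case.observed_state().as_tuple()} "
          f"-> final ({final.delta:.3f}, {final.eta:.3f}, {final.zeta:.3f}) "
          f"[{detect_convergence(traj)}]")

result = compare_cases(cases)
r = result["pearson_r_delta_eta"]
print(f"\nPearson r between observed participation and observed compliance: {r:.3f}")
print("(descriptive only: three cases)" if result["descriptive_only"] else "")
print("All three programs satisfy the cooperative sufficient condition, so "
      "every simulated system evolves from its observed state to full "
      "cooperation; the correlation summarizes the observed means alone.")
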