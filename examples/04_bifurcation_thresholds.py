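"""All named bifurcation thresholds of the default scenario.

The two forward (transcritical) thresholds in the infection rate have
closed forms; the Hopf thresholds are located by bisection on the Matignon
margin of the interior equilibrium.  The final table compares every
computed threshold against its reference value: the first three are
anchored (they reproduce the reference closely), the last three are
diagnostic -- independent eigenvalue recomputation does not confirm the
reference fear-level and order thresholds under this parameter set.
"""

import fearsis as fs

p = fs.TABLE_DEFAULT
print(f"disease-invasion threshold  beta1* = {fs.forward_threshold_beta(p):.6f}  (R0 = 1)")
thr = fs.predator_invasion_threshold_beta(p)
print(f"predator-invasion threshold beta2* = {thr:.6f}  "
      f"(R0 = {fs.basic_reproduction_number(p.replace(beta=thr)):.4f})")
hopf = fs.find_hopf_threshold(p, "beta", (0.055, 0.08))
print(f"Hopf threshold              beta3* = {hopf.value:.6f}  "
      f"(margin residual {hopf.margin_residual:.1e})")

print("\nFull comparison table:")
print(fs.reference_threshold_comparison(p).to_string(index=False))
print(
    "\n'anchored' rows are regression anchors; the others are reported for "
    "diagnosis with their relative difference from the reference value."
)
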