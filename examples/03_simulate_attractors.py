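"""Fractional predictor-corrector simulation of two contrasting attractors.

Integrates the Caputo system with the Adams-Bashforth-Moulton scheme: at
beta = 0.06 the trajectory settles on the co-existence equilibrium; at
beta = 0.6 it approaches a limit cycle whose per-component amplitude the
cycle detector reports.
"""

import fearsis as fs

cfg = fs.SolverConfig(h=0.05, t_end=500.0)
for beta in (0.06, 0.6):
    p = fs.TABLE_DEFAULT.replace(beta=beta)
    y0 = fs.perturbed_equilibrium(p)  # equilibrium of interest + 5%
    traj = fs.simulate(p, y0, cfg)
    cls, amplitude = fs.detect_limit_cycle(traj)
    print(f"beta = {beta}: start {y0.round(3)} -> t={cfg.t_end:g}")
    print(f"  final state          : {traj.final_state.round(4)}")
    print(f"  attractor class      : {cls}")
    print(f"  relative amplitudes  : {amplitude.round(4)}  (S, I, P)")
print(
    "\n'equilibrium' means the post-transient oscillation amplitude is below "
    "1% of the population scale; the beta = 0.6 amplitudes quantify the "
    "predator-prey-disease cycle."
)
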