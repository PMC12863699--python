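"""Equilibria and basic reproduction number along the infection-rate axis.

For the default parameter set the number of feasible steady states grows
with the infection rate beta: below R0 = 1 only the disease-free point
(Lambda/mu, 0, 0) exists; past R0 = 1 the endemic predator-free point
appears; past the predator-invasion value R0 = Lambda/(Lambda - delta*sigma)
the interior co-existence point appears as well.
"""

import fearsis as fs

for beta in (0.04, 0.052, 0.06, 0.6):
    rep = fs.existence_report(fs.TABLE_DEFAULT.replace(beta=beta))
    print(f"beta = {beta}:  R0 = {rep.R0:.3f}")
    print(f"  disease-free point : {rep.pdpf.round(4)}")
    print(f"  predator-free point: {None if rep.pfp is None else rep.pfp.round(4)}")
    print(f"  co-existence point : {None if rep.cep is None else rep.cep.round(4)}")
print(
    "\nEach listed point is an exact steady state (residuals < 1e-8); 'None' "
    "means the point is infeasible at that infection rate."
)
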