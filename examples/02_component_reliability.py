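"""One component's failure probability two ways: closed form vs Monte Carlo.

The limit state is g = R - Q for cortical bone in tension, with a demand of
20 +/- 5 MPa against the 75 +/- 13.98 MPa yield strength. The closed-form
reliability index beta = (mu_R - mu_Q)/sqrt(sigma_R^2 + sigma_Q^2) gives
P_f = Phi(-beta); crude Monte Carlo counting of R < Q over a million paired
draws should land within a few binomial standard errors of it.
"""

from scipy.special import ndtr

import spinerel as sr

resistance = sr.YieldStrengthDistribution("cortical", "tension", 75.0, 13.98)
demand = sr.DemandDistribution("L3", "cortical", "tension", 20.0, 5.0)

beta = sr.beta_closed_form(75.0, 13.98, 20.0, 5.0)
pf_closed = float(ndtr(-beta))
print(f"closed form: beta = {beta:.4f}, P_f = {pf_closed:.3e}")

pf_mc, se = sr.pf_monte_carlo(sr.LimitState(resistance, demand), n=1_000_000, seed=42)
print(f"Monte Carlo (n=1e6, seed=42): P_f = {pf_mc:.3e} +/- {se:.1e}")
print(f"difference = {abs(pf_mc - pf_closed) / se:.2f} standard errors")

# the two loading modes of one component combine under the governing policy
pf = sr.combine_modes(pf_tension=pf_closed, pf_compression=2e-6, policy="governing")
print(f"governing mode pf = {pf:.3e} (the larger of the two modes)")
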