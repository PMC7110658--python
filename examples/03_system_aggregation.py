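"""Series/parallel aggregation, checked against exact enumeration.

Within a vertebra (or disc) the two tissues share the load path: both must
fail, a parallel pair, P_F = prod(P_Fi). A section fails if either its disc
or its vertebra fails, and the column is a series chain of sections:
P_F = 1 - prod(1 - P_Fi). For small systems the exact answer is also
available by enumerating every joint failure outcome; the product formulas
must match it.
"""

import spinerel as sr
from spinerel.system import Comp, Parallel, Series

# one section: (annulus, nucleus) disc pair and (cancellous, cortical)
# vertebra pair in series
pf_ann, pf_nuc, pf_canc, pf_cort = 0.01, 0.2, 0.05, 1e-4
pf_disc = sr.disc_pf(pf_ann, pf_nuc)
pf_vert = sr.vertebra_pf(pf_canc, pf_cort)
pf_sec = sr.sectional_pf(pf_disc, pf_vert)
print(f"disc pf     = {pf_disc:.3e} (both disc tissues must fail)")
print(f"vertebra pf = {pf_vert:.3e}")
print(f"section pf  = {pf_sec:.3e} (either component fails the section)")

tree = Series(
    Parallel(Comp(pf_ann), Comp(pf_nuc)),
    Parallel(Comp(pf_canc), Comp(pf_cort)),
)
exact = sr.enumeration_oracle(tree)
print(f"enumeration over 2^4 joint outcomes = {exact:.3e} "
      f"(matches to {abs(exact - pf_sec):.1e})")

# a 33-section chain of rare section failures: the log1p series form keeps
# precision where the naive product would cancel
pf_backbone = sr.series_pf([1e-6] * 33)
beta = sr.beta_from_pf(pf_backbone)
print(f"\n33 sections at pf 1e-6 each: backbone pf = {pf_backbone:.4e}, "
      f"beta = {beta:.3f}")
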