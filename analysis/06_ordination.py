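"""NMDS ordination of species distances with environmental vector fitting.

Species are the ordination points; per-species environmental values are
RAI-weighted means of site covariates, fitted as vectors with permutation
tests.
"""

from _shared import parse_args
from trapcomm.pipeline import stage_ordination

cfg, out = parse_args(__doc__)
info = stage_ordination(cfg, out)
for name, r in info.items():
    print(
        f"{name}: stress {r['stress']:.4f} (converged={r['converged']}); "
        f"strongest vector {r['envfit_top']}, elevation r2 = {r['envfit_r2_ele']:.4f}"
    )
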