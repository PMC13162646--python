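"""Mantel concordance among the three species-level distance matrices:
occurrence (Jaccard), relative activity (Bray-Curtis), and environmental
response (1-correlation on shrunk coefficients)."""

from _shared import parse_args
from trapcomm.pipeline import stage_concordance

cfg, out = parse_args(__doc__)
info = stage_concordance(cfg, out)
for pair, r in info.items():
    print(f"{pair}: r = {r['r']:.4f}, p = {r['p_value']:.4f}")
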