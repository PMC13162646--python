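"""Cluster species by shrinkage-adjusted environmental responses.

Posterior-mean coefficients are shrunk by tau^2/(tau^2 + sigma^2), column
standardized, converted to 1-correlation distances, Ward-clustered with
silhouette k-selection, and tested with PERMANOVA.
"""

from _shared import parse_args
from trapcomm.pipeline import stage_responses

cfg, out = parse_args(__doc__)
info = stage_responses(cfg, out)
pv = info["permanova"]
print(
    f"selected k = {info['selected_k']} (mean silhouette {info['mean_silhouette']:.4f}), "
    f"cluster sizes {info['cluster_sizes']}"
)
print(f"PERMANOVA: r2 = {pv['r2']:.4f}, F = {pv['F']:.4f}, p = {pv['p_value']:.4f}")
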