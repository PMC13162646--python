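"""Species-similarity clustering and the Delta permutation test.

Builds Jaccard (occurrence) and Bray-Curtis (RAI) distances among species,
screens hierarchical clusterings over k = 2-16 by mean silhouette, and tests
each solution's between-vs-within differentiation (Delta) against
group-size-preserving label permutations.
"""

from _shared import parse_args
from trapcomm.pipeline import stage_structure

cfg, out = parse_args(__doc__)
info = stage_structure(cfg, out)
for name, r in info.items():
    print(
        f"{name}: best k = {r['best_k']} (mean silhouette {r['best_silhouette']:.4f}), "
        f"Delta p at best k = {r['delta_p_at_best_k']:.4f}"
    )
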