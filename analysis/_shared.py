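"""Shared configuration for the numbered analysis drivers.

Every driver works in the same output directory (default ``results/run``),
so each stage picks up the artifacts the previous one wrote. Permutation
counts default to a desk-scale 999; pass --permutations 9999 to match the
full design.
"""

import argparse
import logging
import sys
from pathlib import Path

from trapcomm.pipeline import PipelineConfig


def parse_args(description):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--out", default="results/run", help="shared working directory")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--permutations", type=int, default=999)
    ap.add_argument("--config", default=None, help="optional YAML overriding defaults")
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, stream=sys.stderr, format="%(message)s")
    cfg = PipelineConfig.from_yaml(args.config) if args.config else PipelineConfig()
    cfg.seed = args.seed
    cfg.n_permutations = args.permutations
    return cfg, Path(args.out)
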