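"""Shared settings for the analysis drivers.

One synthetic depth-stratified survey is generated once (01) and re-used
by every later step. Sizes are the package's analysis defaults: 24 sites x
3 depth layers along the precipitation gradient, 600 taxa, 2000 reads per
sample after rarefaction.
"""

from pathlib import Path

SEED = 1
DATA_DIR = Path("results/data")
OUT_DIR = Path("results")

SIM = dict(n_taxa=600, n_sites=24, n_layers=3, reads_per_sample=2000,
           regime="mixed", migration=0.05, seed=SEED)

N_NULL = 299
N_PERM = 499
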