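#!/usr/bin/env python
"""Relaxed-constraint analysis on the fixed paralog topology.

Computes per-branch substitution numbers for the nonsynonymous, synonymous
and intronic site classes by OLS on the reference topology, and Z-tests of
b_nonsyn - b_neutral per branch (neutral = mean of synonymous and intronic;
SE from 1000 column-bootstrap resamples).  Under the flagship scenario all
classes evolve neutrally (omega = 1), so branches should sit near
ratio ~ 1 with only nominal-rate rejections.
"""

import numpy as np

from _common import FLAGSHIP, SEED, ensure_flagship
from paraconv.constraint import branch_constraint_test
from paraconv.experiments import paralog_topology

cfg, aln, regions = ensure_flagship()
classes = cfg.site_classes()
part = {
    "nonsynonymous": np.flatnonzero(classes == 2).tolist(),
    "synonymous": np.flatnonzero(classes == 1).tolist(),
    "intronic": np.flatnonzero(classes == 0).tolist(),
}
topo = paralog_topology(cfg.species_tree, cfg.loci)
table = branch_constraint_test(aln, part, topo, n_boot=1000, seed=SEED)
out = FLAGSHIP / "branch_rates.tsv"
table.to_csv(out, sep="\t", float_format="%.5g")

sig = table.index[table["p"] < 0.02].tolist()
print(f"{len(table)} branches tested; ratio (nonsyn/neutral) "
      f"median {table['ratio'].median():.2f}")
print(f"branches significant at p < 0.02: {sig or 'none'} "
      "(all classes simulated at the neutral rate)")
print(f"table written to {out}")
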