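#!/usr/bin/env python
"""Generate the synthetic study world: a 200-species Yule phylogeny, 18
traits in 8 correlation blocks with lambda = 0.6 phylogenetic signal, 10
spatially autocorrelated environmental covariates, 2000 observations, and
30% missingness. Writes tree.nwk, traits_observed.csv (with gaps) and
traits_truth.csv (complete, for scoring) under results/."""

from common import CONFIG

from treetraits.pipeline import run_stage

if __name__ == "__main__":
    out = run_stage("simulate", CONFIG)
    print(f"simulated {out['n_obs']} observations -> {CONFIG.outdir}/")
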