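#!/usr/bin/env python
"""Species-weighted PCA of the completed trait matrix (weights
1/n_obs(species) so every species counts equally). Reports the variance
profile and how many axes cover 75% of trait variation. Writes loadings,
scores, and variance tables."""

from common import CONFIG

from treetraits.pipeline import run_stage

if __name__ == "__main__":
    out = run_stage("axes", CONFIG)
    shares = out["variance_explained"]
    print("variance explained per axis: "
          + ", ".join(f"{100 * s:.1f}%" for s in shares[:8]) + " ...")
    print(f"{out['n_axes_for_threshold']} axes reach "
          f"{100 * out['threshold']:.0f}% of trait variation")
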