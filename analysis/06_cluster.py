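#!/usr/bin/env python
"""Group the traits into functional clusters: species-weighted rank
correlations, average-linkage clustering on 1 - |rho| with the silhouette
choosing the cluster count, and PIC correlations as the phylogeny-corrected
cross-check. Writes both correlation matrices, cluster labels, and the
dendrogram in Newick."""

from common import CONFIG

from treetraits.pipeline import run_stage

if __name__ == "__main__":
    out = run_stage("cluster", CONFIG)
    print(f"silhouette-selected number of trait clusters: {out['k_opt']}")
    by_cluster = {}
    for trait, label in out["labels"].items():
        by_cluster.setdefault(label, []).append(trait)
    for label in sorted(by_cluster):
        print(f"  cluster {label}: {', '.join(by_cluster[label])}")
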