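#!/usr/bin/env python
"""Score every trait model with genus-buffered (250 km) leave-one-species-out
cross-validation, alongside a plain random-split CV for contrast. The
buffered VEcv is the conservative headline accuracy. Writes cv.json and the
pooled out-of-fit prediction dump."""

from common import CONFIG

from treetraits.pipeline import run_stage

if __name__ == "__main__":
    out = run_stage("validate", CONFIG)
    print(f"mean buffered VEcv across traits: {out['mean_vecv_buffered']:.3f}")
    for trait, r in sorted(out["per_trait"].items()):
        print(f"  {trait:22s} buffered {r['vecv_buffered']:+.3f}  "
              f"random-split {r['vecv_random_split']:+.3f}")
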