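"""Shared configuration for the numbered analysis drivers.

One master seed flows into every stage; all tables land under results/.
"""

from treetraits.pipeline import PipelineConfig

CONFIG = PipelineConfig(outdir="results", master_seed=1)
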