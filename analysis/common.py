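"""Shared configuration for the numbered analysis scripts.

All scripts write into ``results/`` with one global seed, so the whole
analysis reruns byte-identically with ``for s in analysis/[0-9]*.py; do
python "$s"; done``.
"""

from laccscreen.pipeline import PipelineConfig

SEED = 1
OUT_DIR = "results/run"


def config() -> PipelineConfig:
    return PipelineConfig(out_dir=OUT_DIR, seed=SEED)
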