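"""Relate enzyme activity to transcript level in top producers.

Relative laccase-gene expression per strain by the comparative Ct method
(reference gene UBC6, calibrator BY4741), then activity per unit mRNA to ask
whether production differences are transcriptional.
"""

from common import config

from laccscreen.pipeline import PipelineRun

run = PipelineRun(config())
run.qpcr()
run.write_report()
q = run.report["stages"]["qpcr"]
print(f"relative expression for {q['n_strains']} strains -> {run.out / 'qpcr_levels.tsv'}")
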