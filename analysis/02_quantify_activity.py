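"""Quantify laccase activity from the plate kinetic traces.

For each well, the linear phase of the A420 progress curve is isolated by
exhaustive window search (R² >= 0.999, >= 10 points) and the slope converted
to enzyme Units via Beer-Lambert (epsilon = 36,000 1/(M cm), 200 µL wells).
"""

from common import config

from laccscreen.pipeline import PipelineRun

run = PipelineRun(config())
run.quantify()
run.write_report()
q = run.report["stages"]["quantify"]
print(
    f"quantified {q['n_wells']} wells: {q['n_qc_ok']} ok, {q['n_flat']} flat, "
    f"{q['n_no_linear_window']} without a linear window -> {run.out / 'activity.tsv'}"
)
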