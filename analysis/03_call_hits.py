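"""Call producer hits and confirm them in the dual-enzyme secondary screen.

Primary hits are strains above median + 3 MAD of the library activity.
Candidates are then confirmed per enzyme by one-sided Welch t-tests against
the reference strain, and the two enzymes' confirmations are combined with a
Pearson correlation of the mean activities.
"""

from common import config

from laccscreen.pipeline import PipelineRun

run = PipelineRun(config())
run.screen()
run.write_report()
s = run.report["stages"]["screen"]
print(
    f"primary hits: {s['n_primary_hits']} (threshold {s['threshold_U']:.3e} U); "
    f"confirmed: {s['n_secondary_a']} enzyme A, {s['n_secondary_b']} enzyme B, "
    f"{s['n_both']} both, {s['n_union']} total; "
    f"inter-enzyme Pearson r = {s['pearson_r']:.3f} (p = {s['pearson_p']:.3f})"
)
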