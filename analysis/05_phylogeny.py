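"""Build the strain tree from the distance matrix.

Neighbour joining with deterministic tie-breaking, rooted at the midpoint of
the outgroup's pendant edge, written as Newick.
"""

from common import config

from laccscreen.pipeline import PipelineRun

run = PipelineRun(config())
run.tree()
run.write_report()
t = run.report["stages"]["tree"]
print(
    f"NJ tree over {t['n_taxa']} taxa rooted at {t['outgroup']} "
    f"(total branch length {t['total_branch_length']:.3f}) -> {run.out / 'tree.nwk'}"
)
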