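"""Generate the synthetic study inputs.

Produces plate-reader kinetic tables for a ~600-strain primary screen (plus
one reference well per plate), dual-enzyme secondary replicate tables, a
pan-genome presence/absence matrix with planted enriched/depleted/compensated
ORFs, additive strain distances from a known tree, DIA-style proteome
intensities, and a qPCR Ct table — each with its planted ground truth saved
alongside, so the downstream scripts' recoveries can be judged.
"""

from common import config

from laccscreen.pipeline import PipelineRun

run = PipelineRun(config())
run.simulate()
run.write_report()
sim = run.report["stages"]["simulate"]
print(
    f"simulated {sim['n_plates']} plates ({sim['n_strains']} strains, "
    f"{sim['n_planted_hits']} planted hits), {sim['n_orfs']} ORFs, "
    f"{sim['n_taxa']} taxa, {sim['n_proteins']} proteins -> {run.out}"
)
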