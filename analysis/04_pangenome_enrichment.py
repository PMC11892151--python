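"""Associate confirmed producer strains with pan-genome ORF content.

ORFs varying between the confirmed hits and the reference genome are tested
for enrichment/depletion among hits with a two-sided Fisher exact test;
depleted ORFs with an enriched close homolog (identity >= 0.73) are
reclassified as compensated.
"""

from common import config

from laccscreen.pipeline import PipelineRun

run = PipelineRun(config())
run.enrich()
run.write_report()
e = run.report["stages"]["enrich"]
print(
    f"{e['n_retained_orfs']} variable ORFs tested against {e['n_hit_strains']} "
    f"hit strains: {e['n_enriched']} enriched, {e['n_compensated']} compensated, "
    f"{e['n_depleted']} depleted -> {run.out / 'enrichment.tsv'}"
)
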