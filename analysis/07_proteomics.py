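"""Proteome response of producer strains.

Replicate QC (pairwise R² >= 0.85), median-scaling normalization, left-
censored MinProb-style imputation, per-strain Welch t-tests against the
reference (BH q-values, |fold change| >= 2), and a recurrence filter for
proteins affected in at least half of the producer strains.  Also reports the
median technical and biological CVs of the deeply replicated reference.
"""

from common import config

from laccscreen.pipeline import PipelineRun

run = PipelineRun(config())
run.proteomics()
run.write_report()
p = run.report["stages"]["proteomics"]
print(
    f"{p['n_samples_in']} samples ({p['n_samples_excluded']} excluded by QC); "
    f"median CV {p['median_cv_technical']:.1%} technical / "
    f"{p['median_cv_biological']:.1%} biological; "
    f"{p['n_recurrent_up']} recurrently up, {p['n_recurrent_down']} down "
    f"across {p['n_strains_tested']} strains -> {run.out / 'recurrent.tsv'}"
)
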