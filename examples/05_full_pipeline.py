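"""Run the whole pipeline end to end on a simulated cohort and print the
run report.

Equivalent shell usage:

    coievol run --config run.json
    coievol report <outdir>

where run.json holds the same RunConfig fields used below.
"""

from coievol.pipeline import RunConfig, report, run_pipeline
from coievol.simulate import BinCountDistribution, SimConfig

cfg = RunConfig(
    outdir="scratch/example_run",
    seed=5,
    simulate=SimConfig(
        n_families=20,
        bins_per_family=BinCountDistribution(4, 6, 0.5),
        indel_rate=0.3,
        seed=5,
    ),
)
manifest = run_pipeline(cfg)
print(report(cfg.outdir))
# The report covers attrition, outgroup substitution means, the family
# median-omega distribution, the pooled HD:DD omega contrast, the indel
# summary and the trait ANOVA -- one section per pipeline stage.
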