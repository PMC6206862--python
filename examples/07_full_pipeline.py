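"""The whole flow in one call: simulate -> analyze -> report.

Writes every stage's tables into a result bundle directory and prints the
human-readable summary. Re-running with the same config reproduces the
bundle byte for byte.
"""

import lxthet as lx
from lxthet.simulate import DEFAULT_RESID_SD

cfg = lx.PipelineConfig(
    sim=lx.demo_config(seed=7, qtl_spec=[
        lx.QTL(0, "FL", a=0.6 * DEFAULT_RESID_SD["FL"], d=0.0),
        lx.QTL(5, "BW", a=0.0, d=0.6 * DEFAULT_RESID_SD["BW"])]),
    outdir="scratch/example_bundle",
    seed=7,
    ld_shuffles=500,
    structure_kmin=1, structure_kmax=4, structure_runs=2,
    structure_burnin=100, structure_reps=150,
)
bundle = lx.run_pipeline(cfg)
print(lx.report(bundle))
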