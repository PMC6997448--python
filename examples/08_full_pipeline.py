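"""Run the complete pipeline on a synthetic study and read the manifest.

select/split -> discover -> label+annotate -> cluster -> tfmatch ->
regulate, with every output written to a run directory and checksummed in
a manifest; reruns with the same seed are byte-identical.
"""

import json
from pathlib import Path

from methmotif import PipelineConfig, SimulationConfig, gen_fixture, run_pipeline
from methmotif.io import write_fixture_dir

workdir = Path("scratch_example_pipeline")
fixdir = workdir / "inputs"
write_fixture_dir(gen_fixture(SimulationConfig(seed=42)), fixdir)

manifest = run_pipeline(
    PipelineConfig(input_dir=str(fixdir), out_dir=str(workdir / "run"),
                   n_shuffles=500, seed=42)
)
for stage in manifest["stages"]:
    print(f"  {stage['name']:9s} {stage['counts']}")
print(f"outputs: {len(manifest['outputs'])} files, e.g. "
      f"{sorted(manifest['outputs'])[:3]}")

rerun = run_pipeline(
    PipelineConfig(input_dir=str(fixdir), out_dir=str(workdir / "rerun"),
                   n_shuffles=500, seed=42)
)
print("rerun byte-identical:", rerun["outputs"] == manifest["outputs"])
# The per-stage counts audit every number in the result tables; identical
# checksums on rerun demonstrate the pipeline is a pure function of its
# inputs and seed.
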