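"""Generate a complete synthetic study with known ground truth.

Builds CpG flanking sequences with a planted AP-1-like 7-mer, a beta-value
matrix with a 1% high-variance CpG group, hyper/hypo iDMC labels, a toy TF
database with methylation-affinity classes, and tumor/normal expression
matrices — then writes everything to disk in the pipeline's input formats.
"""

from pathlib import Path

from methmotif import SimulationConfig, gen_fixture
from methmotif.io import write_fixture_dir

cfg = SimulationConfig(seed=42)
fixture = gen_fixture(cfg)
outdir = Path("scratch_example_fixture")
write_fixture_dir(fixture, outdir)

truth = fixture["truth"]
word, occ = next(iter(truth.planted_occurrences.items()))
print(f"CpGs simulated:            {cfg.n_cpgs} (42-nt flanks, central CG)")
print(f"planted motif:             {word} in {len(occ)} sequences")
print(f"high-variance CpGs:        {len(truth.true_unstable)}")
print(f"iDMC labels:               {cfg.n_hyper} hyper + {cfg.n_hypo} hypo")
print(f"TF database:               {cfg.tf_db_size} PWMs, "
      f"{len(truth.true_de_genes)} genes with a planted expression shift")
print(f"files written to:          {outdir}/")
# The planted occurrences and variance groups are the ground truth every
# downstream stage is measured against.
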