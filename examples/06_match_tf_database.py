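"""Match a discovered motif against a TF PWM database.

Tomtom-style ungapped column alignment: mean per-column similarity
(1 - Euclidean distance / sqrt(2)), empirical p from a seeded column
shuffle, E = p x database size; matches need >= 5 aligned columns and
E < 10.  The database contains one PWM built from the motif's own
consensus, which should rank first.
"""

from methmotif import SimulationConfig, gen_regulation_fixture, scan_database
from methmotif.motif import Motif

cfg = SimulationConfig(tf_db_size=20, seed=19)
tf_db, *_ = gen_regulation_fixture(cfg, consensi=["TGACGTCA"])

motif = Motif.from_consensus("TGACGTCA")
matches = scan_database(motif, tf_db, min_overlap=5, e_max=10.0,
                        n_shuffles=1000, seed=19)
print(f"query {motif.consensus} vs {len(tf_db)} TF PWMs "
      f"-> {len(matches)} matches pass overlap >= 5 and E < 10:")
for m in matches[:5]:
    print(f"  {m.tf.tf_name} ({m.tf.methyl_class:11s}) "
          f"score={m.score:.3f} overlap={m.overlap} strand={m.strand} "
          f"E={m.e:.3g}")
# TF001 carries the planted consensus, so it tops the ranking with a score
# near 1; the remaining matches are chance similarities under the lenient
# E < 10 screen.
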