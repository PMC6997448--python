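"""Discriminative motif discovery on a planted fixture.

Plants the AP-1 heptamer TGACTCA in 30% of a 500-CpG subset (1% elsewhere)
and asks the discovery procedure to find it against the 5000-sequence
background: exact-word seeding, Fisher scoring, IUPAC hill climbing and
E-value filtering at 0.05.
"""

from methmotif import discover_motifs, gen_flank_sequences, plant_motif

records = gen_flank_sequences(5000, flank_len=20, seed=1)
subset = {r.cpg_id for r in records[:500]}
records, truth = plant_motif(records, "TGACTCA", subset, 0.30, 0.01, seed=1)

positives = {r.cpg_id: r.sequence for r in records[:500]}
background = {r.cpg_id: r.sequence for r in records}
results = discover_motifs(positives, background, min_len=3, max_len=8,
                          e_threshold=0.05, max_rounds=2)

planted = {c for c, _ in truth.planted_occurrences["TGACTCA"]} & set(positives)
for r in results:
    jac = len(r.matched_pos_ids & planted) / len(r.matched_pos_ids | planted)
    print(f"round {r.iteration}: {r.consensus:10s} "
          f"{r.pos_with}/{r.pos_total} vs {r.neg_with}/{r.neg_total}  "
          f"E={r.e_value:.2e}  Jaccard vs planted={jac:.2f}")
# The round-1 consensus is an IUPAC generalization of the planted word; a
# Jaccard near 1 means its matches are essentially the planted occurrences.
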