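"""Evaluate a trained potential on perturbation decoy sets.

Prints the 13 per-set performance measures: five native-recognition
measures (rank of the native, RMSD of the best-scoring structure,
Z-score of the native, score/RMSD correlation, fraction enrichment) and
eight decoy-discrimination measures computed with the native excluded.
"""

from loco import (LoCoParams, accumulate_counts, compile_potential,
                  evaluate_decoy_set, make_decoys, make_training_corpus,
                  metrics_table)

corpus = make_training_corpus(150, length_range=(30, 70), seed=3)
db = compile_potential(accumulate_counts(corpus, LoCoParams()))

natives = make_training_corpus(4, length_range=(30, 50), seed=11)
per_set = {}
for k, nat in enumerate(natives):
    dset = make_decoys(nat, n=30, sigma=12.0, seed=100 + k,
                       name=f"set{k}")
    per_set[dset.name] = evaluate_decoy_set(db, dset)

df = metrics_table(per_set)
print(df.round(3).to_string())
# rank_nat = 1 means the native out-scores all 30 decoys; r_b1 is the
# RMSD rank (among decoys only) of the decoy the potential likes best,
# and log_p_b1 = log10(r_b1 / 30) is the chance of doing that well by
# picking at random.
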