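"""Recover a planted informative feature with the GA subset search.

The synthetic positives carry a residue planted at a fixed position;
negatives carry the same residue at a random other position, so the two
classes have matching compositions and only a position-aware encoder
(the sparse profile, F4) can see the signal.  The GA should select F4.
"""

import numpy as np

from immunoga import GAConfig, SignalSpec, default_encoder_specs, generate, optimize

ds = generate(SignalSpec(n_pos=75, n_neg=75, mechanism="positional-motif",
                         effect_size=0.9, seed=7))
pool = default_encoder_specs([2, 4, 8, 9, 15, 16])  # F4 + five blind encoders
cfg = GAConfig(population_size=16, max_generations=12, internal_folds=5, seed=3)

result = optimize(ds, cfg, specs=pool, n_trees=40)

print("candidate pool:", [s.code for s in pool])
print("best subset:   ", [s.code for s, b in zip(pool, result.best.bits) if b])
print(f"best fitness (internal 5-fold CV AUC): {result.best.fitness:.3f}")
print(f"distinct subsets evaluated: {result.evaluations} "
      f"(of {2 ** len(pool) - 1} possible)")
print("best-fitness trajectory:",
      [round(h['best'], 3) for h in result.history[:6]], "...")
print("\nF4 in the best subset means the search recovered the planted "
      "positional signal; fitness near the single-feature ceiling (~0.9 "
      "at this effect size) says little was gained by adding noise features.")
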