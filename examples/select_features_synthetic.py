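"""Select features on a planted-signal benchmark and compare to the oracle.

Generates a 300-sample, 10-feature dataset where only the first 3 columns
carry class signal, runs chaotic antlion feature selection, and checks the
result against exhaustive search over all 1023 nonempty masks.
"""

import numpy as np

from calofs import SynthSpec, exhaustive_oracle, optimize_subset, synthetic_split
from calofs.objective import holdout_accuracy

spec = SynthSpec(n_samples=300, n_informative=3, n_noise=7, delta=3.0, seed=0)
data, informative = synthetic_split(spec)
print(f"dataset: {spec.n_samples} samples, {data.n_features} features, "
      f"informative columns {[int(i) for i in informative]}")

oracle_mask, oracle_fit = exhaustive_oracle(data)
print(f"oracle (exhaustive) mask: {''.join(map(str, oracle_mask))} "
      f"fitness {oracle_fit:.4f}")

hits = 0
for seed in range(5):
    mask, fit, result = optimize_subset(data, "calo-tent", seed=seed)
    pred, acc = holdout_accuracy(mask, data)
    matched = "== oracle" if abs(fit - oracle_fit) < 1e-12 else f"gap {fit - oracle_fit:+.4f}"
    hits += abs(fit - oracle_fit) < 1e-12
    print(f"calo-tent seed {seed}:  mask {''.join(map(str, mask))} "
          f"fitness {fit:.4f} ({matched}), test accuracy {acc:.3f}")
print(f"matched the exhaustive optimum in {hits}/5 runs "
      f"({result.n_evaluations} fitness evaluations per run vs 1023 masks)")
print()
print("Reading: the fitness 0.99*(1-P) + 0.01*(N_f/N_t) is minimized; a")
print("fitness of k/1000 with perfect validation accuracy means k features")
print("kept. Runs matching the oracle found the global optimum of the")
print("wrapper objective without enumerating all subsets; small gaps mean")
print("one redundant feature too many was retained.")
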