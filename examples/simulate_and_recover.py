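"""Simulate every natural phenotype and recover its status leaf.

Runs the noise-free recovery experiment (10 individuals per phenotype at
the full monitoring tier) and prints the confusion matrix: each row is the
intended leaf of a simulated phenotype, each column the leaf the classifier
assigned.  A purely diagonal matrix means every decision path reproduces
its intended status exactly; then a second run with realistic missingness
shows how conservative (B1) and apparently-anovulatory (E) calls appear
when scheduled tests are skipped.
"""

from mhm.simulate import NoiseSpec, recovery_experiment

clean = recovery_experiment(n_per_phenotype=10, noise=NoiseSpec.none(), cap=3, seed=7)
print("noise-free, tier 3:")
print(clean.confusion)
print("recovery:", clean.recovery_rate)

noisy = recovery_experiment(
    n_per_phenotype=10, noise=NoiseSpec(miss_rate=0.3), cap=3, seed=7
)
print("\n30% missed observations, tier 3:")
print(noisy.confusion)
print("recovery:", noisy.recovery_rate)
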