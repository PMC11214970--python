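"""Parameter recovery on synthetic data, and the cost of a wrong TEF.

With the estimator matched to the generator (same baselines, same guild
TEFs) the species-mean TP is unbiased and its error shrinks as 1/√n. With
a mismatched TEF the bias is deterministic: estimating a herbivore
generated at 4.3‰/step with the conventional 3.4‰ inflates every step by
the ratio 4.3/3.4.
"""

from trophicpos import TEFScheme, default_config, recovery_report

config = default_config(seed=1)

print("matched estimator (guild TEFs):")
report = recovery_report(config)
print(report[["species", "true_tp", "estimated_tp", "bias", "se", "covered_2se"]]
      .round(3).to_string(index=False))

print("\nmismatched estimator (conventional 3.4‰ for every guild):")
mismatched = recovery_report(config, scheme=TEFScheme.constant(3.4))
merged = report[["species", "true_tp"]].assign(bias=mismatched["bias"])
print(merged.round(3).to_string(index=False))

print("\nUnder the matched scheme biases are noise-level and the ±2 SE interval "
      "covers the truth; under the mismatch, herbivores (generated at 4.3‰/step) "
      "are biased high by ≈(4.3/3.4 − 1)·(TP − 1) and carnivores (2.5‰/step) low.")
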