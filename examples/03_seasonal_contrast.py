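"""Winter vs. summer TP with season-matched baselines and Kruskal–Wallis tests.

Baselines themselves shift between seasons (winter macroalgae sit 1.7‰
below summer). Consumer tissue integrates diet over weeks to months, so
its δ¹⁵N lags the baseline shift; here that lag is emulated by generating
consumers against the pooled (season-averaged) baseline while estimating
against the season-specific ones. The same tissue value then reads as more
enrichment steps above the lighter winter baseline — a higher winter TP —
which is an artefact of baseline choice, not a change in diet. Species
need at least three individuals per season to be tested; with ten or fewer
individuals in total the test is exact (all group assignments enumerated).
"""

from dataclasses import replace

from trophicpos import (
    TEFScheme,
    default_config,
    packaged_baseline,
    seasonal_contrast,
    simulate_bulk,
)

config = default_config(seed=1)
# slow tissue turnover: both seasons' tissue reflects the pooled baseline
pooled = packaged_baseline("macroalgae", "pooled")
config.baselines = {
    "winter": replace(pooled, season="winter"),
    "summer": replace(pooled, season="summer"),
}
samples = simulate_bulk(config)

contrasts = seasonal_contrast(
    samples,
    packaged_baseline("macroalgae", "winter"),
    packaged_baseline("macroalgae", "summer"),
    TEFScheme.constant(),
)

print(f"{'species':28s}{'summer':>8s}{'winter':>8s}{'Δ(w−s)':>8s}{'p':>8s}")
for c in contrasts:
    print(f"{c.species:28s}{c.tp_summer:8.2f}{c.tp_winter:8.2f}"
          f"{c.difference:8.2f}{c.p_value:8.3f}")

print("\nΔ(w−s) > 0 for every species: identical tissue δ¹⁵N sits "
      f"{(11.9 - 10.2):.1f}‰/3.4‰ = 0.5 TP higher against the winter baseline. "
      "The exact Kruskal–Wallis p at 5 vs 5 resolves differences this size.")
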