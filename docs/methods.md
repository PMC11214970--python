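# Methods

## The bulk-isotope TP model

Consumer trophic position from bulk-tissue δ¹⁵N is the additive model
`TP = (δ¹⁵N_consumer − δ¹⁵N_base)/ΔN + TP_base`. Its assumptions: the
baseline organism integrates the same nitrogen sources as the consumer's
food chain; enrichment per trophic step is constant at ΔN; and consumer
tissue is at isotopic equilibrium with diet. TP is affine in consumer
δ¹⁵N, which yields two exact identities the package exposes and tests:

- **Baseline offset.** For a fixed ΔN, two baselines shift every
  consumer's TP by the same constant
  `(δ_b2 − δ_b1)/ΔN + (TP_b1 − TP_b2)`. With the packaged pooled
  baselines this is exactly 1.0 TP between the macroalgae (11.6‰) and
  phytoplankton (15.0‰) baselines at ΔN = 3.4‰, and ≈0.47 TP between the
  two primary-consumer baselines.
- **TEF rescaling.** The baseline cancels when switching ΔN:
  `TP' = TP_base + (TP − TP_base)·ΔN/ΔN'`. This converts any
  conventional-TEF estimate to a guild TEF without re-touching the raw
  data, and is how the acceptance script reproduces published
  guild-TEF table cells from the conventional ones.

TEF schemes are either constant (default 3.4‰) or guild-mapped
(filter-feeder 2.2, zooplanktivore 3.0, herbivore–detritivore 4.3,
carnivore 2.5, omnivore 3.4 ‰). The guild scheme has no fallback: an
unknown guild is an error, because a silently wrong ΔN scales the whole
TP excess. Omnivores keep 3.4‰ through the map itself, not special-case
code.

Estimates below TP 2 (for consumers) or TP 1 are returned unclipped and
flagged by `compare.flag_implausible`: sub-2 values are a diagnostic of a
mismatched baseline/TEF, and clamping would hide exactly the signal the
comparison framework exists to expose.

Species summaries compute TP per individual and then take the mean and
sample SD (n−1; SD = 0 for n = 1). Under a common TEF this is identical
to transforming the mean and SD of δ¹⁵N (the model is affine), a
consistency the tests assert.

## Baselines

`estimate_baseline` is a plain arithmetic mean over the selected samples
(no outlier trimming), with deliberate multi-species pooling behind an
explicit flag. `source_aa_baseline` averages Phe and Gly per individual
and then averages individuals; for balanced data this equals averaging
the two acids' grand means, and the per-individual convention is used
because individuals, not acids, are the sampling unit. The packaged
baseline table carries values rounded to one decimal; consequently only
same-baseline arithmetic reproduces published table cells exactly —
cross-baseline reconstructions disagree by ~0.02 TP, which is why the
acceptance checks are framed as offsets and rescalings rather than
absolute reconstructions.

## Amino-acid TP

`tp_csia` averages the trophic set and the source set first and then
differences (rather than averaging per-acid TPs); the set means are the
quantity the calibration constants were fitted to. Three constant sets
are packaged; they disagree systematically, and the crossover difference
below which their ordering flips, `(β₁Δ₂ − β₂Δ₁)/(Δ₂ − Δ₁) = −1.16‰`
for the two Glu/Phe sets, is asserted as a property. Replicate
(measurement) SDs propagate to a per-individual uncertainty via
independent-error propagation through the set means and the 1/Δ slope;
they never enter species SDs, which are across individuals.

## Seasonal contrasts

`seasonal_contrast` computes per-individual TPs against each season's own
baseline and tests winter vs. summer with a two-group Kruskal–Wallis.
Inclusion requires ≥3 individuals per season. The p-value is exact —
full enumeration of all C(n, n₁) group assignments of the pooled values,
tie-corrected H, `p = #{H ≥ H_obs}/total` — when total n ≤ 10, and the χ²
(1 df, tie-corrected, via scipy) approximation otherwise; both variants
are selectable, since reports rarely state which was used. The sign
convention is winter − summer, so a lighter winter baseline with
season-invariant consumer tissue yields positive differences. Because TP
is affine in δ¹⁵N, the test on TPs computed against a shared baseline has
exactly the p-value of the test on raw δ¹⁵N (rank invariance) — asserted
in the tests. No multiple-testing correction is applied by default;
Benjamini–Hochberg (statsmodels) is available behind a flag.

Degenerate inputs: all-identical pooled values give H = 0, p = 1 in both
variants (the tie-correction denominator vanishes; scipy refuses such
input, so the package short-circuits it).

## Synthetic data

The generator runs the estimation models in reverse. Bulk:
`δ¹⁵N = baseline(season) + (TP_true − TP_base)·ΔN(guild) + N(0, σ)`.
Amino acids: source acids at the season's source-AA baseline (optionally
drifting `0.4‰ × (TP_true − 1)` to emulate the slight per-level Phe
enrichment; default off), trophic acids β + Δ·(TP_true − 1) above them,
each acid with independent Gaussian noise. Noise-free generation is
inverted exactly by both estimators — the anchor invariant of the test
suite.

Defaults (the study conditions): season-specific macroalgae baselines
(winter 10.2‰, summer 11.9‰) for bulk, source-AA baselines (12.8‰,
10.5‰) for amino acids, the guild TEF map above, bulk individual noise
σ = 0.3‰ (between the ~0.15‰ analytical precision and the 0.2–1.6‰
ecological spread implied by observed species SDs), per-AA noise 0.5‰
(the order of triplicate replicate dispersion, whose per-acid bound is
1.75‰). The default community spans the five guilds with true TPs
2.2–3.9 and 5 individuals per season per species. Random streams are
split per species × season × block (CRC-32 of the labels feeding a
PCG64 seed sequence), so editing one species never perturbs another's
draws. Noise distributions are Gaussian by assumption; real data may be
skewed or have diet-driven individual heterogeneity, so passing recovery
tests demonstrates correctness of the estimators under the model, not
robustness to model violations.

`recovery_report` estimates with the generator's own season-matched
baselines and a chosen TEF scheme; under the matched scheme bias is
zero in expectation with SE σ/(ΔN√n), and under a mismatched scheme the
bias is the closed form `(ΔN_true/ΔN_est − 1)·(TP_true − TP_base)`, both
asserted in tests.

## Numerical and presentation choices

- Table output rounds half-up (ties away from zero) to two decimals for
  TPs, one for offsets — matching how isotope tables are conventionally
  printed; Python's default bankers' rounding would differ on exact
  halves.
- Method labels compose as `TP_<baseline-token>` plus `-va` for the
  guild ("variable") scheme; amino-acid methods are `TP_Glu-Phe(1)`,
  `TP_Glu-Phe(2)`, `TP_Tr-Sr`. Min/max ties in `method_range` break by a
  fixed canonical label order.
- CSVs are comma-separated UTF-8 with `.` decimals and a required
  header; loaders normalise season/guild labels case-insensitively with
  a configurable synonym map, reject rows with missing/unparseable δ¹⁵N
  individually (with line numbers) and fail fast on schema problems.

## Validation problem sizes

The statistical acceptance checks run at sizes chosen to make their
expected behaviour unambiguous: recovery at n = 30 per species with
σ = 0.3‰ (SE ≈ 0.016 TP, so |bias| < 0.1 is a ~6σ band); exact
Kruskal–Wallis cross-checked against brute-force enumeration at 3 vs 3
(20 assignments); type-I error of the seasonal test over 500 null
replicates at 10 individuals per season — 10 per group because the exact
test at the 3-per-season inclusion minimum cannot reject at α = 0.05 at
all (its smallest attainable p is 2/20 = 0.1), so nominal-level behaviour
is a property of the asymptotic path at moderate n.

## Known limitations

- No isotope-turnover correction between baseline and consumer tissues;
  the seasonal machinery quantifies the resulting baseline-choice
  artefact but does not model lag dynamics.
- No Bayesian TP posterior and no δ¹³C mixing model; estimates are point
  equations with across-individual SDs.
- Reference TPs are user-supplied numbers; the package does not retrieve
  them from external databases.
- The packaged guild map covers only genera whose guild is explicitly
  documented; other species default to "unknown" and must be assigned by
  the user before guild-TEF estimation.
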