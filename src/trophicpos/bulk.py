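"""Bulk-isotope trophic position under interchangeable baselines and TEF schemes.

The consumer's TP follows the standard additive model

    TP = (δ¹⁵N_consumer − δ¹⁵N_base) / ΔN + TP_base

where ΔN is the per-step trophic enrichment factor — either the
conventional 3.4‰ or a guild-specific value. TP is affine in consumer
δ¹⁵N, which makes two exact identities available: two baselines shift all
consumers by a common offset, and switching TEFs rescales the TP excess
above the baseline by the TEF ratio (the baseline cancels).
"""

from __future__ import annotations

import logging
from statistics import fmean, stdev

from .types import Baseline, IsotopeSample, TEFScheme, TPEstimate

__all__ = ["tef_for", "tp_post", "rescale_tef", "species_tp", "tp_matrix"]

logger = logging.getLogger(__name__)


def tef_for(guild: str, scheme: TEFScheme) -> float:
    """Per-step enrichment (‰) for one guild under a TEF scheme.

    The guild scheme has no silent fallback: an unmapped or unknown guild
    is an error, because a wrong TEF biases TP multiplicatively.
    """
    if scheme.mode == "constant":
        return scheme.constant_value
    try:
        return scheme.guild_values[guild]
    except KeyError:
        mapped = ", ".join(sorted(scheme.guild_values))
        raise ValueError(
            f"guild {guild!r} has no TEF under the by-guild scheme (mapped guilds: {mapped})"
        ) from None


def tp_post(d15N_consumer: float, baseline: Baseline, tef: float) -> float:
    """Trophic position of one consumer measurement.

    Values below 2 (or 1) are returned as-is: implausibly low TPs are a
    diagnostic finding about the baseline/TEF choice and are flagged
    downstream, never clamped.
    """
    if tef <= 0:
        raise ValueError(f"TEF must be > 0, got {tef}")
    return (d15N_consumer - baseline.d15N_base) / tef + baseline.tp_base


def rescale_tef(tp: float, tp_base: float, tef_from: float, tef_to: float) -> float:
    """Convert a TP computed under one TEF to another TEF, exactly.

    Because TP − TP_base = (δ_consumer − δ_base)/TEF, the baseline cancels:
    TP' = TP_base + (TP − TP_base) · TEF_from / TEF_to. Identical to
    inverting for δ¹⁵N and recomputing.
    """
    if tef_from <= 0 or tef_to <= 0:
        raise ValueError("TEFs must be > 0")
    return tp_base + (tp - tp_base) * tef_from / tef_to


def species_tp(
    samples: list[IsotopeSample],
    baseline: Baseline,
    scheme: TEFScheme,
    season: str | None = None,
) -> TPEstimate:
    """Mean ± SD trophic position of one species.

    TP is computed per individual and then summarised (sample SD, n−1
    denominator; SD = 0 for n = 1). Method label is ``TP_<baseline>`` with
    ``-va`` appended under the guild scheme. All samples must belong to one
    species, and under the guild scheme to one resolvable guild.
    """
    if not samples:
        raise ValueError("no samples for species_tp")
    species = {s.species for s in samples}
    if len(species) > 1:
        raise ValueError(f"samples span several species: {', '.join(sorted(species))}")
    guilds = {s.guild for s in samples}
    if scheme.mode == "by-guild" and len(guilds) > 1:
        raise ValueError(f"samples span several guilds: {', '.join(sorted(guilds))}")
    tps = [tp_post(s.d15N, baseline, tef_for(s.guild, scheme)) for s in samples]
    return TPEstimate(
        species=next(iter(species)),
        method_label=f"TP_{baseline.method_token}{scheme.label_suffix}",
        mean_tp=fmean(tps),
        sd_tp=stdev(tps) if len(tps) > 1 else 0.0,
        n=len(tps),
        season=season if season is not None else baseline.season,
    )


def tp_matrix(
    samples: list[IsotopeSample],
    baselines: list[Baseline],
    schemes: list[TEFScheme],
    lenient: bool = False,
) -> list[TPEstimate]:
    """Full cross of species × baseline × scheme.

    With ``lenient=True`` a species that cannot be estimated under one
    combination (e.g. unknown guild under the guild scheme) is skipped with
    a logged notice instead of aborting the whole matrix.
    """
    if not baselines or not schemes:
        raise ValueError("need at least one baseline and one TEF scheme")
    by_species: dict[str, list[IsotopeSample]] = {}
    for s in samples:
        by_species.setdefault(s.species, []).append(s)
    out: list[TPEstimate] = []
    for species in sorted(by_species):
        for baseline in baselines:
            for scheme in schemes:
                try:
                    out.append(species_tp(by_species[species], baseline, scheme))
                except ValueError as exc:
                    if not lenient:
                        raise
                    logger.info("skipping %s × TP_%s%s: %s",
                                species, baseline.method_token, scheme.label_suffix, exc)
    return out
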