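"""Compound-specific trophic position from amino-acid δ¹⁵N.

Trophic amino acids (Ala, Glu, Leu, Pro) enrich strongly in ¹⁵N with each
trophic transfer while source amino acids (Phe, Gly) barely do, so their
difference inside a single organism carries the trophic position without
any external baseline:

    TP = (δ¹⁵N_trophic − δ¹⁵N_source − β) / Δ + 1

with β the producer-level trophic-minus-source offset and Δ the per-step
enrichment. Three constant sets are packaged: the single-pair Glu/Phe
calibrations (Δ=7.6, β=3.4 and Δ=6.6, β=2.8) and a multi-AA set
(Δ=5.7, β=3.6) averaging four trophic against two source acids.
"""

from __future__ import annotations

from statistics import fmean, stdev

from .types import AAProfile, CSIAConstants, TPEstimate

__all__ = ["aa_means", "tp_csia", "tp_csia_batch", "replicate_uncertainty"]


def aa_means(profile: AAProfile, constants: CSIAConstants) -> tuple[float, float]:
    """Unweighted (trophic_mean, source_mean) over the constant set's AAs.

    Sets are averaged before differencing (rather than averaging per-AA
    TPs); every listed acid must be present in the profile.
    """
    for aa in (*constants.trophic_set, *constants.source_set):
        if aa not in profile.aa_d15N:
            raise ValueError(
                f"profile {profile.sample_id!r} lacks {aa}, required by constants {constants.label!r}"
            )
    trophic = fmean(profile.aa_d15N[aa] for aa in constants.trophic_set)
    source = fmean(profile.aa_d15N[aa] for aa in constants.source_set)
    return trophic, source


def tp_csia(profile: AAProfile, constants: CSIAConstants) -> float:
    """Trophic position of one individual from its amino-acid profile."""
    trophic, source = aa_means(profile, constants)
    return (trophic - source - constants.beta) / constants.delta + 1.0


def replicate_uncertainty(profile: AAProfile, constants: CSIAConstants) -> float | None:
    """Measurement SD of the TP propagated from replicate SDs, if available.

    Independent per-AA replicate errors propagate through the set means and
    the 1/Δ slope. Returns ``None`` when any needed SD is absent. This is
    analytical uncertainty for one individual; species-level SDs are taken
    across individuals instead.
    """
    needed = (*constants.trophic_set, *constants.source_set)
    if any(aa not in profile.aa_sd for aa in needed):
        return None
    var_t = sum(profile.aa_sd[aa] ** 2 for aa in constants.trophic_set) / len(constants.trophic_set) ** 2
    var_s = sum(profile.aa_sd[aa] ** 2 for aa in constants.source_set) / len(constants.source_set) ** 2
    return (var_t + var_s) ** 0.5 / constants.delta


def tp_csia_batch(
    profiles: list[AAProfile],
    constants_list: list[CSIAConstants],
) -> list[TPEstimate]:
    """Species-level mean ± SD TP per constant set (labels ``TP_<set>``)."""
    if not profiles:
        raise ValueError("no profiles for tp_csia_batch")
    by_species: dict[str, list[AAProfile]] = {}
    for p in profiles:
        by_species.setdefault(p.species, []).append(p)
    out: list[TPEstimate] = []
    for species in sorted(by_species):
        group = by_species[species]
        seasons = {p.season for p in group}
        season = next(iter(seasons)) if len(seasons) == 1 else "pooled"
        for constants in constants_list:
            tps = [tp_csia(p, constants) for p in group]
            out.append(
                TPEstimate(
                    species=species,
                    method_label=f"TP_{constants.label}",
                    mean_tp=fmean(tps),
                    sd_tp=stdev(tps) if len(tps) > 1 else 0.0,
                    n=len(tps),
                    season=season,
                )
            )
    return out
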