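"""Baseline δ¹⁵N estimation from field samples and from source amino acids."""

from __future__ import annotations

from statistics import fmean

from .types import AAProfile, Baseline, IsotopeSample, SOURCE_AAS

__all__ = ["estimate_baseline", "source_aa_baseline"]

_KIND_FOR = {"producer": "producer", "primary-consumer": "primary-consumer"}


def _season_select(items, season_filter: str):
    if season_filter == "pooled":
        return list(items)
    return [s for s in items if s.season == season_filter]


def estimate_baseline(
    samples: list[IsotopeSample],
    kind: str,
    season_filter: str = "pooled",
    name: str | None = None,
    allow_mixed_species: bool = False,
) -> Baseline:
    """Mean δ¹⁵N of a reference taxon as a food-web baseline.

    ``kind`` is ``producer`` (base TP 1) or ``primary-consumer`` (base TP 2).
    Samples from several species are refused unless ``allow_mixed_species``
    is set (deliberate pooling, e.g. congeners with indistinguishable
    signatures and low per-species n).
    """
    if kind not in _KIND_FOR:
        raise ValueError(f"kind {kind!r} must be 'producer' or 'primary-consumer'")
    selected = _season_select(samples, season_filter)
    if not selected:
        raise ValueError(f"no samples left after filtering season={season_filter!r}")
    species = {s.species for s in selected}
    if len(species) > 1 and not allow_mixed_species:
        raise ValueError(
            f"samples span {len(species)} species ({', '.join(sorted(species))}); "
            "pass allow_mixed_species=True to pool deliberately"
        )
    return Baseline(
        name=name or next(iter(sorted(species))),
        kind=kind,
        d15N_base=fmean(s.d15N for s in selected),
        season=season_filter,
        n=len(selected),
    )


def source_aa_baseline(
    profiles: list[AAProfile],
    season_filter: str = "pooled",
    name: str = "AA-Sr",
) -> Baseline:
    """Baseline δ¹⁵N from consumer source amino acids (Phe and Gly).

    Source AAs barely fractionate per trophic step, so their δ¹⁵N in a
    consumer preserves the baseline. Per individual, the source value is
    the mean of Phe and Gly; the baseline is the mean of those
    per-individual values (base TP 1).
    """
    selected = _season_select(profiles, season_filter)
    if not selected:
        raise ValueError(f"no profiles left after filtering season={season_filter!r}")
    missing = [p.sample_id for p in selected if any(aa not in p.aa_d15N for aa in SOURCE_AAS)]
    if missing:
        raise ValueError(
            "profiles missing Phe or Gly: " + ", ".join(sorted(missing))
        )
    per_individual = [fmean(p.aa_d15N[aa] for aa in SOURCE_AAS) for p in selected]
    return Baseline(
        name=name,
        kind="source-AA",
        d15N_base=fmean(per_individual),
        season=season_filter,
        n=len(selected),
        label=name,
    )
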