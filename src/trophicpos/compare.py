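"""Cross-method comparison: ranges, plausibility flags, reference deltas,
and winter/summer contrasts tested with the Kruskal–Wallis statistic."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from statistics import fmean, stdev

import pandas as pd
from scipy import stats

from .bulk import tef_for, tp_post
from .types import Baseline, IsotopeSample, TEFScheme, TPEstimate

__all__ = [
    "CANONICAL_METHOD_ORDER",
    "MethodRange",
    "PlausibilityFlag",
    "SeasonContrast",
    "method_range",
    "flag_implausible",
    "compare_to_reference",
    "kruskal_2group",
    "seasonal_contrast",
    "write_season_table",
]

logger = logging.getLogger(__name__)

#: Tie-break order for method labels in range reports (bulk methods in
#: presentation order, then the amino-acid methods).
CANONICAL_METHOD_ORDER = (
    "TP_algae", "TP_algae-va",
    "TP_phyto", "TP_phyto-va",
    "TP_Masp", "TP_Masp-va",
    "TP_Pima", "TP_Pima-va",
    "TP_AA-Sr", "TP_AA-Sr-va",
    "TP_Glu-Phe(1)", "TP_Glu-Phe(2)", "TP_Tr-Sr",
)


def _canonical_rank(label: str) -> tuple[int, str]:
    try:
        return (CANONICAL_METHOD_ORDER.index(label), label)
    except ValueError:
        return (len(CANONICAL_METHOD_ORDER), label)


@dataclass(frozen=True)
class MethodRange:
    """Spread of TP estimates for one species across methods."""

    species: str
    min_method: str
    min_tp: float
    max_method: str
    max_tp: float

    @property
    def spread(self) -> float:
        return self.max_tp - self.min_tp


@dataclass(frozen=True)
class PlausibilityFlag:
    species: str
    method_label: str
    mean_tp: float
    reason: str


@dataclass(frozen=True)
class SeasonContrast:
    """Winter-vs-summer TP contrast for one species under one method."""

    species: str
    method_label: str
    tp_summer: float
    tp_winter: float
    sd_summer: float
    sd_winter: float
    p_value: float
    n_summer: int
    n_winter: int

    @property
    def difference(self) -> float:
        """Winter − summer; positive when the winter estimate is higher."""
        return self.tp_winter - self.tp_summer


def method_range(estimates: list[TPEstimate]) -> MethodRange:
    """Min/max mean TP across methods for one species.

    Ties are broken by canonical method order, so a repeated extreme value
    is always attributed to the first method in presentation order.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two estimates to form a range")
    species = {e.species for e in estimates}
    if len(species) > 1:
        raise ValueError(f"estimates span several species: {', '.join(sorted(species))}")
    ordered = sorted(estimates, key=lambda e: _canonical_rank(e.method_label))
    lo = min(ordered, key=lambda e: e.mean_tp)
    hi = max(ordered, key=lambda e: e.mean_tp)
    return MethodRange(next(iter(species)), lo.method_label, lo.mean_tp, hi.method_label, hi.mean_tp)


def flag_implausible(
    estimates: list[TPEstimate],
    consumer_floor: float = 2.0,
    producer_floor: float = 1.0,
) -> list[PlausibilityFlag]:
    """Flag estimates below theoretical floors, without mutating anything.

    A consumer strictly below TP 2 cannot be explained by feeding solely on
    producers; below TP 1 is below the producer level itself (double flag).
    Flags are diagnostics on the baseline/TEF choice, not corrections.
    """
    flags: list[PlausibilityFlag] = []
    for e in estimates:
        if e.mean_tp < consumer_floor:
            flags.append(PlausibilityFlag(e.species, e.method_label, e.mean_tp, "below consumer floor (TP < 2)"))
        if e.mean_tp < producer_floor:
            flags.append(PlausibilityFlag(e.species, e.method_label, e.mean_tp, "below producer floor (TP < 1)"))
    return flags


def compare_to_reference(
    estimates: list[TPEstimate],
    reference_tps: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Delta of each estimate against an external reference TP table.

    ``reference_tps`` maps species to (mean, sd), e.g. diet-study
    compilations. Species absent from the reference get delta ``"nd"``.
    """
    records = []
    for e in estimates:
        ref = reference_tps.get(e.species)
        records.append(
            {
                "species": e.species,
                "method_label": e.method_label,
                "season": e.season,
                "mean_tp": e.mean_tp,
                "tp_ref": ref[0] if ref else "nd",
                "delta": e.mean_tp - ref[0] if ref else "nd",
            }
        )
    return pd.DataFrame.from_records(records)


def _kw_statistic(values: list[float], n1: int) -> float:
    """Tie-corrected Kruskal–Wallis H for a two-group split (first n1 vs rest)."""
    n = len(values)
    ranks = stats.rankdata(values)
    r1 = ranks[:n1].sum()
    r2 = ranks[n1:].sum()
    n2 = n - n1
    h = 12.0 / (n * (n + 1)) * (r1 * r1 / n1 + r2 * r2 / n2) - 3 * (n + 1)
    # tie correction
    tie_sum = sum(t**3 - t for t in pd.Series(values).value_counts())
    denom = 1.0 - tie_sum / (n**3 - n)
    if denom <= 0:
        return 0.0  # all observations identical
    return h / denom


def kruskal_2group(x: list[float], y: list[float], method: str = "auto") -> tuple[float, float]:
    """Two-group Kruskal–Wallis test; returns (H, p).

    ``method`` is ``"asymptotic"`` (χ², 1 df, tie-corrected — the usual
    reported variant), ``"exact"`` (enumeration of all group assignments of
    the pooled values), or ``"auto"``: exact when total n ≤ 10, else
    asymptotic. The exact p is the fraction of assignments whose H is at
    least the observed one.
    """
    x, y = list(map(float, x)), list(map(float, y))
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    n = len(x) + len(y)
    if method == "auto":
        method = "exact" if n <= 10 else "asymptotic"
    if method == "asymptotic":
        if len(set(x + y)) == 1:
            return 0.0, 1.0  # degenerate: scipy refuses all-identical input
        h, p = stats.kruskal(x, y)
        return float(h), float(p)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    pooled = x + y
    h_obs = _kw_statistic(pooled, len(x))
    total = 0
    at_least = 0
    idx = range(n)
    for chosen in combinations(idx, len(x)):
        chosen_set = set(chosen)
        perm = [pooled[i] for i in chosen] + [pooled[i] for i in idx if i not in chosen_set]
        total += 1
        if _kw_statistic(perm, len(x)) >= h_obs - 1e-12:
            at_least += 1
    return h_obs, at_least / total


def seasonal_contrast(
    samples: list[IsotopeSample],
    baseline_winter: Baseline,
    baseline_summer: Baseline,
    scheme: TEFScheme,
    min_n: int = 3,
    p_method: str = "auto",
    bh_correct: bool = False,
) -> list[SeasonContrast]:
    """Winter-vs-summer TP contrast per species, season-matched baselines.

    Per-individual TPs use the baseline of the individual's own season.
    Species with fewer than ``min_n`` individuals in either season are
    excluded with a logged notice. Significance is the two-group
    Kruskal–Wallis p-value on the per-individual TP lists. No
    multiple-testing correction by default; ``bh_correct=True`` applies
    Benjamini–Hochberg across the retained species.
    """
    by_species: dict[str, dict[str, list[IsotopeSample]]] = {}
    for s in samples:
        if s.season in ("winter", "summer"):
            by_species.setdefault(s.species, {"winter": [], "summer": []})[s.season].append(s)

    contrasts: list[SeasonContrast] = []
    for species in sorted(by_species):
        groups = by_species[species]
        n_w, n_s = len(groups["winter"]), len(groups["summer"])
        if n_w < min_n or n_s < min_n:
            logger.info("excluding %s: n_winter=%d, n_summer=%d (need ≥%d each)",
                        species, n_w, n_s, min_n)
            continue
        tps = {}
        for season, baseline in (("winter", baseline_winter), ("summer", baseline_summer)):
            tps[season] = [tp_post(s.d15N, baseline, tef_for(s.guild, scheme)) for s in groups[season]]
        _, p = kruskal_2group(tps["winter"], tps["summer"], method=p_method)
        contrasts.append(
            SeasonContrast(
                species=species,
                method_label=f"TP_{baseline_winter.method_token}{scheme.label_suffix}",
                tp_summer=fmean(tps["summer"]),
                tp_winter=fmean(tps["winter"]),
                sd_summer=stdev(tps["summer"]) if n_s > 1 else 0.0,
                sd_winter=stdev(tps["winter"]) if n_w > 1 else 0.0,
                p_value=p,
                n_summer=n_s,
                n_winter=n_w,
            )
        )
    if bh_correct and contrasts:
        from statsmodels.stats.multitest import multipletests

        _, adjusted, _, _ = multipletests([c.p_value for c in contrasts], method="fdr_bh")
        contrasts = [
            SeasonContrast(
                c.species, c.method_label, c.tp_summer, c.tp_winter,
                c.sd_summer, c.sd_winter, float(p_adj), c.n_summer, c.n_winter,
            )
            for c, p_adj in zip(contrasts, adjusted)
        ]
    return contrasts


def write_season_table(contrasts: list[SeasonContrast], path) -> pd.DataFrame:
    """Write a seasonal-contrast report CSV (one row per species × method)."""
    records = [
        {
            "species": c.species,
            "method_label": c.method_label,
            "summer": f"{c.tp_summer:.2f} ± {c.sd_summer:.2f}",
            "winter": f"{c.tp_winter:.2f} ± {c.sd_winter:.2f}",
            "difference_winter_minus_summer": round(c.difference, 2),
            "p_value": c.p_value,
            "n_summer": c.n_summer,
            "n_winter": c.n_winter,
        }
        for c in sorted(contrasts, key=lambda c: (c.species, c.method_label))
    ]
    df = pd.DataFrame.from_records(records)
    df.to_csv(path, index=False)
    return df
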