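"""CSV readers/writers and packaged reference values.

Bulk CSV schema: ``sample_id, species, family, guild, season, tissue,
d15N, d13C`` (``family``, ``tissue``, ``d13C`` optional). Amino-acid CSV
schema: ``sample_id, species, season`` plus one column per amino acid
(``Phe``, ``Gly``, ``Ala``, ``Glu``, ``Leu``, ``Pro``) and optional
``<AA>_sd`` replicate-SD columns. Comma-separated, UTF-8, ``.`` decimal,
header required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .types import (
    AA_NAMES,
    AA_REPLICATE_SD_BOUND,
    AAProfile,
    Baseline,
    GUILDS,
    IsotopeSample,
    SEASONS,
    TPEstimate,
)

__all__ = [
    "SchemaError",
    "BulkLoadResult",
    "load_bulk_csv",
    "load_aa_csv",
    "load_reference_csv",
    "packaged_baselines",
    "packaged_guild_map",
    "write_tp_table",
    "round_half_up",
]


class SchemaError(ValueError):
    """A CSV file does not match the expected schema."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching how printed tables round.

    Banker's rounding (Python's default) rounds 2.465 to 2.46; isotope
    tables round it to 2.47, hence an explicit half-up rule.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# Case-insensitive synonyms accepted on load, extendable per call.
_SEASON_SYNONYMS = {"august": "winter", "march": "summer", "both": "pooled", "all": "pooled"}
_GUILD_SYNONYMS = {
    "ff": "filter-feeder",
    "filter feeder": "filter-feeder",
    "filterfeeder": "filter-feeder",
    "zp": "zooplanktivore",
    "planktivore": "zooplanktivore",
    "herbivore": "herbivore-detritivore",
    "detritivore": "herbivore-detritivore",
    "herbivore detritivore": "herbivore-detritivore",
    "hd": "herbivore-detritivore",
    "c": "carnivore",
    "o": "omnivore",
    "": "unknown",
    "nd": "unknown",
}


def _normalize(value: str, permitted: tuple[str, ...], synonyms: dict[str, str], what: str) -> str:
    token = str(value).strip().lower()
    token = synonyms.get(token, token)
    if token not in permitted:
        raise ValueError(
            f"{what} value {value!r} not recognised; permitted labels: {', '.join(permitted)}"
        )
    return token


@dataclass(frozen=True)
class Rejection:
    """A row dropped during load, with its 1-based file line number."""

    line: int
    sample_id: str
    reason: str


@dataclass(frozen=True)
class BulkLoadResult:
    samples: list[IsotopeSample]
    rejections: list[Rejection]

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)


def _read_csv_str(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def load_bulk_csv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    season_synonyms: dict[str, str] | None = None,
    guild_synonyms: dict[str, str] | None = None,
) -> BulkLoadResult:
    """Load per-individual bulk δ¹⁵N samples.

    ``column_map`` maps canonical field names to file column names when the
    file uses different headers. Rows with a missing or unparseable ``d15N``
    are rejected (reported with line numbers), not silently dropped;
    unrecognised season/guild labels raise.
    """
    df = _read_csv_str(path)
    cmap = {k: k for k in ("sample_id", "species", "family", "guild", "season", "tissue", "d15N", "d13C")}
    cmap.update(column_map or {})
    for required in ("sample_id", "species", "d15N"):
        if cmap[required] not in df.columns:
            raise SchemaError(f"required column {cmap[required]!r} missing from {path}")

    season_syn = {**_SEASON_SYNONYMS, **{k.lower(): v for k, v in (season_synonyms or {}).items()}}
    guild_syn = {**_GUILD_SYNONYMS, **{k.lower(): v for k, v in (guild_synonyms or {}).items()}}

    def _get(row, key, default=""):
        col = cmap[key]
        return row[col] if col in df.columns else default

    samples: list[IsotopeSample] = []
    rejections: list[Rejection] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        sid = str(_get(row, "sample_id"))
        raw = str(_get(row, "d15N")).strip()
        if raw == "":
            rejections.append(Rejection(line, sid, "missing d15N"))
            continue
        try:
            d15n = float(raw)
        except ValueError:
            rejections.append(Rejection(line, sid, f"unparseable d15N {raw!r} (line {line})"))
            continue
        d13c_raw = str(_get(row, "d13C")).strip()
        samples.append(
            IsotopeSample(
                sample_id=sid,
                species=str(_get(row, "species")).strip(),
                family=(str(_get(row, "family")).strip() or None),
                guild=_normalize(_get(row, "guild", "unknown") or "unknown", GUILDS, guild_syn, "guild"),
                season=_normalize(_get(row, "season", "pooled") or "pooled", SEASONS, season_syn, "season"),
                tissue=(str(_get(row, "tissue")).strip() or None),
                d15N=d15n,
                d13C=float(d13c_raw) if d13c_raw else None,
            )
        )
    return BulkLoadResult(samples, rejections)


def load_aa_csv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sd_warn_bound: float = AA_REPLICATE_SD_BOUND,
) -> list[AAProfile]:
    """Load wide-format per-individual amino-acid δ¹⁵N profiles.

    One column per amino acid; absent columns give absent map entries, not
    zeros. ``<AA>_sd`` columns carry replicate SDs; an SD above
    ``sd_warn_bound`` (analytical bound, ‰) attaches a QC warning to the
    profile and emits a :class:`UserWarning`, but the profile still loads.
    """
    df = _read_csv_str(path)
    cmap = {k: k for k in ("sample_id", "species", "season")}
    cmap.update(column_map or {})
    aa_cols = [aa for aa in AA_NAMES if aa in df.columns]
    if len(df.columns) and not aa_cols and len(df) > 0:
        raise SchemaError(
            f"no recognised amino-acid column in {path}; expected any of {', '.join(AA_NAMES)}"
        )

    profiles: list[AAProfile] = []
    for idx, row in df.iterrows():
        line = idx + 2
        sid = str(row.get(cmap["sample_id"], f"row{line}"))
        values: dict[str, float] = {}
        sds: dict[str, float] = {}
        qc: list[str] = []
        for aa in aa_cols:
            raw = str(row[aa]).strip()
            if raw == "":
                continue
            try:
                values[aa] = float(raw)
            except ValueError as exc:
                raise SchemaError(f"unparseable {aa} value {raw!r} at line {line}") from exc
            sd_col = f"{aa}_sd"
            if sd_col in df.columns and str(row[sd_col]).strip():
                sd = float(row[sd_col])
                sds[aa] = sd
                if sd > sd_warn_bound:
                    msg = f"{sid}: replicate SD {sd:g}‰ for {aa} exceeds analytical bound {sd_warn_bound:g}‰"
                    qc.append(msg)
                    warnings.warn(msg, UserWarning, stacklevel=2)
        season_col = cmap["season"]
        season = row[season_col] if season_col in df.columns and str(row[season_col]).strip() else "pooled"
        profiles.append(
            AAProfile(
                sample_id=sid,
                species=str(row.get(cmap["species"], "")).strip(),
                season=_normalize(season, SEASONS, _SEASON_SYNONYMS, "season"),
                aa_d15N=values,
                aa_sd=sds,
                qc_warnings=tuple(qc),
            )
        )
    return profiles


def load_reference_csv(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a species→reference-TP table (columns: species, tp_ref_mean, tp_ref_sd)."""
    df = pd.read_csv(path)
    for col in ("species", "tp_ref_mean"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    out: dict[str, tuple[float, float]] = {}
    for _, row in df.iterrows():
        sd = float(row["tp_ref_sd"]) if "tp_ref_sd" in df.columns and pd.notna(row["tp_ref_sd"]) else 0.0
        out[str(row["species"])] = (float(row["tp_ref_mean"]), sd)
    return out


# Packaged baseline δ¹⁵N values (‰): pooled plus per-season columns.
# Producers and the source-AA baseline sit at TP 1; the two primary
# consumers (a cowrie and a pearl oyster) at TP 2.
_BASELINE_TABLE: dict[str, tuple[str, str, dict[str, float]]] = {
    # name: (kind, method label token, {season: d15N})
    "macroalgae": ("producer", "algae", {"pooled": 11.6, "winter": 10.2, "summer": 11.9}),
    "phytoplankton": ("producer", "phyto", {"pooled": 15.0, "winter": 13.1, "summer": 16.5}),
    "Mauritia": ("primary-consumer", "Masp", {"pooled": 16.3, "winter": 15.8, "summer": 16.6}),
    "Pinctada": ("primary-consumer", "Pima", {"pooled": 14.7, "winter": 15.2, "summer": 14.5}),
    "AA-Sr": ("source-AA", "AA-Sr", {"pooled": 11.6, "winter": 12.8, "summer": 10.5}),
}


def packaged_baselines(season: str = "pooled") -> list[Baseline]:
    """The five packaged reef baselines for one season.

    Values are as printed to one decimal; only arithmetic done against a
    single baseline reproduces published table cells exactly, since the
    unrounded values behind cross-baseline reconstructions differ by a few
    hundredths of a TP.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; permitted: {', '.join(SEASONS)}")
    return [
        Baseline(name=name, kind=kind, d15N_base=by_season[season], season=season, label=label)
        for name, (kind, label, by_season) in _BASELINE_TABLE.items()
    ]


def packaged_baseline(name: str, season: str = "pooled") -> Baseline:
    """Look up one packaged baseline by name or method token."""
    for b in packaged_baselines(season):
        if b.name == name or b.method_token == name:
            return b
    names = sorted({n for pair in _BASELINE_TABLE.items() for n in (pair[0], pair[1][1])})
    raise KeyError(f"unknown baseline {name!r}; packaged names: {', '.join(names)}")


#: Genus→guild assignments for taxa whose guild the source study names
#: explicitly; everything else is "unknown" and must be supplied by the user.
_PACKAGED_GUILDS = {
    "Acanthurus": "herbivore-detritivore",
    "Ctenochaetus": "herbivore-detritivore",
    "Scarus": "herbivore-detritivore",
    "Pterois": "carnivore",
    "Scorpaenodes": "carnivore",
    "Trachinotus": "carnivore",
}


def packaged_guild_map() -> dict[str, str]:
    return dict(_PACKAGED_GUILDS)


def guild_for_species(species: str, extra: dict[str, str] | None = None) -> str:
    """Resolve a guild from the packaged genus map (species name's first word)."""
    table = {**_PACKAGED_GUILDS, **(extra or {})}
    if species in table:
        return table[species]
    genus = species.split()[0] if species else ""
    return table.get(genus, "unknown")


def write_bulk_csv(samples: list[IsotopeSample], path: str | Path) -> None:
    """Write samples in the bulk CSV schema (full precision, round-trip safe)."""
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "species": s.species,
                "family": s.family or "",
                "guild": s.guild,
                "season": s.season,
                "tissue": s.tissue or "",
                "d15N": repr(s.d15N),
                "d13C": repr(s.d13C) if s.d13C is not None else "",
            }
            for s in samples
        ]
    ).to_csv(path, index=False)


def write_aa_csv(profiles: list[AAProfile], path: str | Path) -> None:
    """Write profiles in the wide amino-acid CSV schema."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"sample_id": p.sample_id, "species": p.species, "season": p.season}
        for aa in AA_NAMES:
            if aa in p.aa_d15N:
                row[aa] = repr(p.aa_d15N[aa])
            if aa in p.aa_sd:
                row[f"{aa}_sd"] = repr(p.aa_sd[aa])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_tp_table(estimates: list[TPEstimate], path: str | Path) -> pd.DataFrame:
    """Write a species × method TP matrix as CSV and return the frame.

    One row per species × season; one column per method label, values
    rounded half-up to two decimals. SDs are identical across methods up
    to TEF scaling, so "mean ± SD" appears only in the first method column
    and later columns carry the mean alone. ``min_method``/``max_method``
    columns mark the extreme estimates per row.
    """
    if not estimates:
        raise ValueError("no estimates to write")
    methods = list(dict.fromkeys(e.method_label for e in estimates))
    rows: dict[tuple[str, str], dict[str, TPEstimate]] = {}
    for e in estimates:
        rows.setdefault((e.species, e.season), {})[e.method_label] = e

    records = []
    for (species, season), by_method in sorted(rows.items()):
        rec: dict[str, object] = {"species": species, "season": season}
        present = [(m, by_method[m]) for m in methods if m in by_method]
        for i, (m, e) in enumerate(present):
            mean = round_half_up(e.mean_tp, 2)
            if i == 0:
                rec[m] = f"{mean:.2f} ± {round_half_up(e.sd_tp, 2):.2f}"
            else:
                rec[m] = f"{mean:.2f}"
        rec["min_method"] = min(present, key=lambda me: me[1].mean_tp)[0]
        rec["max_method"] = max(present, key=lambda me: me[1].mean_tp)[0]
        records.append(rec)

    df = pd.DataFrame.from_records(records)
    df.to_csv(path, index=False)
    return df
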