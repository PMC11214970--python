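"""Domain types for isotope-based trophic position estimation.

All δ¹⁵N values are per-mil (‰) relative to atmospheric N₂. Trophic
position (TP) is the continuous food-web rank: 1 for a primary producer,
2 for a strict primary consumer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GUILDS",
    "SEASONS",
    "SOURCE_AAS",
    "TROPHIC_AAS",
    "AA_NAMES",
    "DEFAULT_GUILD_TEFS",
    "CONVENTIONAL_TEF",
    "AA_REPLICATE_SD_BOUND",
    "IsotopeSample",
    "AAProfile",
    "Baseline",
    "TEFScheme",
    "CSIAConstants",
    "TPEstimate",
    "GLU_PHE_1",
    "GLU_PHE_2",
    "TR_SR",
    "CSIA_PRESETS",
]

#: Feeding guilds recognised throughout the package.
GUILDS = (
    "filter-feeder",
    "zooplanktivore",
    "herbivore-detritivore",
    "carnivore",
    "omnivore",
    "unknown",
)

#: Permitted season labels. "pooled" is first-class: cross-method tables
#: pool both field campaigns.
SEASONS = ("winter", "summer", "pooled")

#: Amino acids whose δ¹⁵N changes little per trophic transfer and so
#: preserves the baseline value.
SOURCE_AAS = ("Phe", "Gly")

#: Amino acids strongly enriched in ¹⁵N at each trophic transfer.
TROPHIC_AAS = ("Ala", "Glu", "Leu", "Pro")

AA_NAMES = SOURCE_AAS + TROPHIC_AAS

#: Conventional per-step ¹⁵N trophic enrichment factor (Post-style), ‰.
CONVENTIONAL_TEF = 3.4

#: Guild-specific per-step enrichment factors, ‰. Omnivores keep the
#: conventional value.
DEFAULT_GUILD_TEFS: dict[str, float] = {
    "filter-feeder": 2.2,
    "zooplanktivore": 3.0,
    "herbivore-detritivore": 4.3,
    "carnivore": 2.5,
    "omnivore": 3.4,
}

#: Analytical bound on per-AA replicate SD (‰); exceeding it flags a QC
#: warning on load, never an error.
AA_REPLICATE_SD_BOUND = 1.75

_BASELINE_KINDS = ("producer", "primary-consumer", "source-AA")


def _check_season(season: str) -> str:
    if season not in SEASONS:
        raise ValueError(
            f"season {season!r} not recognised; permitted labels: {', '.join(SEASONS)}"
        )
    return season


def _check_guild(guild: str) -> str:
    if guild not in GUILDS:
        raise ValueError(
            f"guild {guild!r} not recognised; permitted labels: {', '.join(GUILDS)}"
        )
    return guild


@dataclass(frozen=True)
class IsotopeSample:
    """One individual's bulk δ¹⁵N measurement with taxonomy, guild and season."""

    sample_id: str
    species: str
    d15N: float
    guild: str = "unknown"
    season: str = "pooled"
    family: str | None = None
    tissue: str | None = None
    d13C: float | None = None  # carried through, never used in TP math

    def __post_init__(self) -> None:
        if not math.isfinite(self.d15N) or abs(self.d15N) >= 100:
            raise ValueError(
                f"sample {self.sample_id!r}: d15N={self.d15N!r} must be finite with |d15N| < 100‰"
            )
        _check_season(self.season)
        _check_guild(self.guild)


@dataclass(frozen=True)
class AAProfile:
    """One individual's per-amino-acid δ¹⁵N values, optionally with replicate SDs.

    ``aa_d15N`` maps amino-acid names (``Phe``, ``Gly``, ``Ala``, ``Glu``,
    ``Leu``, ``Pro``) to per-mil values; absent acids are simply absent from
    the map. ``qc_warnings`` records load-time quality notices (e.g. a
    replicate SD above the analytical bound).
    """

    sample_id: str
    species: str
    aa_d15N: dict[str, float]
    season: str = "pooled"
    aa_sd: dict[str, float] = field(default_factory=dict)
    qc_warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check_season(self.season)
        for aa, value in self.aa_d15N.items():
            if aa not in AA_NAMES:
                raise ValueError(f"profile {self.sample_id!r}: unknown amino acid {aa!r}")
            if not math.isfinite(value):
                raise ValueError(f"profile {self.sample_id!r}: non-finite δ¹⁵N for {aa}")
        for aa, sd in self.aa_sd.items():
            if sd < 0:
                raise ValueError(f"profile {self.sample_id!r}: negative replicate SD for {aa}")


@dataclass(frozen=True)
class Baseline:
    """A named δ¹⁵N reference at the base of the food web.

    ``tp_base`` is 1 for primary producers and source-AA baselines, 2 for
    primary consumers. ``label`` is the short token used to compose method
    labels (e.g. ``algae`` → ``TP_algae``); it defaults to ``name``.
    """

    name: str
    kind: str
    d15N_base: float
    season: str = "pooled"
    n: int | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _BASELINE_KINDS:
            raise ValueError(
                f"baseline kind {self.kind!r} not one of {', '.join(_BASELINE_KINDS)}"
            )
        _check_season(self.season)
        if not math.isfinite(self.d15N_base):
            raise ValueError(f"baseline {self.name!r}: non-finite d15N_base")

    @property
    def tp_base(self) -> float:
        """Trophic position of the reference organism (1 or 2)."""
        return 2.0 if self.kind == "primary-consumer" else 1.0

    @property
    def method_token(self) -> str:
        return self.label if self.label is not None else self.name


@dataclass(frozen=True)
class TEFScheme:
    """Per-trophic-step ¹⁵N enrichment model: one constant or a guild→value map."""

    mode: str  # "constant" | "by-guild"
    constant_value: float = CONVENTIONAL_TEF
    guild_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "by-guild"):
            raise ValueError(f"TEF scheme mode {self.mode!r} must be 'constant' or 'by-guild'")
        if self.mode == "constant" and self.constant_value <= 0:
            raise ValueError("constant TEF must be > 0")
        for guild, value in self.guild_values.items():
            _check_guild(guild)
            if value <= 0:
                raise ValueError(f"TEF for guild {guild!r} must be > 0, got {value}")

    @classmethod
    def constant(cls, value: float = CONVENTIONAL_TEF) -> "TEFScheme":
        return cls(mode="constant", constant_value=value)

    @classmethod
    def by_guild(cls, mapping: dict[str, float] | None = None) -> "TEFScheme":
        return cls(mode="by-guild", guild_values=dict(mapping or DEFAULT_GUILD_TEFS))

    @property
    def label_suffix(self) -> str:
        """``-va`` (variable) for the guild scheme, empty for the constant one."""
        return "-va" if self.mode == "by-guild" else ""


@dataclass(frozen=True)
class CSIAConstants:
    """Constants for amino-acid-based TP: trophic/source AA sets, Δ and β.

    ``beta`` is the producer-level offset between trophic and source AA
    δ¹⁵N; ``delta`` the per-step trophic-minus-source enrichment, both ‰.
    """

    label: str
    delta: float
    beta: float
    trophic_set: tuple[str, ...]
    source_set: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if not self.trophic_set or not self.source_set:
            raise ValueError("trophic and source AA sets must be non-empty")
        if set(self.trophic_set) & set(self.source_set):
            raise ValueError("trophic and source AA sets must be disjoint")


#: Glu/Phe constants of the original single-pair calibration.
GLU_PHE_1 = CSIAConstants("Glu-Phe(1)", delta=7.6, beta=3.4, trophic_set=("Glu",), source_set=("Phe",))
#: Glu/Phe constants from larger meta-analyses.
GLU_PHE_2 = CSIAConstants("Glu-Phe(2)", delta=6.6, beta=2.8, trophic_set=("Glu",), source_set=("Phe",))
#: Multi-AA constants: means over four trophic and two source acids.
TR_SR = CSIAConstants("Tr-Sr", delta=5.7, beta=3.6, trophic_set=TROPHIC_AAS, source_set=SOURCE_AAS)

CSIA_PRESETS: dict[str, CSIAConstants] = {c.label: c for c in (GLU_PHE_1, GLU_PHE_2, TR_SR)}


@dataclass(frozen=True)
class TPEstimate:
    """A species × method × season trophic-position summary."""

    species: str
    method_label: str
    mean_tp: float
    sd_tp: float
    n: int
    season: str = "pooled"

    def __post_init__(self) -> None:
        _check_season(self.season)
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_tp < 0:
            raise ValueError("sd_tp must be >= 0")
        if self.n == 1 and self.sd_tp != 0:
            raise ValueError("sd_tp must be 0 when n == 1")
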