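"""Core domain types: habitats, the seasonal calendar, and the survey dataset bundle.

The study system is a tropical-forest mosaic surveyed for two sympatric
great-ape species (western lowland gorilla and central chimpanzee).  Five
habitat types are recognised; the year is divided into two dry and two
rainy seasons.  All field tables are held as pandas DataFrames inside a
single :class:`SurveyDataset` bundle that the analysis modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

#: The five habitat codes: Mature Forest, Young Secondary Forest,
#: Light Gap, Swamp, Riparian Forest.
HABITATS: tuple[str, ...] = ("MF", "YSF", "LG", "SW", "RF")

#: Season codes: Long Dry, Long Rainy, Short Dry, Short Rainy.
SEASONS: tuple[str, ...] = ("LDS", "LRS", "SDS", "SRS")

#: The two ape species tracked by the surveys.
APES: tuple[str, ...] = ("gorilla", "chimpanzee")

#: Default plot area in m^2 (25 m x 25 m botanical plots).
DEFAULT_PLOT_AREA: float = 625.0


class SchemaError(ValueError):
    """An input table is missing a required column or has a bad header."""


class ValidationError(ValueError):
    """An input table contains values that violate the data contract."""


@dataclass(frozen=True)
class SeasonCalendar:
    """Total mapping from month-of-year (1-12) to one of the four seasons.

    Season boundaries in the source climatology are fuzzy (transition
    months are ambiguous), so the mapping is configuration, not a
    constant.  The default assigns Nov-Feb to the long dry season,
    Mar-Jun to the long rainy season, Jul-Aug to the short dry season
    and Sep-Oct to the short rainy season.
    """

    months: Mapping[int, str]

    def __post_init__(self) -> None:
        keys = set(self.months)
        if keys != set(range(1, 13)):
            missing = sorted(set(range(1, 13)) - keys)
            extra = sorted(keys - set(range(1, 13)))
            raise ValidationError(
                f"calendar must cover months 1-12 exactly "
                f"(missing={missing}, extra={extra})"
            )
        bad = {m: s for m, s in self.months.items() if s not in SEASONS}
        if bad:
            raise ValidationError(f"unknown season codes in calendar: {bad}")

    def season_of(self, month: int) -> str:
        """Return the season a calendar month belongs to."""
        if month not in self.months:
            raise ValidationError(f"month must be in 1-12, got {month!r}")
        return self.months[month]

    def months_of(self, season: str) -> list[int]:
        """All months mapped to *season* (may be empty under custom calendars)."""
        return sorted(m for m, s in self.months.items() if s == season)


DEFAULT_CALENDAR = SeasonCalendar(
    {
        11: "LDS", 12: "LDS", 1: "LDS", 2: "LDS",
        3: "LRS", 4: "LRS", 5: "LRS", 6: "LRS",
        7: "SDS", 8: "SDS",
        9: "SRS", 10: "SRS",
    }
)


@dataclass
class SurveyDataset:
    """The six field tables bound together with a season calendar.

    Attributes
    ----------
    availability : DataFrame
        Habitat-availability survey points; columns
        ``transect_id, position_m, habitat``.
    nests : DataFrame
        Fresh night-nest records; columns ``ape, month, habitat, group_id``.
    fecal : DataFrame
        Long-format per-taxon seed counts from fecal samples; columns
        ``sample_id, ape, month, taxon, seeds``.
    phenology : DataFrame
        Monthly fruiting scores for monitored individuals; columns
        ``individual_id, taxon, month, dbh_cm, score_unripe_tree,
        score_ripe_tree, score_unripe_ground, score_ripe_ground``.
    plots : DataFrame
        Long-format botanical plot inventories; columns
        ``plot_id, habitat, taxon, stems`` (LG plots never occur).
    taxa : DataFrame
        Fruit trait table; columns ``taxon, family, mean_fruit_weight_g,
        mean_seeds_per_fruit``.
    calendar : SeasonCalendar
        The month-to-season mapping used for all seasonal stratification.
    plot_area : float
        Area of each botanical plot in m^2.
    """

    availability: pd.DataFrame
    nests: pd.DataFrame
    fecal: pd.DataFrame
    phenology: pd.DataFrame
    plots: pd.DataFrame
    taxa: pd.DataFrame
    calendar: SeasonCalendar = field(default_factory=lambda: DEFAULT_CALENDAR)
    plot_area: float = DEFAULT_PLOT_AREA

    def validate(self) -> list[str]:
        """Check cross-table contracts; return warning strings.

        Raises :class:`ValidationError` for hard violations (bad habitat
        codes, negative counts, out-of-range months or scores).  Taxa
        referenced by fecal/phenology/plot tables but absent from the
        trait table are *not* an error: they are returned as
        ``unclassifiable`` warnings so downstream scoring can flag them.
        """
        warnings: list[str] = []
        for name, df, col in (
            ("availability", self.availability, "habitat"),
            ("nests", self.nests, "habitat"),
            ("plots", self.plots, "habitat"),
        ):
            bad = set(df[col].unique()) - set(HABITATS)
            if bad:
                raise ValidationError(f"{name}: unknown habitat codes {sorted(bad)}")
        if (self.plots["habitat"] == "LG").any():
            raise ValidationError("plots: botanical plots are never placed in LG")
        for name, df, col in (
            ("fecal", self.fecal, "seeds"),
            ("plots", self.plots, "stems"),
        ):
            if (df[col] < 0).any():
                raise ValidationError(f"{name}: negative counts in column {col!r}")
        for name, df in (("nests", self.nests), ("fecal", self.fecal),
                         ("phenology", self.phenology)):
            m = df["month"]
            if ((m < 1) | (m > 12)).any():
                raise ValidationError(f"{name}: month out of range 1-12")
        if (self.availability["position_m"] < 0).any():
            raise ValidationError("availability: negative position_m")
        if (self.phenology["dbh_cm"] <= 0).any():
            raise ValidationError("phenology: dbh_cm must be positive")
        for col in ("score_unripe_tree", "score_ripe_tree",
                    "score_unripe_ground", "score_ripe_ground"):
            if not self.phenology[col].isin([0, 1, 2]).all():
                raise ValidationError(f"phenology: {col} must be 0, 1 or 2")
        bad_ape = set(self.nests["ape"]) | set(self.fecal["ape"])
        bad_ape -= set(APES)
        if bad_ape:
            raise ValidationError(f"unknown ape labels {sorted(bad_ape)}")
        tw = self.taxa.set_index("taxon")
        pos = tw["mean_fruit_weight_g"].dropna()
        if (pos <= 0).any():
            raise ValidationError("taxa: mean_fruit_weight_g must be > 0")
        spf = tw["mean_seeds_per_fruit"].dropna()
        if (spf < 1).any():
            raise ValidationError("taxa: mean_seeds_per_fruit must be >= 1")
        for t in sorted(self.unclassifiable_taxa()):
            warnings.append(f"taxon {t!r} lacks fruit traits: unclassifiable")
        return warnings

    def referenced_taxa(self) -> set[str]:
        """All taxa appearing in fecal, phenology or plot tables."""
        return (
            set(self.fecal["taxon"])
            | set(self.phenology["taxon"])
            | set(self.plots["taxon"])
        )

    def unclassifiable_taxa(self) -> set[str]:
        """Taxa referenced by field tables but lacking usable fruit traits."""
        usable = set(
            self.taxa.dropna(
                subset=["mean_fruit_weight_g", "mean_seeds_per_fruit"]
            )["taxon"]
        )
        return self.referenced_taxa() - usable

    def nests_for(self, ape: str) -> pd.DataFrame:
        if ape not in APES:
            raise ValidationError(f"unknown ape {ape!r}")
        return self.nests[self.nests["ape"] == ape]

    def fecal_for(self, ape: str) -> pd.DataFrame:
        if ape not in APES:
            raise ValidationError(f"unknown ape {ape!r}")
        return self.fecal[self.fecal["ape"] == ape]
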