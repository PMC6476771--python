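"""Season-level fallback/preferred classification and the six consumption traits.

A fallback fruit is one an ape eats chiefly when overall fruit availability
is low.  Operationally, the four seasons are split into the two of higher
and the two of lower community-wide fruit availability (summed FAP), and a
taxon is a fallback *candidate* for an ape when

  (a) it fruits in at least three seasons,
  (b) its own availability follows the community (mean seasonal FAP higher
      in the high seasons), and
  (c) its consumption runs against it (mean seasonal MCS higher in the low
      seasons).

Final per-ape lists are sized at one third of the classified taxa, filling
the fallback list first (a taxon qualifying as both preferred and fallback
is assigned fallback), then the preferred list from the top of the GIS
ranking.  Per-ape statuses collapse deterministically onto one of six
consumption traits (Preferred/Fallback x gorilla/chimpanzee/apes) used as
the column unit of the habitat ordination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .core import SEASONS, SeasonCalendar, ValidationError

STATUSES = ("preferred", "fallback", "neither", "UC")

TRAITS = (
    "Preferred apes",
    "Preferred gorilla",
    "Preferred chimpanzee",
    "Fallback apes",
    "Fallback gorilla",
    "Fallback chimpanzee",
    "none",
)


def seasonal_totals(
    monthly: pd.DataFrame, calendar: SeasonCalendar
) -> pd.DataFrame:
    """Collapse a taxon x month table to taxon x season by summation."""
    season_of = {m: calendar.season_of(m) for m in monthly.columns}
    out = monthly.T.groupby([season_of[m] for m in monthly.columns]).sum().T
    return out.reindex(columns=SEASONS, fill_value=0.0)


def season_split(total_fap_by_season: pd.Series) -> tuple[list[str], list[str]]:
    """Split the four seasons into the two of higher and two of lower total FAP.

    Ties are broken by fixed season order (LDS, LRS, SDS, SRS) with a
    warning, so the split is always deterministic.
    """
    present = [s for s in SEASONS if s in total_fap_by_season.index]
    if len(present) < 4:
        raise ValidationError(
            f"season split needs all four seasons, have {present}"
        )
    totals = total_fap_by_season.reindex(list(SEASONS))
    if totals.duplicated().any():
        warnings.warn(
            "tied seasonal FAP totals; high/low split resolved by "
            "fixed season order", stacklevel=2,
        )
    # stable sort: ties keep canonical season order
    order = totals.sort_values(ascending=False, kind="stable").index
    return list(order[:2]), list(order[2:])


def fallback_candidates(
    fap_seasonal: pd.DataFrame,
    mcs_seasonal: pd.DataFrame,
    high_seasons: list[str],
    low_seasons: list[str],
    mcs_floor: float = 0.001,
) -> list[str]:
    """Taxa meeting the three fallback criteria for one ape.

    Taxa whose study-total MCS falls below *mcs_floor* are excluded as
    too rarely eaten to classify.  Candidacy is assessed from the FAP
    and MCS profiles alone, so a taxon can qualify even when its GIS is
    unclassified.
    """
    out = []
    for taxon in fap_seasonal.index:
        fap = fap_seasonal.loc[taxon]
        mcs = (
            mcs_seasonal.loc[taxon]
            if taxon in mcs_seasonal.index
            else pd.Series(0.0, index=fap.index)
        )
        if mcs.sum() < mcs_floor:
            continue
        fruiting_seasons = int((fap > 0).sum())
        if fruiting_seasons < 3:
            continue
        if not fap[high_seasons].mean() > fap[low_seasons].mean():
            continue
        if not mcs[low_seasons].mean() > mcs[high_seasons].mean():
            continue
        out.append(taxon)
    return out


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ApeLists:
    """Preferred and fallback taxon lists for one ape, with bookkeeping."""

    preferred: list[str]
    fallback: list[str]
    target: int
    dual: list[str] = field(default_factory=list)  # qualified as both
    uc_fallback: list[str] = field(default_factory=list)


def assign_lists(
    gis: pd.DataFrame,
    candidates: list[str],
    mcs_seasonal: pd.DataFrame,
    low_seasons: list[str],
) -> ApeLists:
    """Build the per-ape preferred and fallback lists.

    The list-size target is round(N/3) with N the number of classified
    taxa.  Fallback slots are filled before preferred ones; if more
    candidates exist than slots they are kept in order of descending
    low-season consumption.  The preferred list is then the top of the
    GIS ranking excluding fallback taxa.
    """
    classified = gis[gis["status"] == "classified"].sort_values("rank")
    n = len(classified)
    target = _round_half_away(n / 3.0)

    def low_mcs(t: str) -> float:
        if t in mcs_seasonal.index:
            return float(mcs_seasonal.loc[t, low_seasons].mean())
        return 0.0

    fallback = sorted(candidates, key=low_mcs, reverse=True)[:target]
    uc_fallback = [t for t in fallback if t not in classified.index]
    preferred = [t for t in classified.index if t not in fallback][:target]
    # taxa that also sit in the preferred zone (top round(N/3) by GIS) but
    # were claimed by the fallback list first
    preferred_zone = set(classified.index[:target])
    dual = [t for t in fallback if t in preferred_zone]
    return ApeLists(
        preferred=preferred,
        fallback=fallback,
        target=target,
        dual=dual,
        uc_fallback=uc_fallback,
    )


def collapse_trait(status_gorilla: str, status_chimpanzee: str) -> str:
    """Map a pair of per-ape statuses onto one of the six consumption traits.

    Both preferred -> "Preferred apes"; both fallback -> "Fallback apes";
    exactly one ape with a status (the other neither/UC) -> the single-ape
    trait.  The conflicting pair (preferred for one, fallback for the
    other) follows the fallback-first rule and collapses to the fallback
    ape's trait.  No status at all -> "none".
    """
    g, c = status_gorilla, status_chimpanzee
    for s in (g, c):
        if s not in STATUSES:
            raise ValidationError(f"unknown status {s!r}")
    if g == "fallback" and c == "fallback":
        return "Fallback apes"
    if g == "preferred" and c == "preferred":
        return "Preferred apes"
    if g == "fallback":
        return "Fallback gorilla"
    if c == "fallback":
        return "Fallback chimpanzee"
    if g == "preferred":
        return "Preferred gorilla"
    if c == "preferred":
        return "Preferred chimpanzee"
    return "none"


def assign_traits(
    scores: dict,
    calendar: SeasonCalendar,
    mcs_floor: float = 0.001,
) -> pd.DataFrame:
    """End-to-end trait assignment from a ``score_dataset`` result.

    Returns a frame indexed by taxon with ``status_gorilla``,
    ``status_chimpanzee`` and the collapsed ``trait`` column.
    """
    fap_seasonal = seasonal_totals(scores["fap"], calendar)
    high, low = season_split(fap_seasonal.sum(axis=0))

    statuses: dict[str, pd.Series] = {}
    lists: dict[str, ApeLists] = {}
    for ape in ("gorilla", "chimpanzee"):
        gis = scores[ape]["gis"]
        mcs_seasonal = seasonal_totals(scores[ape]["consumption"].mcs, calendar)
        candidates = fallback_candidates(
            fap_seasonal, mcs_seasonal, high, low, mcs_floor
        )
        al = assign_lists(gis, candidates, mcs_seasonal, low)
        lists[ape] = al
        status = pd.Series("neither", index=gis.index)
        status[gis["status"] != "classified"] = "UC"
        status[status.index.isin(al.preferred)] = "preferred"
        status[status.index.isin(al.fallback)] = "fallback"
        statuses[ape] = status

    taxa = sorted(set(statuses["gorilla"].index) | set(statuses["chimpanzee"].index))
    rows = []
    for t in taxa:
        g = statuses["gorilla"].get(t, "UC")
        c = statuses["chimpanzee"].get(t, "UC")
        rows.append(
            dict(taxon=t, status_gorilla=g, status_chimpanzee=c,
                 trait=collapse_trait(g, c))
        )
    out = pd.DataFrame(rows).set_index("taxon")
    out.attrs["high_seasons"] = high
    out.attrs["low_seasons"] = low
    out.attrs["lists"] = lists
    return out
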