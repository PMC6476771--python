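"""CSV readers and writers for the survey tables.

All tables are plain UTF-8 CSV with a header row.  Taxon aliasing
(collapsing congeners recorded under several raw names onto a single
genus-level aggregate, e.g. several *Landolphia* species onto
``Landolphia spp.``) happens at ingest via an optional ``aliases.csv``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import (
    DEFAULT_CALENDAR,
    DEFAULT_PLOT_AREA,
    SchemaError,
    SeasonCalendar,
    SurveyDataset,
)

SCHEMAS: dict[str, list[str]] = {
    "availability": ["transect_id", "position_m", "habitat"],
    "nests": ["ape", "month", "habitat", "group_id"],
    "fecal": ["sample_id", "ape", "month", "taxon", "seeds"],
    "phenology": [
        "individual_id", "taxon", "month", "dbh_cm",
        "score_unripe_tree", "score_ripe_tree",
        "score_unripe_ground", "score_ripe_ground",
    ],
    "plots": ["plot_id", "habitat", "taxon", "stems"],
    "taxa": ["taxon", "family", "mean_fruit_weight_g", "mean_seeds_per_fruit"],
}

DEFAULT_FILENAMES: dict[str, str] = {name: f"{name}.csv" for name in SCHEMAS}


def _read_table(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"{name} table not found at {path}")
    df = pd.read_csv(path)
    missing = [c for c in SCHEMAS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} ({path}): missing column(s) {missing}")
    return df[SCHEMAS[name]]


def _apply_aliases(df: pd.DataFrame, aliases: Mapping[str, str]) -> pd.DataFrame:
    if not aliases or "taxon" not in df.columns:
        return df
    out = df.copy()
    out["taxon"] = out["taxon"].map(lambda t: aliases.get(t, t))
    return out


def load_dataset(
    directory: str | Path,
    calendar: SeasonCalendar = DEFAULT_CALENDAR,
    plot_area: float = DEFAULT_PLOT_AREA,
    filenames: Mapping[str, str] | None = None,
) -> SurveyDataset:
    """Load the six CSV tables from *directory* into a validated bundle.

    An optional ``aliases.csv`` (columns ``raw_name, taxon``) in the same
    directory is applied to every taxon column before validation, so that
    genus-level aggregates are keyed consistently across tables.
    """
    directory = Path(directory)
    names = dict(DEFAULT_FILENAMES)
    if filenames:
        names.update(filenames)

    alias_path = directory / "aliases.csv"
    aliases: dict[str, str] = {}
    if alias_path.exists():
        adf = pd.read_csv(alias_path)
        for col in ("raw_name", "taxon"):
            if col not in adf.columns:
                raise SchemaError(f"aliases.csv: missing column {col!r}")
        aliases = dict(zip(adf["raw_name"], adf["taxon"]))

    tables = {
        name: _apply_aliases(_read_table(directory / names[name], name), aliases)
        for name in SCHEMAS
    }
    # an aliased fecal table may now contain duplicate (sample, taxon) rows
    if aliases:
        tables["fecal"] = (
            tables["fecal"]
            .groupby(["sample_id", "ape", "month", "taxon"], as_index=False)["seeds"]
            .sum()
        )
        tables["plots"] = (
            tables["plots"]
            .groupby(["plot_id", "habitat", "taxon"], as_index=False)["stems"]
            .sum()
        )

    ds = SurveyDataset(calendar=calendar, plot_area=plot_area, **tables)
    ds.validate()
    return ds


def write_dataset(dataset: SurveyDataset, directory: str | Path) -> dict[str, Path]:
    """Write all six tables as canonical CSVs; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in SCHEMAS:
        path = directory / DEFAULT_FILENAMES[name]
        getattr(dataset, name)[SCHEMAS[name]].to_csv(path, index=False)
        paths[name] = path
    return paths
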