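"""Fruit preference scoring from fecal seed counts, phenology and botanical plots.

The scoring stack estimates, per fruiting taxon, how strongly each ape
species prefers its fruit relative to how available that fruit was:

1.  Stem density        D_i   = sum_k n_ik / (K * S)            [stems / m^2]
2.  Fruit Availability  FAP_ij = (sum_n SS_nij * B_nij / N_i) * D_i
    Potential                                                    [score * m^2 / m^2]
    where SS_nij is the summed 0-2 fruiting score of monitored individual n
    in month j (four score components: unripe/ripe x tree/ground, so
    SS ranges 0-8), B_nij its basal area (m^2) and N_i the number of
    monitored individuals of taxon i.
3.  Fruit quantity      QF: seeds in a fecal sample are converted to
    fruit counts with the taxon's mean seeds per fruit (0 seeds -> 0
    fruits; fewer seeds than one fruit's worth -> 1 fruit; otherwise
    seeds/mean rounded *up*), then to grams with the mean fruit weight.
4.  Mean Consumption    MCS_ij = (QF_ij / sum_i QF_ij) * (Pf_ij / NPf_j)
    Score               -- the taxon's share of the reconstructed fruit
    mass that month, damped by the fraction of that month's fecal
    samples containing it.
5.  Global Importance   GIS_i = [sum_j MCS_ij / FAP_ij] / J * Pe_i
    Score               summed over months with FAP_ij > 0, with J the
    number of study months and Pe_i the number of months the taxon was
    consumed divided by the number of months it bore fruit.

Higher GIS means more preferred: heavy consumption despite (or relative
to) modest availability.  Taxa never seen fruiting in the phenology
survey cannot receive a score and are flagged UC (unclassified).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DEFAULT_PLOT_AREA, SurveyDataset, ValidationError

#: phenology score columns contributing to SS, in schema order
SCORE_COLS = (
    "score_unripe_tree",
    "score_ripe_tree",
    "score_unripe_ground",
    "score_ripe_ground",
)
RIPE_COLS = ("score_ripe_tree", "score_ripe_ground")


def stem_density(
    plots: pd.DataFrame, plot_area: float = DEFAULT_PLOT_AREA
) -> pd.Series:
    """Per-taxon stem density D_i = (total stems) / (K * S), stems per m^2.

    K counts *all* inventoried plots, including those where a taxon is
    absent, so a taxon's density reflects the whole surveyed area.
    """
    if plot_area <= 0:
        raise ValidationError(f"plot area must be positive, got {plot_area}")
    K = plots["plot_id"].nunique()
    if K < 1:
        raise ValidationError("need at least one botanical plot")
    totals = plots.groupby("taxon")["stems"].sum()
    return (totals / (K * plot_area)).rename("D")


def basal_area(dbh_cm: float | np.ndarray) -> float | np.ndarray:
    """Basal area in m^2 from diameter at breast height in cm."""
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh <= 0):
        raise ValidationError("dbh must be positive")
    out = np.pi * (dbh / 200.0) ** 2
    return float(out) if np.isscalar(dbh_cm) else out


def fap_table(
    phenology: pd.DataFrame,
    density: pd.Series,
    months: list[int] | None = None,
    ripe_only: bool = False,
) -> pd.DataFrame:
    """Fruit Availability Potential, taxon x month.

    Individuals not observed in a month contribute a score sum of zero
    but still count in N_i, so sparse monitoring lowers (never inflates)
    availability.  Taxa absent from the phenology table get no row: they
    are unclassifiable (UC), which is different from FAP = 0.  Taxa
    without a density estimate (never inventoried) get D = 0.
    """
    if months is None:
        months = sorted(phenology["month"].unique())
    cols = list(RIPE_COLS if ripe_only else SCORE_COLS)
    ph = phenology.copy()
    ph["SS"] = ph[cols].sum(axis=1)
    ph["B"] = basal_area(ph["dbh_cm"].to_numpy())
    ph["SSB"] = ph["SS"] * ph["B"]

    n_i = ph.groupby("taxon")["individual_id"].nunique()
    ssb = (
        ph.groupby(["taxon", "month"])["SSB"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(columns=months, fill_value=0.0)
    )
    d = density.reindex(ssb.index).fillna(0.0)
    fap = ssb.div(n_i, axis=0).mul(d, axis=0)
    fap.columns.name = "month"
    return fap


def fruit_quantity(
    seeds: int, mean_seeds_per_fruit: float, mean_fruit_weight_g: float
) -> float:
    """Grams of fruit implied by a per-sample seed count.

    Zero seeds is zero fruit; a partial fruit's worth of seeds is one
    fruit; otherwise the seed count divided by the mean seeds per fruit,
    rounded up to the next whole fruit.
    """
    if seeds < 0:
        raise ValidationError("seed count must be nonnegative")
    if not (mean_seeds_per_fruit >= 1 and mean_fruit_weight_g > 0):
        raise ValidationError("taxon lacks usable fruit trait values")
    if seeds == 0:
        fruits = 0
    elif seeds < mean_seeds_per_fruit:
        fruits = 1
    else:
        fruits = math.ceil(seeds / mean_seeds_per_fruit)
    return fruits * mean_fruit_weight_g


@dataclass
class ConsumptionTable:
    """Monthly consumption summaries for one ape species.

    All frames are taxon x month.  ``qf`` is reconstructed fruit mass in
    grams, ``pf`` the number of fecal samples containing the taxon,
    ``npf`` (month-indexed Series) the number of samples analysed, and
    ``mcs`` the Mean Consumption Score.  ``skipped`` lists taxa found in
    samples but excluded for lack of fruit trait values.
    """

    qf: pd.DataFrame
    pf: pd.DataFrame
    npf: pd.Series
    mcs: pd.DataFrame
    skipped: list[str]


def consumption_table(
    fecal: pd.DataFrame,
    taxa: pd.DataFrame,
    months: list[int] | None = None,
) -> ConsumptionTable:
    """QF and MCS for every (taxon, month) from one ape's fecal samples.

    Months where no reconstructed fruit mass exists at all yield MCS = 0
    for every taxon.  Taxa lacking trait values are skipped with a flag
    (their seed counts cannot be converted to mass) but still occupy
    samples, so NPf is unaffected.
    """
    if months is None:
        months = sorted(fecal["month"].unique())
    traits = taxa.set_index("taxon")[
        ["mean_fruit_weight_g", "mean_seeds_per_fruit"]
    ].dropna()

    npf = (
        fecal.groupby("month")["sample_id"]
        .nunique()
        .reindex(months, fill_value=0)
        .rename("NPf")
    )

    consumed = fecal[fecal["seeds"] > 0]
    skipped = sorted(set(consumed["taxon"]) - set(traits.index))
    usable = consumed[consumed["taxon"].isin(traits.index)].copy()

    if len(usable):
        spf = traits["mean_seeds_per_fruit"]
        wt = traits["mean_fruit_weight_g"]
        s = usable["seeds"].to_numpy(dtype=float)
        mean_s = usable["taxon"].map(spf).to_numpy(dtype=float)
        fruits = np.where(s < mean_s, 1.0, np.ceil(s / mean_s))
        usable["qf"] = fruits * usable["taxon"].map(wt).to_numpy(dtype=float)
    else:
        usable["qf"] = pd.Series(dtype=float)

    taxa_idx = sorted(set(usable["taxon"]))
    qf = (
        usable.groupby(["taxon", "month"])["qf"].sum()
        .unstack(fill_value=0.0)
        .reindex(index=taxa_idx, columns=months, fill_value=0.0)
    )
    pf = (
        usable.groupby(["taxon", "month"])["sample_id"].nunique()
        .unstack(fill_value=0)
        .reindex(index=taxa_idx, columns=months, fill_value=0)
    )

    month_mass = qf.sum(axis=0)
    share = qf.div(month_mass.where(month_mass > 0), axis=1).fillna(0.0)
    freq = pf.div(npf.where(npf > 0), axis=1).fillna(0.0)
    mcs = share * freq
    for frame in (qf, pf, mcs):
        frame.columns.name = "month"
        frame.index.name = "taxon"
    return ConsumptionTable(qf=qf, pf=pf, npf=npf, mcs=mcs, skipped=skipped)


def gis_table(
    mcs: pd.DataFrame,
    fap: pd.DataFrame,
    n_study_months: int | None = None,
    extra_uc_taxa: list[str] | None = None,
) -> pd.DataFrame:
    """Global Importance Score per taxon, with rank, Pe and status.

    The union of taxa from the consumption and availability tables is
    scored.  Taxa with no month of positive FAP (including taxa never
    monitored for phenology) are status UC and unranked.  For classified
    taxa the monthly ratio MCS/FAP is summed over fruiting months only;
    months with consumption but no measured availability are excluded
    from the sum yet still count in the Pe numerator, so Pe can exceed 1
    (the formula is applied literally, without clamping); such taxa are
    flagged in the ``pe_over_months`` column.  Ranks are descending by
    GIS; ties share order of appearance.
    """
    months = list(fap.columns)
    if n_study_months is None:
        n_study_months = len(months)
    if n_study_months < 1:
        raise ValidationError("need at least one study month")
    all_taxa = sorted(set(mcs.index) | set(fap.index) | set(extra_uc_taxa or []))
    mcs = mcs.reindex(index=all_taxa, columns=months, fill_value=0.0).fillna(0.0)
    fap_known = fap.reindex(columns=months, fill_value=0.0)

    rows = []
    for taxon in all_taxa:
        consumed_months = int((mcs.loc[taxon] > 0).sum())
        if taxon not in fap_known.index:
            rows.append(
                dict(taxon=taxon, GIS=np.nan, Pe=np.nan, status="UC",
                     fruiting_months=0, consumed_months=consumed_months,
                     pe_over=False)
            )
            continue
        f = fap_known.loc[taxon]
        fruiting = f > 0
        n_fruiting = int(fruiting.sum())
        if n_fruiting == 0:
            rows.append(
                dict(taxon=taxon, GIS=np.nan, Pe=np.nan, status="UC",
                     fruiting_months=0, consumed_months=consumed_months,
                     pe_over=False)
            )
            continue
        ratio_sum = float((mcs.loc[taxon][fruiting] / f[fruiting]).sum())
        pe = consumed_months / n_fruiting
        gis = ratio_sum / n_study_months * pe
        rows.append(
            dict(taxon=taxon, GIS=gis, Pe=pe, status="classified",
                 fruiting_months=n_fruiting, consumed_months=consumed_months,
                 pe_over=pe > 1.0)
        )
    out = pd.DataFrame(rows).set_index("taxon")
    classified = out[out["status"] == "classified"]
    ranks = classified["GIS"].rank(ascending=False, method="first")
    out["rank"] = ranks.reindex(out.index)
    return out.sort_values(["status", "rank"], ascending=[False, True])


def rank_preference(gis: pd.DataFrame) -> list[str]:
    """Taxa in descending preference order; UC taxa last, unranked.

    GIS values below 0.001 are displayed as 0 in reports but keep their
    underlying value for ranking.
    """
    classified = gis[gis["status"] == "classified"].sort_values("rank")
    uc = gis[gis["status"] != "classified"]
    return list(classified.index) + list(uc.index)


def score_dataset(
    dataset: SurveyDataset,
    n_study_months: int | None = None,
    ripe_only: bool = False,
) -> dict:
    """Run the full scoring stack on a dataset.

    Returns a dict with ``density`` (Series), ``fap`` (DataFrame) and,
    per ape, ``consumption`` (ConsumptionTable) and ``gis`` (DataFrame).
    """
    months = sorted(
        set(dataset.phenology["month"]) | set(dataset.fecal["month"])
    )
    if n_study_months is None:
        n_study_months = len(months)
    density = stem_density(dataset.plots, dataset.plot_area)
    fap = fap_table(dataset.phenology, density, months, ripe_only=ripe_only)
    out: dict = {"density": density, "fap": fap, "months": months}
    for ape in ("gorilla", "chimpanzee"):
        fec = dataset.fecal_for(ape)
        cons = consumption_table(fec, dataset.taxa, months)
        out[ape] = {
            "consumption": cons,
            "gis": gis_table(cons.mcs, fap, n_study_months,
                             extra_uc_taxa=cons.skipped),
        }
    return out
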