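"""Seeded synthetic survey datasets with known ground truth.

The generator emulates the field design the analysis assumes: transect
points sampled from fixed habitat proportions, botanical plots with
Poisson stem counts, roughly ten phenology individuals per taxon scored
monthly on the 0/1/2 scale, nests placed multinomially with habitat
probabilities proportional to availability times a true selectivity
ratio, and fecal samples whose per-taxon fruit counts are Poisson with
intensity proportional to (preference weight x that month's population
fruit availability).  That multiplicative coupling makes the Global
Importance Score proportional to the true preference weight in
expectation, which is what the parameter-recovery tests exploit.

Designed "fallback" taxa fruit in every season but have their
consumption preference boosted in the two seasons of low community-wide
fruit availability, reproducing the signature the trait classifier looks
for.  Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import APES, DEFAULT_CALENDAR, SEASONS, SeasonCalendar, SurveyDataset
from .scoring import fap_table, stem_density
from .traits import season_split

#: community-wide relative fruiting intensity by season: the long rainy
#: and short rainy seasons are the masting seasons, the dry seasons lean
DEFAULT_SEASON_INTENSITY = {"LDS": 0.35, "LRS": 1.0, "SDS": 0.55, "SRS": 0.9}

#: default true selectivity (unnormalised W'): gorillas prefer swamps and
#: shun mature forest, chimpanzees the reverse -- the classic contrast
DEFAULT_TRUE_WPRIME = {
    "gorilla": {"MF": 0.4, "YSF": 1.0, "LG": 1.2, "SW": 3.0, "RF": 1.0},
    "chimpanzee": {"MF": 2.5, "YSF": 0.4, "LG": 0.4, "SW": 1.0, "RF": 1.2},
}

DEFAULT_AVAILABILITY = {"MF": 0.45, "YSF": 0.20, "LG": 0.05, "SW": 0.18, "RF": 0.12}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study; defaults mirror the field design."""

    seed: int = 0
    months: tuple[int, ...] = tuple(range(1, 13))
    availability: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AVAILABILITY)
    )
    n_taxa: int = 20
    n_transects: int = 20
    points_per_transect: int = 120          # one point every 50 m on 6 km
    n_plots: int = 184
    plot_area: float = 625.0
    phenology_individuals: int = 10
    samples_per_month: int = 30             # fecal samples per ape per month
    nests_per_season: int = 500             # per ape
    n_fallback: int = 3
    fallback_boost: float = 5.0
    mean_fruits_per_sample: float = 8.0
    stem_rate_shape: float = 1.2            # Gamma shape for lambda draws
    stem_rate_scale: float = 1.5            # Gamma scale (stems/plot)
    dbh_log_mean: float = math.log(30.0)    # lognormal DBH, cm
    dbh_log_sd: float = 0.4
    fruit_weight_range: tuple[float, float] = (5.0, 80.0)
    seeds_per_fruit_range: tuple[int, int] = (1, 20)
    preference_log_sd: float = 1.2
    season_intensity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEASON_INTENSITY)
    )
    true_wprime: dict[str, dict[str, float]] = field(
        default_factory=lambda: {a: dict(w) for a, w in DEFAULT_TRUE_WPRIME.items()}
    )
    calendar: SeasonCalendar = field(default_factory=lambda: DEFAULT_CALENDAR)

    def validate(self) -> None:
        if any(w <= 0 for w in self.availability.values()):
            raise ValueError("availability weights must be positive")
        if not math.isclose(sum(self.availability.values()), 1.0, abs_tol=1e-9):
            raise ValueError("availability weights must sum to 1")
        for name in ("n_taxa", "n_transects", "points_per_transect", "n_plots",
                     "phenology_individuals", "samples_per_month",
                     "nests_per_season"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_fallback >= self.n_taxa:
            raise ValueError("n_fallback must be smaller than n_taxa")


@dataclass
class GroundTruth:
    """Generating parameters needed by the recovery tests."""

    preference: dict[str, dict[str, float]]       # ape -> taxon -> weight
    preference_rank: dict[str, list[str]]         # ape -> taxa best-first
    fallback_taxa: list[str]
    true_wprime: dict[str, dict[str, float]]      # normalised to sum to m
    selection_class: dict[str, dict[str, str]]    # ape -> habitat -> class
    high_seasons: list[str]
    low_seasons: list[str]
    stem_rates: dict[str, dict[str, float]]       # taxon -> habitat -> lambda
    config: dict


def _normalised_wprime(raw: dict[str, float]) -> dict[str, float]:
    m = len(raw)
    total = sum(raw.values())
    return {h: m * w / total for h, w in raw.items()}


def generate(config: GeneratorConfig) -> tuple[SurveyDataset, GroundTruth]:
    """Draw one complete synthetic dataset plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    habitats = list(config.availability)
    plot_habitats = [h for h in habitats if h != "LG"]
    taxa_names = [f"T{i + 1:02d}" for i in range(config.n_taxa)]
    fallback_taxa = taxa_names[: config.n_fallback]
    months = list(config.months)
    cal = config.calendar

    # --- availability points --------------------------------------------
    weights = np.array([config.availability[h] for h in habitats])
    codes = rng.choice(len(habitats), size=config.n_transects * config.points_per_transect,
                       p=weights)
    availability = pd.DataFrame(
        {
            "transect_id": np.repeat(
                [f"TR{t + 1:02d}" for t in range(config.n_transects)],
                config.points_per_transect,
            ),
            "position_m": np.tile(
                np.arange(config.points_per_transect) * 50.0, config.n_transects
            ),
            "habitat": [habitats[c] for c in codes],
        }
    )

    # --- botanical plots -------------------------------------------------
    pw = np.array([config.availability[h] for h in plot_habitats])
    pw = pw / pw.sum()
    plot_hab = rng.choice(len(plot_habitats), size=config.n_plots, p=pw)
    lam = rng.gamma(
        config.stem_rate_shape,
        config.stem_rate_scale,
        size=(config.n_taxa, len(plot_habitats)),
    )
    plot_rows = []
    for k in range(config.n_plots):
        h = plot_hab[k]
        stems = rng.poisson(lam[:, h])
        for t, s in enumerate(stems):
            if s > 0:
                plot_rows.append(
                    (f"P{k + 1:03d}", plot_habitats[h], taxa_names[t], int(s))
                )
    plots = pd.DataFrame(
        plot_rows, columns=["plot_id", "habitat", "taxon", "stems"]
    )
    stem_rates = {
        taxa_names[t]: {plot_habitats[h]: float(lam[t, h])
                        for h in range(len(plot_habitats))}
        for t in range(config.n_taxa)
    }

    # --- phenology --------------------------------------------------------
    base = rng.uniform(0.4, 0.9, size=config.n_taxa)
    jitter = rng.uniform(0.6, 1.4, size=(config.n_taxa, len(SEASONS)))
    f_ts = np.empty((config.n_taxa, len(SEASONS)))
    for si, season in enumerate(SEASONS):
        f_ts[:, si] = base * config.season_intensity[season] * jitter[:, si]
    # designed fallback taxa fruit in every season and track the community
    # seasonal pattern, so criteria (a) and (b) hold by construction
    for i in range(config.n_fallback):
        for si, season in enumerate(SEASONS):
            f_ts[i, si] = 0.75 * config.season_intensity[season] + 0.2
    f_ts = np.clip(f_ts, 0.0, 1.0)

    dbh = rng.lognormal(
        config.dbh_log_mean, config.dbh_log_sd,
        size=(config.n_taxa, config.phenology_individuals),
    )
    ph_rows = []
    for t in range(config.n_taxa):
        for n in range(config.phenology_individuals):
            iid = f"{taxa_names[t]}-{n + 1:02d}"
            for month in months:
                f = f_ts[t, SEASONS.index(cal.season_of(month))]
                p = np.array([1.0 - 0.9 * f, 0.4 * f, 0.5 * f])
                scores = rng.choice(3, size=4, p=p)
                ph_rows.append(
                    (iid, taxa_names[t], month, round(float(dbh[t, n]), 1),
                     *scores.tolist())
                )
    phenology = pd.DataFrame(
        ph_rows,
        columns=[
            "individual_id", "taxon", "month", "dbh_cm",
            "score_unripe_tree", "score_ripe_tree",
            "score_unripe_ground", "score_ripe_ground",
        ],
    )

    # --- fruit traits -----------------------------------------------------
    wlo, whi = config.fruit_weight_range
    slo, shi = config.seeds_per_fruit_range
    weights_g = np.round(rng.uniform(wlo, whi, size=config.n_taxa), 1)
    seeds_pf = rng.integers(slo, shi + 1, size=config.n_taxa)
    taxa = pd.DataFrame(
        {
            "taxon": taxa_names,
            "family": [f"Fam{(i % 7) + 1}" for i in range(config.n_taxa)],
            "mean_fruit_weight_g": weights_g,
            "mean_seeds_per_fruit": seeds_pf.astype(float),
        }
    )

    # --- population fruit availability (drives consumption) ---------------
    density = stem_density(plots, config.plot_area)
    fap = fap_table(phenology, density, months)
    fap_seasonal_total = (
        fap.T.groupby([cal.season_of(m) for m in fap.columns]).sum().T.sum(axis=0)
    )
    high, low = season_split(fap_seasonal_total.reindex(list(SEASONS), fill_value=0.0))

    # --- nests ------------------------------------------------------------
    norm_w = {a: _normalised_wprime(config.true_wprime[a]) for a in APES}
    nest_rows = []
    for ape in APES:
        probs = np.array(
            [config.availability[h] * norm_w[ape][h] for h in habitats]
        )
        probs = probs / probs.sum()
        for season in SEASONS:
            smonths = [m for m in cal.months_of(season) if m in months]
            if not smonths:
                continue
            hab_draw = rng.choice(len(habitats), size=config.nests_per_season, p=probs)
            month_draw = rng.choice(smonths, size=config.nests_per_season)
            for j in range(config.nests_per_season):
                nest_rows.append(
                    (ape, int(month_draw[j]), habitats[hab_draw[j]],
                     f"{ape[:1]}{season}{j + 1:04d}")
                )
    nests = pd.DataFrame(nest_rows, columns=["ape", "month", "habitat", "group_id"])

    # --- fecal samples ----------------------------------------------------
    pref = {
        ape: rng.lognormal(0.0, config.preference_log_sd, size=config.n_taxa)
        for ape in APES
    }
    fap_m = fap.reindex(taxa_names).fillna(0.0)
    fecal_rows = []
    for ape in APES:
        for month in months:
            season = cal.season_of(month)
            boost = np.ones(config.n_taxa)
            if season in low:
                boost[: config.n_fallback] = config.fallback_boost
            intensity = pref[ape] * boost * fap_m[month].to_numpy()
            total = intensity.sum()
            if total > 0:
                intensity = intensity / total * config.mean_fruits_per_sample
            for s in range(config.samples_per_month):
                sid = f"{ape[:1]}{month:02d}s{s + 1:03d}"
                fruits = rng.poisson(intensity)
                any_row = False
                for t in np.flatnonzero(fruits):
                    fecal_rows.append(
                        (sid, ape, month, taxa_names[t],
                         int(fruits[t] * seeds_pf[t]))
                    )
                    any_row = True
                if not any_row:     # empty sample still counts in NPf
                    fecal_rows.append((sid, ape, month, taxa_names[0], 0))
    fecal = pd.DataFrame(
        fecal_rows, columns=["sample_id", "ape", "month", "taxon", "seeds"]
    )

    dataset = SurveyDataset(
        availability=availability,
        nests=nests,
        fecal=fecal,
        phenology=phenology,
        plots=plots,
        taxa=taxa,
        calendar=cal,
        plot_area=config.plot_area,
    )

    def classify(w: float) -> str:
        if w > 1.0:
            return "preferred"
        if w < 1.0:
            return "avoided"
        return "proportional"

    truth = GroundTruth(
        preference={
            ape: dict(zip(taxa_names, map(float, pref[ape]))) for ape in APES
        },
        preference_rank={
            ape: [taxa_names[i] for i in np.argsort(-pref[ape])] for ape in APES
        },
        fallback_taxa=fallback_taxa,
        true_wprime=norm_w,
        selection_class={
            ape: {h: classify(norm_w[ape][h]) for h in habitats} for ape in APES
        },
        high_seasons=high,
        low_seasons=low,
        stem_rates=stem_rates,
        config={
            k: v for k, v in asdict(config).items() if k != "calendar"
        },
    )
    return dataset, truth


# --------------------------------------------------------------- toy fixture

#: DBH values (cm) whose basal areas are exactly 0.10, 0.05 and 0.20 m^2
_DBH_B010 = 200.0 * math.sqrt(0.10 / math.pi)
_DBH_B005 = 200.0 * math.sqrt(0.05 / math.pi)
_DBH_B020 = 200.0 * math.sqrt(0.20 / math.pi)


def make_toy_fixture() -> tuple[SurveyDataset, dict]:
    """A tiny two-habitat, four-month dataset with hand-computed expectations.

    Two scorable taxa (A, B), one taxon (C) present in feces but lacking
    trait data, ten availability points per habitat, and gorilla nests
    concentrated in mature forest.  The returned dict holds the expected
    density, FAP, QF, MCS, GIS and selectivity values, all derived by
    direct hand substitution into the formulas.
    """
    availability = pd.DataFrame(
        {
            "transect_id": ["TR1"] * 20,
            "position_m": [50.0 * i for i in range(20)],
            "habitat": ["MF"] * 10 + ["SW"] * 10,
        }
    )
    nests = pd.DataFrame(
        {
            "ape": ["gorilla"] * 20,
            "month": [1] * 10 + [2] * 10,
            "habitat": ["MF"] * 15 + ["SW"] * 5,
            "group_id": [f"g{i}" for i in range(20)],
        }
    )
    plots = pd.DataFrame(
        [
            ("P1", "MF", "A", 6),
            ("P3", "SW", "A", 4),
            ("P2", "MF", "B", 3),
            ("P4", "SW", "B", 2),
        ],
        columns=["plot_id", "habitat", "taxon", "stems"],
    )

    def ph(iid, taxon, month, dbh, ss):
        # decompose a score sum into four components, each 0-2
        comps = [0, 0, 0, 0]
        for i in range(ss):
            comps[i % 4] += 1
        return (iid, taxon, month, dbh, *comps)

    phenology = pd.DataFrame(
        [
            ph("a1", "A", 1, _DBH_B010, 4), ph("a2", "A", 1, _DBH_B005, 2),
            ph("a1", "A", 2, _DBH_B010, 2), ph("a2", "A", 2, _DBH_B005, 0),
            ph("a1", "A", 3, _DBH_B010, 0), ph("a2", "A", 3, _DBH_B005, 0),
            ph("a1", "A", 4, _DBH_B010, 4), ph("a2", "A", 4, _DBH_B005, 4),
            ph("b1", "B", 1, _DBH_B020, 0),
            ph("b1", "B", 2, _DBH_B020, 2),
            ph("b1", "B", 3, _DBH_B020, 4),
            ph("b1", "B", 4, _DBH_B020, 0),
        ],
        columns=[
            "individual_id", "taxon", "month", "dbh_cm",
            "score_unripe_tree", "score_ripe_tree",
            "score_unripe_ground", "score_ripe_ground",
        ],
    )
    fecal = pd.DataFrame(
        [
            # gorilla month 1: four samples
            ("g1s1", "gorilla", 1, "A", 12),
            ("g1s2", "gorilla", 1, "A", 3),
            ("g1s3", "gorilla", 1, "A", 7),
            ("g1s4", "gorilla", 1, "A", 0),
            ("g1s4", "gorilla", 1, "C", 6),     # taxon without trait data
            # gorilla month 2: two samples
            ("g2s1", "gorilla", 2, "A", 5),
            ("g2s2", "gorilla", 2, "B", 4),
            # gorilla month 3: two samples
            ("g3s1", "gorilla", 3, "B", 2),
            ("g3s2", "gorilla", 3, "B", 5),
            # gorilla month 4: two samples, nothing consumed
            ("g4s1", "gorilla", 4, "A", 0),
            ("g4s2", "gorilla", 4, "A", 0),
            # chimpanzee month 1: one sample
            ("c1s1", "chimpanzee", 1, "A", 5),
        ],
        columns=["sample_id", "ape", "month", "taxon", "seeds"],
    )
    taxa = pd.DataFrame(
        {
            "taxon": ["A", "B"],
            "family": ["FamA", "FamB"],
            "mean_fruit_weight_g": [20.0, 10.0],
            "mean_seeds_per_fruit": [5.0, 2.0],
        }
    )
    dataset = SurveyDataset(
        availability=availability,
        nests=nests,
        fecal=fecal,
        phenology=phenology,
        plots=plots,
        taxa=taxa,
    )
    expected = {
        "months": [1, 2, 3, 4],
        "density": {"A": 0.004, "B": 0.002},
        "fap": {
            "A": {1: 0.001, 2: 0.0004, 3: 0.0, 4: 0.0012},
            "B": {1: 0.0, 2: 0.0008, 3: 0.0016, 4: 0.0},
        },
        "qf_gorilla": {
            "A": {1: 120.0, 2: 20.0},
            "B": {2: 20.0, 3: 40.0},
        },
        "mcs_gorilla": {
            "A": {1: 0.75, 2: 0.25, 3: 0.0, 4: 0.0},
            "B": {1: 0.0, 2: 0.25, 3: 1.0, 4: 0.0},
        },
        # A: (750 + 625)/4 * 2/3 ; B: (312.5 + 625)/4 * 1
        "gis_gorilla": {"A": 1375.0 / 4.0 * (2.0 / 3.0), "B": 937.5 / 4.0},
        "pe_gorilla": {"A": 2.0 / 3.0, "B": 1.0},
        "rank_gorilla": {"B": 1, "A": 2},
        # chimp: single sample of A in month 1 -> MCS 1, ratio 1000
        "gis_chimpanzee": {"A": 1000.0 / 4.0 * (1.0 / 3.0), "B": 0.0},
        "unclassifiable": {"C"},
        # nests (15 MF, 5 SW) on p = (0.5, 0.5): w = (1.5, 0.5)
        "wprime_gorilla_LDS": {"MF": 1.5, "SW": 0.5},
        "chi2_gorilla_LDS": 5.0,
        "df_gorilla_LDS": 1,
    }
    return dataset, expected
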