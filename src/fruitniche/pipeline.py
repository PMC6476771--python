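"""One-command orchestration: load -> selection -> scoring -> traits -> ordination.

Every output table is a CSV stamped (via the run log) with the config
hash that produced it, and the log records every exclusion the analysis
makes (empty plots, unclassifiable taxa, skipped samples) because those
counts are part of the reported results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import DEFAULT_CALENDAR, SeasonCalendar, SurveyDataset
from .io import load_dataset
from .ordination import (
    bray_curtis,
    build_contingency,
    correspondence_analysis,
    dispersion_homogeneity,
    permanova,
)
from .scoring import score_dataset
from .selection import seasonal_selection, selection_to_frame
from .traits import assign_traits, seasonal_totals


@dataclass
class RunConfig:
    """Settings for a full pipeline run."""

    input_dir: str
    output_dir: str
    alpha: float = 0.05
    n_study_months: int | None = None
    mcs_floor: float = 0.001
    ripe_only: bool = False
    permutations: int = 999
    seed: int = 0
    nest_unit: str = "nest"
    calendar: SeasonCalendar = field(default_factory=lambda: DEFAULT_CALENDAR)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "calendar" in raw:
            raw["calendar"] = SeasonCalendar(
                {int(k): v for k, v in raw["calendar"].items()}
            )
        return cls(**raw)

    def digest(self) -> str:
        payload = {
            k: (v.months if isinstance(v, SeasonCalendar) else v)
            for k, v in self.__dict__.items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_all(config: RunConfig, dataset: SurveyDataset | None = None) -> dict:
    """Execute the full analysis; write all output tables; return results.

    Any stage failure is re-raised annotated with the stage name so a
    caller can report where the pipeline stopped.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config_hash: {config.digest()}"]
    results: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    if dataset is None:
        dataset = stage("load")(
            lambda: load_dataset(config.input_dir, calendar=config.calendar)
        )
    for w in dataset.validate():
        log.append(f"load: {w}")
    results["dataset"] = dataset

    # --- habitat selection ------------------------------------------------
    def _selection():
        res = {}
        for ape in ("gorilla", "chimpanzee"):
            seasonal = seasonal_selection(
                dataset, ape, alpha=config.alpha, unit=config.nest_unit
            )
            frame = selection_to_frame(seasonal)
            frame.to_csv(out / f"selection_{ape}.csv", index=False)
            res[ape] = seasonal
        return res

    results["selection"] = stage("selection")(_selection)

    # --- diet scoring -----------------------------------------------------
    def _scores():
        scores = score_dataset(
            dataset, n_study_months=config.n_study_months,
            ripe_only=config.ripe_only,
        )
        scores["density"].rename("D").to_csv(out / "density.csv")
        scores["fap"].to_csv(out / "fap.csv")
        for ape in ("gorilla", "chimpanzee"):
            scores[ape]["consumption"].mcs.to_csv(out / f"mcs_{ape}.csv")
            scores[ape]["gis"].to_csv(out / f"gis_{ape}.csv")
            for t in scores[ape]["consumption"].skipped:
                log.append(f"scoring[{ape}]: taxon {t!r} skipped (no trait data)")
        return scores

    scores = stage("scoring")(_scores)
    results["scores"] = scores

    # --- consumption traits ----------------------------------------------
    def _traits():
        assignment = assign_traits(
            scores, dataset.calendar, mcs_floor=config.mcs_floor
        )
        assignment.to_csv(out / "traits.csv")
        log.append(f"traits: high seasons {assignment.attrs['high_seasons']}, "
                   f"low seasons {assignment.attrs['low_seasons']}")
        for ape, al in assignment.attrs["lists"].items():
            log.append(
                f"traits[{ape}]: target {al.target}, "
                f"{len(al.fallback)} fallback, {len(al.preferred)} preferred, "
                f"dual {al.dual}, uc_fallback {al.uc_fallback}"
            )
        return assignment

    assignment = stage("traits")(_traits)
    results["traits"] = assignment

    # --- ordination -------------------------------------------------------
    def _ordination():
        res = {}
        for by, fname in (("trait", "ca_traits"), ("taxon", "ca_species")):
            table, n_excl = build_contingency(dataset.plots, assignment, by=by)
            log.append(f"ordination[{by}]: {n_excl} empty plots excluded")
            ca = correspondence_analysis(table)
            coords = pd.concat(
                [ca.row_coords.assign(kind="habitat"),
                 ca.col_coords.assign(kind=by)]
            )
            coords.to_csv(out / f"{fname}.csv")
            ca.deviations.to_csv(out / f"{fname}_deviations.csv")
            res[by] = {"table": table, "ca": ca, "n_excluded": n_excl}

        # seasonal dissimilarity tests on monthly profiles (months as rows)
        season_rows = []
        cal = dataset.calendar
        for label, matrix in (
            ("FAP", scores["fap"]),
            ("MCS_gorilla", scores["gorilla"]["consumption"].mcs),
            ("MCS_chimpanzee", scores["chimpanzee"]["consumption"].mcs),
        ):
            prof = matrix.T            # months x taxa
            groups = [cal.season_of(m) for m in prof.index]
            if min(pd.Series(groups).value_counts()) < 2:
                log.append(f"ordination[{label}]: skipped (singleton season)")
                continue
            dist = bray_curtis(prof)
            pa = permanova(dist, groups, n_perm=config.permutations,
                           seed=config.seed)
            dh = dispersion_homogeneity(dist, groups,
                                        n_perm=config.permutations,
                                        seed=config.seed)
            season_rows.append(
                dict(matrix=label, pseudo_F=pa.statistic, p=pa.p_value,
                     dispersion_F=dh.statistic, dispersion_p=dh.p_value,
                     permutations=config.permutations)
            )
        pd.DataFrame(season_rows).to_csv(out / "permanova.csv", index=False)
        res["seasonal_tests"] = season_rows
        return res

    results["ordination"] = stage("ordination")(_ordination)

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    results["log"] = log
    return results
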