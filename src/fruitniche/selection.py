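"""Design-1 resource-selection analysis of nest counts against habitat availability.

Selection is quantified with the standardised Manly selectivity ratio

    W_i  = (r_i / p_i) / sum_j (r_j / p_j),        W'_i = m * W_i,

where ``r_i`` is the proportion of nests built in habitat *i*, ``p_i`` the
proportion of that habitat available along the transects, and ``m`` the
number of habitat types.  ``W'`` compares use against proportionality:
values above 1 indicate preference, below 1 avoidance.  A global
chi-square goodness-of-fit test of observed nest counts against expected
counts under proportional use gates the per-habitat calls; individual
habitats are then classified with Bonferroni-adjusted confidence
intervals on W' (preferred when the lower bound exceeds 1, avoided when
the upper bound is below 1, otherwise proportional).

Availability is treated as known (design 1: observations at the
population level, animals not individually identified), so the sampling
variance of the unstandardised ratio ``w_i = r_i / p_i`` is
``r_i (1 - r_i) / (n p_i^2)`` with *n* the total nest count; the
standard error of W' follows by the same normalisation and scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import HABITATS, SEASONS, SurveyDataset, ValidationError

CLASSES = ("preferred", "avoided", "proportional")


@dataclass
class SelectionResult:
    """Per-habitat selectivity ratios with the global goodness-of-fit test.

    ``table`` has one row per habitat with columns
    ``habitat, count, r, p, W, W_prime, se, ci_low, ci_high, class``.
    """

    table: pd.DataFrame
    m: int
    n: int
    chi2: float
    df: int
    p_value: float
    alpha: float

    def wprime(self) -> pd.Series:
        return self.table.set_index("habitat")["W_prime"]

    def classes(self) -> pd.Series:
        return self.table.set_index("habitat")["class"]


def availability_proportions(points: pd.DataFrame) -> pd.Series:
    """Proportion of survey points per habitat (p_i), indexed by habitat code.

    Habitats absent from the points are reported with p = 0 so that the
    caller can see (and be warned about) the zero-availability flag.
    """
    if len(points) == 0:
        raise ValidationError("availability: need at least one survey point")
    counts = points["habitat"].value_counts()
    props = counts.reindex(HABITATS, fill_value=0) / counts.sum()
    return props.rename("p")


def chi_square_gof(
    nest_counts: Mapping[str, int], availability: Mapping[str, float]
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of nest counts against proportional use.

    chi2 = sum_i (o_i - n p_i)^2 / (n p_i) over habitats with p_i > 0;
    df = (#habitats with p_i > 0) - 1; p from the upper tail.
    """
    habitats = [h for h, p in availability.items() if p > 0]
    for h, o in nest_counts.items():
        if o > 0 and availability.get(h, 0.0) == 0.0:
            raise ValidationError(
                f"habitat {h!r} has zero availability but {o} nests"
            )
    o = np.array([nest_counts.get(h, 0) for h in habitats], dtype=float)
    p = np.array([availability[h] for h in habitats], dtype=float)
    p = p / p.sum()
    n = o.sum()
    if n == 0:
        raise ValidationError("zero total nests")
    expected = n * p
    chi2 = float(((o - expected) ** 2 / expected).sum())
    df = len(habitats) - 1
    p_value = float(stats.chi2.sf(chi2, df))
    return chi2, df, p_value


def manly_selection(
    nest_counts: Mapping[str, int],
    availability: Mapping[str, float],
    alpha: float = 0.05,
) -> SelectionResult:
    """Compute standardised selectivity ratios and classify each habitat.

    Habitats with zero availability and zero use are dropped from the
    analysis; zero availability with nonzero use is rejected.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    chi2, df, p_value = chi_square_gof(nest_counts, availability)

    habitats = [h for h, p in availability.items() if p > 0]
    o = np.array([nest_counts.get(h, 0) for h in habitats], dtype=float)
    p = np.array([availability[h] for h in habitats], dtype=float)
    p = p / p.sum()
    n = o.sum()
    m = len(habitats)

    r = o / n
    w = r / p                     # unstandardised use/availability ratio
    sum_w = w.sum()
    W = w / sum_w
    W_prime = m * W

    # design-1 variance with availability known, propagated through the
    # shared normalisation (denominator treated as fixed)
    var_w = r * (1.0 - r) / (n * p**2)
    se = m * np.sqrt(var_w) / sum_w

    z = stats.norm.ppf(1.0 - alpha / (2.0 * m))   # Bonferroni, family size m
    ci_low = W_prime - z * se
    ci_high = W_prime + z * se

    table = pd.DataFrame(
        {
            "habitat": habitats,
            "count": o.astype(int),
            "r": r,
            "p": p,
            "W": W,
            "W_prime": W_prime,
            "se": se,
            "ci_low": ci_low,
            "ci_high": ci_high,
        }
    )
    result = SelectionResult(
        table=table, m=m, n=int(n), chi2=chi2, df=df, p_value=p_value, alpha=alpha
    )
    result.table["class"] = classify_selection(result, alpha)
    return result


def classify_selection(result: SelectionResult, alpha: float = 0.05) -> list[str]:
    """Per-habitat preference call from the Bonferroni CIs on W'.

    Any non-proportional call requires the global chi-square to be
    significant at *alpha*; otherwise all habitats are proportional.
    """
    if result.p_value > alpha:
        return ["proportional"] * len(result.table)
    out = []
    for _, row in result.table.iterrows():
        if row["ci_low"] > 1.0:
            out.append("preferred")
        elif row["ci_high"] < 1.0:
            out.append("avoided")
        else:
            out.append("proportional")
    return out


def seasonal_selection(
    dataset: SurveyDataset,
    ape: str,
    alpha: float = 0.05,
    unit: str = "nest",
) -> dict[str, SelectionResult]:
    """One SelectionResult per season for *ape*, stratified by nest month.

    ``unit`` selects the counting unit: individual nests (default) or
    nest groups (one count per distinct ``group_id`` per habitat).
    Seasons without any nests are absent from the result, not zeroed.
    """
    if unit not in ("nest", "group"):
        raise ValidationError(f"unit must be 'nest' or 'group', got {unit!r}")
    nests = dataset.nests_for(ape).copy()
    availability = availability_proportions(dataset.availability)
    nests["season"] = nests["month"].map(dataset.calendar.season_of)

    results: dict[str, SelectionResult] = {}
    for season in SEASONS:
        sub = nests[nests["season"] == season]
        if len(sub) == 0:
            continue
        if unit == "group":
            sub = sub.drop_duplicates(subset=["group_id", "habitat"])
        counts = sub["habitat"].value_counts().to_dict()
        results[season] = manly_selection(counts, availability.to_dict(), alpha)
    return results


def selection_to_frame(results: dict[str, SelectionResult]) -> pd.DataFrame:
    """Flatten seasonal results to one tidy frame (for CSV output)."""
    rows = []
    for season, res in results.items():
        for _, row in res.table.iterrows():
            rows.append(
                {
                    "season": season,
                    **row.to_dict(),
                    "chi2": res.chi2,
                    "df": res.df,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
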