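"""The scoring stack: density, basal area, FAP, QF, MCS and GIS."""

import math

import numpy as np
import pandas as pd
import pytest

from fruitniche import (
    ValidationError,
    basal_area,
    consumption_table,
    fap_table,
    fruit_quantity,
    gis_table,
    rank_preference,
    score_dataset,
    stem_density,
)


def test_stem_density_counts_all_plots():
    """K includes plots where the taxon is absent: 10 stems / (4*625)."""
    plots = pd.DataFrame(
        [("P1", "MF", "A", 6), ("P2", "MF", "B", 1),
         ("P3", "SW", "A", 4), ("P4", "SW", "B", 2)],
        columns=["plot_id", "habitat", "taxon", "stems"],
    )
    d = stem_density(plots)
    assert d["A"] == pytest.approx(10 / 2500)
    assert d["B"] == pytest.approx(3 / 2500)
    with pytest.raises(ValidationError):
        stem_density(plots, plot_area=0)


def test_basal_area_formula_and_scaling():
    assert basal_area(10.0) == pytest.approx(math.pi * 0.05**2)
    assert basal_area(20.0) == pytest.approx(4 * basal_area(10.0))
    assert basal_area(1e-6) < 1e-12
    with pytest.raises(ValidationError):
        basal_area(0.0)


def test_fap_direct_substitution(toy):
    """Two monitored stems (SS,B)=(4,0.10),(2,0.05), D=0.004 -> 0.001."""
    dataset, expected = toy
    density = stem_density(dataset.plots)
    fap = fap_table(dataset.phenology, density, months=[1, 2, 3, 4])
    for taxon, by_month in expected["fap"].items():
        for month, val in by_month.items():
            assert fap.loc[taxon, month] == pytest.approx(val, abs=1e-15)
    # taxon never found in phenology has no FAP row at all (UC, not zero)
    assert "C" not in fap.index


@pytest.mark.parametrize(
    "seeds,mean_seeds,weight,expected",
    [
        (12, 5, 20.0, 60.0),     # ceil(2.4) = 3 fruits
        (3, 5, 20.0, 20.0),      # partial fruit's worth -> 1 fruit
        (0, 5, 20.0, 0.0),
        (5, 5, 20.0, 20.0),      # exactly one fruit
        (10, 3, 7.5, 30.0),      # ceil(10/3) = 4 fruits
        (1, 1, 2.0, 2.0),
    ],
)
def test_fruit_quantity_reconstruction(seeds, mean_seeds, weight, expected):
    assert fruit_quantity(seeds, mean_seeds, weight) == expected


def test_fruit_quantity_rejects_missing_traits():
    with pytest.raises(ValidationError):
        fruit_quantity(5, float("nan"), 20.0)


def test_mcs_direct_substitution():
    """QF share 0.75 x sample frequency 0.75 = 0.5625."""
    fecal = pd.DataFrame(
        [("s1", "gorilla", 1, "A", 10), ("s2", "gorilla", 1, "A", 10),
         ("s3", "gorilla", 1, "A", 10), ("s4", "gorilla", 1, "B", 20),
         ("s4", "gorilla", 1, "A", 0)],
        columns=["sample_id", "ape", "month", "taxon", "seeds"],
    )
    taxa = pd.DataFrame(
        {"taxon": ["A", "B"], "family": ["f", "f"],
         "mean_fruit_weight_g": [100.0, 100.0],
         "mean_seeds_per_fruit": [10.0, 20.0]},
    )
    cons = consumption_table(fecal, taxa, months=[1])
    # A: 3 samples x 1 fruit x 100 g = 300 of 400 g total, in 3 of 4 samples
    assert cons.qf.loc["A", 1] == 300.0
    assert cons.mcs.loc["A", 1] == pytest.approx(0.75 * 0.75)
    # B: only taxon in its sample: share 0.25, freq 0.25
    assert cons.mcs.loc["B", 1] == pytest.approx(0.0625)


def test_mcs_bounds_and_share_identity(small_dataset):
    """Shares sum to 1 in consuming months; MCS <= Pf/NPf everywhere."""
    dataset, _ = small_dataset
    scores = score_dataset(dataset)
    for ape in ("gorilla", "chimpanzee"):
        cons = scores[ape]["consumption"]
        share = cons.qf.div(cons.qf.sum(axis=0), axis=1)
        sums = share.sum(axis=0).dropna()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        freq = cons.pf.div(cons.npf, axis=1)
        assert ((cons.mcs <= freq + 1e-12).all()).all()
        assert ((cons.mcs >= 0) & (cons.mcs <= 1)).all().all()


def test_gis_direct_substitution():
    """Ratios {10,20}, J=12, 4 fruiting months, 2 consumed -> GIS 1.25."""
    months = list(range(1, 13))
    fap = pd.DataFrame(
        {m: [0.1 if m <= 4 else 0.0] for m in months}, index=["A"]
    )
    mcs = pd.DataFrame({m: [0.0] for m in months}, index=["A"])
    mcs[1] = 1.0    # 1.0 / 0.1 = 10
    mcs[2] = 2.0    # 2.0 / 0.1 = 20
    gis = gis_table(mcs, fap, n_study_months=12)
    assert gis.loc["A", "GIS"] == pytest.approx(1.25)
    assert gis.loc["A", "Pe"] == pytest.approx(0.5)


def test_gis_toy_fixture_exact(toy):
    dataset, expected = toy
    scores = score_dataset(dataset, n_study_months=4)
    for ape in ("gorilla", "chimpanzee"):
        gis = scores[ape]["gis"]
        for taxon, val in expected[f"gis_{ape}"].items():
            assert gis.loc[taxon, "GIS"] == pytest.approx(val, rel=1e-12)
    g = scores["gorilla"]["gis"]
    for taxon, val in expected["pe_gorilla"].items():
        assert g.loc[taxon, "Pe"] == pytest.approx(val)
    for taxon, rk in expected["rank_gorilla"].items():
        assert g.loc[taxon, "rank"] == rk
    # taxon C: consumed but never monitored -> UC, listed after ranked taxa
    assert g.loc["C", "status"] == "UC"
    assert rank_preference(g)[-1] == "C"
    # QF values
    cons = scores["gorilla"]["consumption"]
    for taxon, by_month in expected["qf_gorilla"].items():
        for month, val in by_month.items():
            assert cons.qf.loc[taxon, month] == val


def test_gis_zero_when_never_consumed(toy):
    dataset, _ = toy
    scores = score_dataset(dataset, n_study_months=4)
    chimp = scores["chimpanzee"]["gis"]
    assert chimp.loc["B", "GIS"] == 0.0
    assert chimp.loc["B", "rank"] > chimp.loc["A", "rank"]


def test_gis_invariant_to_sample_duplication(toy):
    """Duplicating every fecal sample changes neither shares nor frequencies."""
    dataset, _ = toy
    scores1 = score_dataset(dataset, n_study_months=4)
    dup = dataset.fecal.copy()
    dup["sample_id"] = dup["sample_id"] + "_dup"
    dataset2 = type(dataset)(
        availability=dataset.availability, nests=dataset.nests,
        fecal=pd.concat([dataset.fecal, dup], ignore_index=True),
        phenology=dataset.phenology, plots=dataset.plots, taxa=dataset.taxa,
    )
    scores2 = score_dataset(dataset2, n_study_months=4)
    pd.testing.assert_frame_equal(
        scores1["gorilla"]["gis"], scores2["gorilla"]["gis"]
    )


def test_gis_scales_inversely_with_fap(small_dataset):
    """FAP scaled by c>0 scales every GIS by 1/c; ranks unchanged."""
    dataset, _ = small_dataset
    scores = score_dataset(dataset)
    mcs = scores["gorilla"]["consumption"].mcs
    g1 = gis_table(mcs, scores["fap"], n_study_months=12)
    g2 = gis_table(mcs, scores["fap"] * 3.0, n_study_months=12)
    cls = g1["status"] == "classified"
    np.testing.assert_allclose(
        g2.loc[cls, "GIS"], g1.loc[cls, "GIS"] / 3.0, rtol=1e-12
    )
    pd.testing.assert_series_equal(g1.loc[cls, "rank"], g2.loc[cls, "rank"])


def test_pe_can_exceed_one_and_is_flagged():
    """Consumption in a non-fruiting month inflates Pe past 1 (no clamping)."""
    months = [1, 2, 3]
    fap = pd.DataFrame({1: [0.1], 2: [0.0], 3: [0.0]}, index=["A"])
    mcs = pd.DataFrame({1: [0.5], 2: [0.5], 3: [0.0]}, index=["A"])
    gis = gis_table(mcs, fap, n_study_months=3)
    assert gis.loc["A", "Pe"] == pytest.approx(2.0)
    assert bool(gis.loc["A", "pe_over"])
    # the non-fruiting month is excluded from the ratio sum: 0.5/0.1 / 3 * 2
    assert gis.loc["A", "GIS"] == pytest.approx(5.0 / 3.0 * 2.0)
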