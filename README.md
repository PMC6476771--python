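# fruitniche

Analysis pipeline for studying how two sympatric frugivores — western
lowland gorillas and central chimpanzees in this design — partition
habitat and fruit resources. The package takes six standard field
tables (habitat-availability transect points, fresh nest records, fecal
seed counts, monthly fruit phenology, botanical plot inventories, and a
fruit trait table), and produces:

* **Seasonal habitat selection** via design-1 Manly selectivity ratios
  with a chi-square goodness-of-fit gate and Bonferroni-adjusted
  preference/avoidance calls per habitat.
* **Fruit preference ranking** via a scoring stack built from the raw
  field data: stem density *D*, Fruit Availability Potential *FAP*,
  reconstructed fruit quantity *QF*, Mean Consumption Score *MCS*, and
  the Global Importance Score *GIS* that ranks taxa by consumption
  relative to availability.
* **Fallback-food classification** from the seasonal contrast between
  each taxon's availability and its consumption, collapsed to six plant
  "consumption traits" (Preferred/Fallback × gorilla/chimpanzee/both).
* **Ordination**: correspondence analysis of the habitat × trait stem
  abundance table (inertia decomposition plus an observed-minus-expected
  deviation table), and PERMANOVA with a dispersion-homogeneity check of
  seasonal differences in Bray–Curtis dissimilarities of monthly
  FAP/MCS profiles.
* A **synthetic-data generator** that emulates the whole field design
  with known ground truth (true selectivity ratios, true preference
  weights, designed fallback taxa), used by the parameter-recovery tests.

## The model in brief

Habitat selection uses the standardised selectivity ratio

```
W_i = (r_i / p_i) / Σ_j (r_j / p_j),     W'_i = m · W_i
```

with `r_i` the proportion of nests in habitat *i*, `p_i` its
availability, and `m` the number of habitats; `W' > 1` indicates
preference.

The diet side chains four quantities per taxon *i* and month *j*:

```
D_i    = Σ_k n_ik / (K · S)                          stems per m²
FAP_ij = (Σ_n SS_nij · B_nij / N_i) · D_i            availability index
QF_ij  = fruits(seeds; mean seeds/fruit) · mean fruit weight   grams
MCS_ij = (QF_ij / Σ_i QF_ij) · (Pf_ij / NPf_j)       consumption score
GIS_i  = [Σ_j MCS_ij / FAP_ij] / J · Pe_i            preference score
```

where `SS` is the summed 0–2 fruiting score of a monitored individual,
`B` its basal area, `Pf/NPf` the fraction of that month's fecal samples
containing the taxon, `J` the number of study months, and `Pe` the
number of months consumed over months fruiting. A *fallback* taxon
fruits in at least three seasons, is more available in the two
high-availability seasons, yet is eaten more in the two lean seasons.

## Worked example

```python
import fruitniche as fn

ds, truth = fn.generate(fn.GeneratorConfig(seed=7))
sel = fn.seasonal_selection(ds, "gorilla")
print(sel["LDS"].table[["habitat", "W_prime", "ci_low", "ci_high", "class"]])
```

```
habitat  W_prime  ci_low  ci_high        class
     MF    0.351   0.264    0.437      avoided
    YSF    0.931   0.718    1.144 proportional
     LG    0.718   0.323    1.113 proportional
     SW    2.209   1.939    2.479    preferred
     RF    0.792   0.530    1.054 proportional
```

In the long dry season this simulated gorilla population nests in swamp
(SW) more than twice as often as availability predicts (`W' = 2.21`,
CI above 1 → preferred) and avoids mature forest (MF), matching the
generator's true selectivity. The global test (χ² = 295.0, df 4,
p ≈ 1e-62) licenses the per-habitat calls.

```python
sc = fn.score_dataset(ds)
print(sc["gorilla"]["gis"].head(3)[["GIS", "Pe", "rank", "status"]])
tr = fn.assign_traits(sc, ds.calendar)
print(tr["trait"].value_counts())
```

```
           GIS   Pe  rank      status
T13    141.470  1.0   1.0  classified
T03    117.274  1.0   2.0  classified
T17     80.517  1.0   3.0  classified

Fallback apes           4
Preferred apes          4
Preferred chimpanzee    3
Fallback chimpanzee     3
Preferred gorilla       1
none                    5
```

T13 ranks first for this simulated gorilla (highest consumption relative
to availability); T03, one of the three taxa the generator designed as
fallback (lean-season consumption boost), is correctly pulled into the
fallback lists despite its high GIS — the fallback-first rule assigns
dual-qualified taxa to fallback.

The same analyses are available from the shell:

```
fruitniche simulate --seed 7 --out data/
fruitniche select --data data/ --ape gorilla
fruitniche score --data data/
fruitniche traits --data data/
fruitniche ordinate --data data/ --matrix fap --permutations 999 --seed 1
fruitniche run --config run.yaml
```

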