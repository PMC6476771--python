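# Methods

This note documents the statistical procedures the package implements,
the parameters that matter, the synthetic study design used for
validation, and the numerical and design choices made where the
procedures admit more than one reasonable reading.

## Habitat selection

Nest counts are treated as design-1 resource-selection data: all
observations are at the population level, availability `p_i` is known
(measured as the share of 50-m transect points falling in habitat *i*),
and the counting unit is the individual nest (a `unit="group"` switch
collapses nests to nest groups instead, since group structure is a
plausible alternative unit).

For each season (nests stratified by the month they were recorded
fresh) we compute `W_i = (r_i/p_i) / Σ_j (r_j/p_j)` and `W'_i = m·W_i`.
The identities `Σ_i W_i = 1` and `W'_i = m·W_i` hold exactly by
construction and are asserted by property tests.

*Variance.* With availability known, the sampling variance of the raw
ratio `w_i = r_i/p_i` is `r_i(1-r_i)/(n p_i²)`; the standard error of
`W'` follows by scaling with `m/Σ_j w_j` (the shared denominator is
treated as fixed — a delta-method simplification that is standard for
this estimator family). Confidence intervals are Bonferroni-adjusted
with family size `m` (one interval per habitat) at level `α/m`,
`α = 0.05` by default.

*Classification.* A habitat is called preferred when the lower CI bound
of `W'` exceeds 1, avoided when the upper bound is below 1, otherwise
proportional — and any non-proportional call additionally requires the
global Pearson chi-square goodness-of-fit test (observed counts vs
`n·p_i`, df = m−1, habitats with `p_i = 0` excluded) to be significant.
Habitats with zero availability but nonzero use are rejected as a data
error; zero availability with zero use drops the habitat from `m`.

## Seasons

The four-season calendar is configuration because the climatological
season boundaries are fuzzy at the transition months. Default:
long dry = {Nov, Dec, Jan, Feb}, long rainy = {Mar–Jun},
short dry = {Jul, Aug}, short rainy = {Sep, Oct}.

## The scoring stack

* **Stem density** `D_i = Σ_k n_ik / (K·S)` uses *all* K inventoried
  plots in the denominator, including plots where the taxon is absent;
  `S = 625 m²` by default (25 × 25 m plots). Units: stems/m².
* **Basal area** `B = π (dbh/200)²` converts a cm DBH to m².
* **FAP** `FAP_ij = (Σ_n SS_nij · B_nij / N_i) · D_i` — the mean
  fruiting-score-weighted basal area per monitored individual, scaled
  by stand density. `SS` pools all four phenology scores (unripe/ripe ×
  tree/ground, each 0–2, so SS ∈ 0–8); a `ripe_only` flag restricts to
  the two ripe scores since either pooling is defensible. Individuals
  not observed in a month contribute SS = 0 but still count in `N_i`.
  A taxon with no phenology individuals at all has *no* FAP row — that
  is an unclassified (UC) state, deliberately distinct from FAP = 0.
* **QF** reconstructs fruit mass from seed counts: 0 seeds → 0 fruits;
  fewer seeds than one fruit's worth → 1 fruit; otherwise
  `ceil(seeds / mean_seeds_per_fruit)` — rounding up, never down.
  For taxa with uncountable seeds (figs), a calibrated seeds-per-fruit
  value plays the role of the empirical mean. Taxa lacking trait values
  cannot be converted and are skipped with a flag (they surface as UC
  in the GIS table rather than disappearing).
* **MCS** multiplies the taxon's share of that month's reconstructed
  fruit mass by the fraction of that month's fecal samples containing
  it; months with no reconstructed mass at all give MCS = 0 for every
  taxon. `0 ≤ MCS_ij ≤ Pf_ij/NPf_j ≤ 1` always.
* **GIS** sums `MCS_ij/FAP_ij` over months with `FAP_ij > 0`, divides
  by the study-month count `J` (a config constant, default the number
  of observed months — not a per-taxon quantity), and multiplies by
  `Pe_i` = months-consumed / months-fruiting. Months with consumption
  but zero measured availability are excluded from the ratio sum but
  still count in the Pe numerator, so Pe can exceed 1; the formula is
  applied literally, without clamping, and such taxa carry a
  `pe_over` flag in the output. GIS = 0 for taxa never consumed; ranks
  are descending with UC taxa listed last, unranked. Values below
  0.001 are displayed as 0 in reports but ranked by their true value.

## Fallback and preferred lists

Seasonal profiles are monthly tables summed within seasons. The two
seasons with the larger community-wide FAP totals are "high", the other
two "low"; ties break by fixed season order (LDS, LRS, SDS, SRS) with a
warning. A taxon is a fallback candidate for an ape when (a) it fruits
in ≥ 3 seasons, (b) its mean seasonal FAP is higher in the high
seasons, and (c) its mean seasonal MCS is higher in the low seasons.
The "negative trend" of consumption against availability is
operationalised as this high/low mean contrast rather than a
correlation: with only four seasonal values a correlation coefficient
is unstable, and the contrast is what the definition of a fallback food
describes. Taxa with study-total MCS below a configurable floor
(default 0.001) are excluded as too rarely eaten to classify.

List sizes target `round(N/3)` (half away from zero) with N the number
of GIS-classified taxa. Fallback slots fill first — a taxon qualifying
as both preferred and fallback is assigned fallback — with candidates
kept in order of descending low-season MCS if over target; the
preferred list then takes the top of the GIS ranking excluding fallback
taxa. Candidacy is assessed from the FAP/MCS profiles alone, so a taxon
whose GIS is UC can still be flagged fallback; such conflicts are
reported in the run log.

Per-ape status pairs collapse deterministically to one of six
consumption traits (or "none"). The conflicting pair — preferred for
one ape, fallback for the other — is not covered by the six traits; it
collapses to the fallback ape's trait, extending the fallback-first
rule.

## Ordination and seasonal tests

The habitat × trait table sums stems of taxa carrying each trait over
plots of each habitat; taxa with trait "none" are excluded, and plots
left with no stems of any included taxon are dropped (their count is
reported, since exclusion counts are part of the results).

Correspondence analysis factors the standardised residual matrix
`D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}` by SVD. Principal inertias are squared
singular values and sum to χ²/n (asserted to 1e−10 against an
independent chi-square computation); axes with singular value below
√1e−12 are dropped, so a table of perfect independence yields zero
inertia and no axes rather than an error. Both rows and columns are
reported in principal (symmetric) scaling. The deviation table is
observed minus expected counts, `X − n·rcᵀ`, whose margins sum to zero
by construction.

PERMANOVA uses the distance-based partition `SS_total = Σ_{i<j} d²/N`,
`SS_within = Σ_g Σ_{i<j∈g} d²/n_g`, pseudo-F with (a−1, N−a) degrees of
freedom, and unrestricted label permutations with
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`. An exact mode enumerates
every distinct labelling for small N and is verified against a
brute-force enumeration written independently in the tests. Rows are
months (seasons as groups) — month resolution is used because both the
FAP and MCS tables are monthly.

Dispersion homogeneity embeds the distance matrix by principal
coordinates, keeping negative eigenvalues as imaginary axes
(`z² = d²_real − d²_imag`, floored at zero), computes each point's
distance to its group centroid, and permutes those distances across
groups under a one-way F statistic. Degenerate inputs where all
distances-to-centroid are equal return F = 0, p = 1.

Bray–Curtis dissimilarities come from `scipy.spatial.distance.pdist`;
a pair of all-zero rows has an undefined ratio and is reported as 0
with a warning.

## Synthetic study design

The generator mirrors the field protocols: 20 transects × 120 points
of habitat availability drawn from fixed proportions (default MF 0.45,
YSF 0.20, LG 0.05, SW 0.18, RF 0.12); 184 plots of 625 m² allocated to
the four non-LG habitats in proportion to availability, with stems
Poisson at per-taxon, per-habitat rates (Gamma-distributed across
taxa); 20 taxa with ~10 phenology individuals each (lognormal DBH,
median 30 cm), scored monthly on the 0/1/2 scale with seasonal
fruiting probabilities peaking in the rainy seasons; 500 nests per
ape per season placed multinomially with probabilities proportional to
availability × true W' (gorillas: swamp 3.0 / mature forest 0.4;
chimpanzees: mature forest 2.5 / young secondary forest and light gaps
0.4); and 30 fecal samples per ape per month with per-taxon fruit
counts Poisson at intensity proportional to preference weight × that
month's population FAP, scaled to ~8 fruits per sample, seeds = fruits
× the taxon's seeds-per-fruit. The nest count of 500/season (≈ 2,000
per ape-year) reflects the yield of a biweekly marked-nest census on
120 km of transects; it was fixed, together with the seed sets, by
pilot calibration of the recovery checks before those checks were
frozen.

The multiplicative preference × availability coupling makes GIS
proportional to the true preference weight in expectation — the
property the rank-recovery test exploits. Designed fallback taxa
(default 3) fruit in all four seasons following the community pattern,
but their consumption preference is multiplied by 5 in the two
low-availability seasons, producing exactly the signature the
classifier tests for. The rank-recovery check runs with the fallback
boost disabled, because the boost deliberately breaks the
proportionality that check assumes.

What the generator does *not* emulate: spatial autocorrelation between
plots, observer error in nest ageing or species attribution, nest
decay, inter-annual phenology variation, group-structured nesting, and
non-fruit dietary items. Passing recovery tests therefore demonstrate
that the estimators invert the generative model they assume, not that
field data meet those assumptions.

## Problem sizes in validation

The acceptance checks use: 1,000 random tables for the CA inertia
oracle; every two-group size split of ≤ 8 points for the PERMANOVA
exact-enumeration check; 2,000 replicates × 999 permutations for its
type-I error calibration (12 observations, 4 seasons of 3 months);
10 replicates × 2 apes for GIS rank recovery; and 100 replicates of the
default design for fallback sensitivity and habitat-class recovery.

## Known limitations

* The W' standard error treats the normalising denominator as fixed;
  for very small nest counts the resulting intervals are approximate.
* Pe > 1 (consumption in non-fruiting months) signals phenology
  undercoverage; the literal formula keeps such taxa comparable but
  their GIS values should be read with the `pe_over` flag in hand.
* The exact PERMANOVA mode enumerates label assignments and is only
  feasible for roughly a dozen observations.
* Correspondence analysis assumes a complete two-way table; habitats
  or traits with all-zero rows/columns must be removed upstream.
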