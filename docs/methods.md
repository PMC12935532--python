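# Methods

This note documents the accounting model implemented by `defocarb`, its
assumptions, the parameters that matter, and the design choices made where
the method left genuine freedom. It describes what the code computes; every
number quoted here is produced by the test suite or by
`scripts/acceptance.py`, not asserted by hand.

## Grid model

All layers live on one abstract planar grid (`GridSpec`): row-major, origin
top-left, a constant pixel area in hectares (default 0.09 ha, the 30 m
convention) and an accounting window (default 2001–2022). There is no
projection, resampling or latitude-dependent pixel weighting — inputs must
be pre-aligned. This keeps the arithmetic core exact and deterministic;
pre-processing real rasters onto a shared grid is out of scope.

The internal nodata sentinel (−9999) is applied uniformly at read time.
Masks are strictly {0, 1, nodata}; year layers hold 0 (no event) or a
calendar year inside the window.

## Spatial attribution

A loss pixel is **deforestation** only if it was natural forest in the base
year: canopy density ≥ `tcd_threshold` (default 25 %, ≥-rule, so 24.9 fails
and 25.0 passes) and plantation mask = 0. Loss failing this test is
degradation or rotational clearing and is reported in a separate total,
never in the commodity accounts.

Each deforestation pixel is claimed by at most one dataset. Datasets are
scanned level-major — commodity, then land use, then mosaic — with ties
within a level broken by the higher rubric score, then registry order.
Eligibility for a pixel lost in year *t*:

* **annual datasets** must observe the class within `[t, t +
  spatial_lag_years]` and not beyond their `last_valid_year`. An annual
  dataset is a class layer plus a companion `<id>__year` observation-year
  layer; this companion is the minimal structure that makes the lag window
  a real constraint (tree crops in particular become detectable only some
  years after clearing).
* **static maps** are valid for all loss years ≤ `last_valid_year`, with no
  lower bound — tree-crop and plantation extents persist, so an old loss
  under a current cocoa map is still attributable to cocoa.

Pixels no agricultural or forestry dataset claims are checked against the
fire layer (default: fire year must equal the loss year exactly;
`fire_window_years` widens this). Fire-only loss is excluded from
deforestation — agriculture always beats fire, so a pasture claim within
the lag window wins over a coincident fire. Next comes the dominant-driver
fallback: `commodity_driven` and `shifting_agriculture` feed the
mixed-agriculture statistical pool, `forestry` feeds the plantation pool,
`other` is counted with degradation (non-commodity). Whatever remains is
`unattributed` and also enters the statistical pool.

`spatial_lag_years` defaults to 3. The sensitivity harness exposes 1 and 5
as bounds; the implementation guarantees that commodity-attributed area is
non-decreasing in the lag.

## Statistical land balance

Unresolved deforestation arrives as five pools per region-year: the three
single-land-use pools (spatial evidence said cropland / pasture /
plantation but no commodity), the cropland–pasture mosaic, and the mixed
agriculture pool (driver fallback + unattributed).

**Step 1 — land uses.** Expansion of each land use is measured from the
statistics over a backward window `[t − statistical_lag_years, t]`
(default lag 3), either *gross* (sum of positive year-on-year increments;
abandonment elsewhere in the window does not cancel expansion — this is the
default and is how abandonment is "accounted for") or *net* (endpoint
difference). Missing years are linearly interpolated. Under the default
displacement rule (`cropland_first`), cropland expansion is satisfied first
from the mixed pool — modelling cropland displacing pasture, which expands
into forest — and the remainder is split between pasture and plantation
proportionally to their expansions; with the toggle off the split is fully
proportional. Mosaic pools split between cropland and pasture only.

**Budget bookkeeping.** Because backward windows overlap, a single reported
expansion increment could absorb deforestation in several consecutive
years. The pipeline therefore tracks each region's expansion increments as
a FIFO budget: spatially attributed areas consume their land-use and crop
budgets first, and every statistical allocation consumes what it receives.
In gross mode the caps handed to the allocator are the *remaining* window
budgets. This closure is what makes the land balance exact on consistent
statistics: on degraded synthetic landscapes the recovered commodity
shares match the ground truth to machine precision (the acceptance
criterion only requires 1 % absolute). Net mode, which is a sensitivity
setting, uses plain windowed expansions without FIFO tracking.

**Restriction.** `restrict_by_stats` has three settings. The default,
`pools`, caps only statistically split pools at their remaining expansion
— single-land-use pools pass through on their spatial evidence; `all` also
caps the pass-through pools; `none` removes all caps. Overflow is reported
explicitly as *deforestation without production*; pools with no usable
statistics are reported *unallocated*. Residual classes are rows in every
output, never dropped, so conservation is checkable end to end.

**Step 2 — crops.** Cropland allocations are split across crops by positive
harvested-area expansion over the same kind of window. With
`multicropping` on (default), each year's harvested areas are first
divided by the cropping intensity `CI = max(1, Σ harvested / cropland
area)`, so harvested-area booms that come from double cropping (the
safrinha-maize pattern) do not claim physical land twice. Pasture maps to
the combined `cattle_meat_leather` class (an economic meat/leather split
is out of scope); plantations map to `forestry_products`.

## Committed carbon emissions

Per deforested hectare, in MgC:

* vegetation = AGB × (1 + root-to-shoot + deadwood fraction + litter
  fraction) × 0.47. Deadwood and litter fractions are biome-level defaults
  (tropical 0.08/0.04, temperate 0.12/0.08, boreal 0.16/0.12,
  config-extensible); the original elevation/precipitation dimensions of
  such look-up tables are collapsed to biome only.
* SOC loss = fraction × standing 0–100 cm SOC stock, the fraction specific
  to the replacing land-use group and biome (defaults: cropland 0.25–0.30,
  pasture 0.10–0.12, plantation 0.08–0.10). On peat pixels the SOC term is
  forced to zero — drained-peat fluxes are booked separately and would
  otherwise be double-counted. A cross-module test verifies the exclusion.

Gross emissions are the component sum × 44/12. Net emissions deduct the
replacing commodity's mature plant carbon stock (MgC/ha, commodity-level
with group fallback) × `plant_stock_scale` (default 1.0; 0.75 models
average pre-harvest stocks) × area × 44/12. Negative net emissions are
allowed and reported — flooring them would silently break conservation.
Emissions are committed (booked once at the loss year); no decay curves,
regrowth credits or non-CO₂ gases.

For statistical pools the replacing land use is unknown at pixel level, so
pool carbon is aggregated per (region, year, pool, biome) — vegetation
carbon plus standing SOC — and each allocation receives its area share of
the pool's vegetation plus SOC × the fraction of *its* land-use group.
Residual classes (no identified production) use the mean fraction over the
three groups: the forest was still cleared, so booking zero SOC would
understate the total. The plant-stock deduction is applied on aggregated
(region, commodity, year) areas, equivalent to per-pixel deduction when
stocks are uniform per commodity; residual classes deduct nothing.

## Peatland drainage

Deforestation on peat (post-2000 cohorts only) accrues an annual flux =
area × emission factor (land-use group × biome; oil palm has a dedicated
row, other crops use their biome's cropland row). The deforestation year
accrues a full year, forced by the worked example in the test suite: one
hectare drained for oil palm in 2010 and accounted until 2022 accrues 13
annual charges of 54.41 MgCO₂. Only the tropical oil-palm factor is an
established printed value; the other table cells are package defaults at
wetland-supplement-style magnitudes and are ordinary configuration inputs.

Spatially commodity-attributed peat is charged to that commodity directly.
Peat inside statistical pools is split evenly across all commodities with
positive allocation in that region-year (`peat_split="even"`;
`"proportional"` splits by allocated area instead), per region-year rather
than per region-period. The accumulation horizon is `until_end` (default),
`none`, or a fixed number of years; accumulated emissions are linear in
area and accrual years, and truncated horizons can never exceed the
until-end total.

## Quality index

`IQI = Σ_j FL_j · OA′_j · Score_j / Σ_j FL_j` over the datasets
contributing to one (region, commodity, year) estimate, where FL is the
contributed deforested area, Score is the mean of three equally weighted
rubric criteria (spatial granularity, temporal granularity, explicitness —
declared per dataset in the registry), and OA′ is the dataset's overall
accuracy, multiplied for statistical contributions by the mean of the two
statistics flag scores (land-use and production). Flag scores: official
1.0, semi-official 0.75, estimated 0.5, imputed/unofficial 0.25
(config-overridable); an absent production flag scores 1.0 (sources that
report directly without flagging). Statistical contributions inherit their
pool's source composition pro rata, including the base loss dataset for
unattributed pixels. Bands follow the half-open edges literally:
≥ 0.6 dLUC-commodity, [0.55, 0.6) dLUC-landuse, < 0.55 sLUC. The IQI is a
confidence indicator and is never used to filter estimates; zero-area
records are flagged rather than given a fabricated value.

## Reporting

Footprint rows are (region, commodity, year) with deforested area,
gross/net committed MtCO₂, accumulated peat MtCO₂, IQI and band.
Amortization spreads area and committed emissions evenly over
`amortize_years` (default 5) starting at the event year; peat columns pass
through unamortized because their temporal profile is already explicit.
The sensitivity harness re-runs the pipeline under named switches
(threshold 10/75, lags 1/5, partial/full statistical modes, displacement
and restriction toggles, multicropping off, peat horizons, 75 % plant
stock) and reports percentage change from baseline to two decimals,
sign = (variant − reference)/reference × 100. `partial_statistical` drops
commodity/land-use/mosaic layers but keeps the driver map and fire;
`full_statistical` keeps only the loss layer — no plantation mask, no fire
exclusion — so all threshold-passing loss becomes statistical pool, which
is why it inflates totals.

## Synthetic landscapes and what passing tests show

The generator emulates frontier geometry with clustered rectangular
conversion events on natural forest, each carrying one loss year and one
commodity drawn from the configured mix (defaults: soy 0.25, maize 0.15,
oil palm 0.20, cocoa 0.10, cattle 0.20, forestry 0.10 on a 64×64 grid with
two regions, all tropical unless configured otherwise). Evidence degrades
controllably: commodity-map coverage 0.9 with detection delays of 0–2
years, land-use coverage 0.8 of the remainder, mosaic fraction 0.1,
classification noise as label swaps among commodities only (never
forest↔non-forest, so area conservation is structural). Non-commodity fire
(5 % of loss) and rotational/degradation loss outside natural forest (15 %
of conversions) exercise the exclusion paths. Carbon layers are uniform
draws per biome (tropical AGB 100–400 Mg/ha, SOC 80–200 MgC/ha,
root-to-shoot 0.18–0.28) recorded into the ground truth at generation, so
emission recovery is exact rather than distributional. Statistics are
built from the true conversions on constant bases, starting five years
before the window so lag windows are always covered, flagged `official`.

What passing tests therefore show: the bookkeeping is exact — conservation
to machine precision, exact ground-truth recovery under full evidence, and
exact share recovery under statistics-only attribution *when the
statistics are consistent with the landscape*. They do not show robustness
to the error structure of real global products (misregistration,
systematic omission, statistics that disagree with the maps); on real
data the residual classes and the IQI, not the recovery error, carry that
information. Scale is also deliberately desk-sized: grids of 24²–64²
pixels keep the full acceptance suite under a minute, and nothing in the
arithmetic depends on grid size.

## Numerical choices

* Areas are pixel counts × constant pixel area, so conservation checks
  compare exactly (tolerance 1e-6 relative is enforced, observed ~1e-15).
* Proportional splits guard zero denominators: empty pools allocate
  nothing, zero-expansion region-years report `unallocated`.
* Tie-breaks are total: level rank, then rubric score, then registry
  order, so attribution is deterministic for any registry.
* Sub-1e-12 residues from floating proportional splits are suppressed
  rather than reported as spurious residual rows.
* All randomness flows through one `numpy` generator seeded per landscape;
  identical parameters give bit-identical landscapes and byte-identical
  pipeline outputs.

## Known limitations

Secondary-forest loss after the base year is structurally invisible (the
density layer is base-year only). The meat/leather and broader co-product
economics, trade re-allocation, peat fires, drainage-depth dynamics,
SOC/BGB decay over time and formal uncertainty propagation are all out of
scope. The equal-split rule for statistical peat and the per-region-year
definition of "identified commodity expansions" are documented choices
where the method statement allows alternatives; both are configurable.
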