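# Methods

## Scope and structure

`floodcarbon` compares two land uses — keeping forest standing under a
REDD+ payment scheme versus clearing it for an oil-palm new planting —
on annualized 25-year net present value, per landscape stratum. A
stratum is an accounting tuple (carbon class × oil-palm suitability ×
tenure × extent in ha); the analysis needs nothing spatial beyond that
bookkeeping, so strata are table rows and GeoJSON geometry, when
written, is decorative (`"geometry": null` by default).

## Plot carbon

Above-ground biomass per stem uses the height-free moist-tropical
allometry in DBH and wood density only. Height is deliberately absent:
regional inventories typically record species and DBH alone, and the
six-class binning (mid-points 25–450 MgC/ha) absorbs most per-tree
error. Two under-specified points are fixed as configuration:

* **Carbon fraction of biomass** — default 0.5, exposed as a parameter.
  The conventional alternative 0.47 shifts plot densities by 6%, which
  rarely moves a plot across a class boundary given the class widths.
* **Class boundaries** — half-open, lower-inclusive (`[50, 100)` …),
  so a plot at exactly 50 MgC/ha is class 2 and ≥400 is class 6. Labels
  like "50–100" are ambiguous at the edges; one convention had to be
  fixed and is tested.

Unknown species default to 0.5 g/cm³ wood density (conservative for
mixed stands).

## Carbon accounting

Stock = extent × class mid-point, exactly; grouped totals must equal
the grand total to machine precision (a tested invariant). With integer
extents all stocks are integers. Note for users reproducing published
tables of this kind: a class-wise stock table and an independently
compiled tenure-wise table may disagree by rounding residue in their
grand totals (here ~150 MgC on ~4.7M); the package reproduces each
table's own arithmetic and does not reconcile them.

## Oil-palm reference level

The baseline against which REDD+ carbon is credited is the
time-averaged above-ground carbon of the counterfactual planting over
a 25-year crop life. A partially observed per-palm age series
(ages 1–19) is completed by:

* flanking-mean fill for a single interior gap, equal annual increments
  for runs of gaps (both are linear interpolation, implemented as one
  rule);
* back-fill before the first observation (conservative; year-1–2 palm
  carbon is near-negligible either way — configurable in principle but
  not a sensitive choice);
* holding the age-19 value for years 20–25 (overstates the baseline,
  hence conservative for REDD+).

The mean per-palm value × palms/ha (136 / 68 / 34 at full / half /
quarter capacity) gives the per-suitability reference `R_s`.

**Default reference levels are the published constants
{46, 20, 7} MgC/ha**, not values recomputed from a series. The printed
degraded-class values are *not* proportional scalings of the full-stand
value (136·x = 46 would imply 23 and 11.5, not 20 and 7); whatever
produced them cannot be reconstructed from published information, so
reproduction runs use the printed constants and a computed reference is
available by configuration (`reference_source="computed"`).

## Discounting convention

All cash flows are end-of-year; the year-1 flow is discounted by one
full period:

    NPV = Σ_{t=1..25} a_t / (1+r)^t,     annualized NPV = NPV / 25.

Annualization divides by the horizon (not an annuity-equivalent). This
is the unique simple convention under which one engine reproduces all
eight published coarse-model values (upfront {37, 103, 202, 409} and
staggered {24, 68, 135, 274} USD/ha/yr at 11%) — their joint
reproduction is itself a test. Reported dollar and CO₂e figures round
half-away-from-zero, with a 1e-6 pre-round guarding binary
representation at exact .5 ties. The carbon→CO₂e factor is fixed at
3.67 exactly (not 44/12): the published fund cells match 3.67
precisely.

## REDD+ cash flows

Revenue `V = (midpoint − R_s) × 3.67 × price` per hectare. Upfront
stance: year 1 gets `V − 25` and years 2–25 get `−10` (USD/ha
establishment and running costs). Staggered stance: year 1 gets
`V/2 − 25`, years 2–25 get `V/48 … ` precisely `(V/2)/24 − 10`.
Negative net carbon (forest class below the palm baseline) yields
negative revenue — no flooring — which is what makes the lowest carbon
class financially unattractive under a full-capacity reference at every
price.

## Oil-palm model

A new-planting estate DCF at three capacity classes (1.0 / 0.5 / 0.25
of 136 palms/ha), with yield proportional to capacity.

**Yield curve.** Years 1–2 zero (immature), peak 30 tFFB/ha in years
8–11, linear decline to 17 t at year 25. The immature-to-peak ramp
(12.1, 18, 22, 25.4, 28 t in years 3–7) is chosen so the 25-year mean
is exactly 21.92 t/ha/yr; the half- and quarter-capacity curves then
average 10.96 and 5.48 by construction.

**Costs and calibration.** The per-year estate cost schedule behind the
published annualized NPVs is not public, so the default schedule is a
calibration: harvesting + transport fixed at a realistic $35/tFFB,
felling/ground preparation $1,214.8/ha in year 1, and the two free
parameters — fixed annual costs (general charges + field upkeep,
$824.47/ha/yr) and a capacity-dependent "supplying" (replacement
planting) charge in years 1–2 ($105.71 and $238.86/ha/yr at half and
quarter capacity) — solved so that annualized NPV at the 11% industry
discount rate equals the published $594 / $129 / −$109 per class
exactly. Supplying growing with palm mortality is the economically
sensible direction (more flood-killed palms to replace). Any
user-supplied schedule is accepted. At the sensitivity rates (5%, 8%,
14%) the calibrated model tracks the published class NPVs to within a
few percent but not to the dollar; those figures are treated as
calibration inputs, not reproduction targets.

## Allocation

Ties go to REDD+ ("equal or higher" wins). Funds over the winning set
are computed from the unrounded CO₂e total and rounded once — the only
rule consistent with every published fund cell, including the one that
lands on an exact half dollar. Percent coverage is rounded to the
nearest integer. One known edge: under the reproduced convention, the
half-capacity class at the lowest price and ≥350 MgC/ha computes to
$127/ha/yr against the $129 estate — about $2 short of the published
qualitative claim that it wins; this sits within the published
rounding and is left as computed.

## Synthetic landscape generator

The generator exists so every stage is testable without field data. It
emulates:

* **Inventory** — 230 plots (110 ha total) with Poisson stem counts
  (mean 50/plot), truncated log-normal DBH (floor 10 cm, median
  ≈25 cm — a plausible logged-forest structure, stated as an assumption
  since no DBH distribution is published), uniform wood density
  (0.4–0.8 g/cm³).
* **Landscape** — per-carbon-class extents default to the published
  unprotected-forest column (total 30,173 ha) and suitability extents
  to the published class map (9,327 / 4,352 / 16,492 ha). Each class
  extent is split across suitability and tenure *proportionally* (an
  independence allocation): the true joint distribution of carbon ×
  suitability is not published, so independence is the neutral choice.
  Class marginals are exact; the two configured totals may disagree by
  a couple of hectares (they do, by 2 ha, in the published marginals)
  and a tolerance (default 5 ha) guards larger inconsistencies.
* **Palm series** — a saturating growth curve
  `m(a) = 0.49·(1 − e^(−0.12a))` MgC/palm observed at the 11 default
  field ages {2–5, 7–8, 13, 15–16, 18–19}; the asymptote/rate put the
  implied full-capacity reference near the published mid-40s MgC/ha.

One integer seed drives everything; same-seed runs are byte-identical
(hashes recorded in the run manifest).

**What passing tests on synthetic data do not show:** the generator has
no spatial autocorrelation, no real joint class×suitability structure,
and deterministic marginals — so landscape-level roll-ups on synthetic
data demonstrate the *machinery* (allocation, monotonicity in price,
fund arithmetic), not the real landscape's coverage percentages, which
depend on the unpublished joint distribution.

## Problem sizes

The default pipeline run uses 230 plots × ~50 stems, a 72-stratum
landscape, 25-year horizons and a 4 × 2 × 4 scenario grid; everything
completes in seconds, and the property suite exercises the same sizes.

## Known limitations

* Above-ground carbon only; below-ground/soil carbon excluded by
  design (no regional data; mangrove/peat systems are therefore
  undervalued).
* No transaction-cost model beyond the flat establishment/running
  costs; no timber revenue; FFB (not crude-palm-oil) economics.
* The coarse model's published mean yield is quoted inconsistently at
  source (21.42 vs 21.92 t/ha/yr); the package uses 21.92 everywhere.
* Oil-palm NPVs at non-11% discount rates are approximate (see
  calibration above).
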