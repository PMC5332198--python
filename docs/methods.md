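# Methods

## Problem and model

The package attributes ambient-pollution mortality burden to emitting
source-states and sectors. Its inputs are gridded *sensitivity surfaces*
Δx — the change in monthly-mean ambient concentration (24-hr-average PM₂.₅ in
μg/m³, or daily 8-hr-maximum O₃ in ppb) per grid cell attributable to a tagged
group of sources. Surfaces are signed: fresh NOx emissions consume O₃ in cold
months (titration), so winter NOx→O₃ sensitivities are negative.

Mortality follows the linear rate-difference equation

    Δy = Σ_i Σ_j  y0_ij · β · Δx_ij · Pop_ij

summed over all N×M grid cells, where y0 is the baseline adult (≥ 25 yr)
mortality rate (deaths/person/yr), Pop the adult population, and β the
concentration–response function (CRF). Defaults: β = 0.01 per μg/m³ PM₂.₅ and
β = 0.0004 per ppb O₃ (0.4 % per 10 ppb). The model is deliberately linear —
no log-linear exponentiation — and CRF uncertainty is out of scope: all
outputs scale linearly in β, so distributional conclusions are unaffected.

Two modeled months stand for the year: January and July each represent six
months. `annualized_mortality` returns the annual-rate deaths as if that
month's Δx held all year; the half-year impact is half of that, and the annual
impact is the sum of the two half-year values (equivalently the mean of the
two annual rates). The same convention drives annualized emissions
(6 × January tons + 6 × July tons). The O₃ CRF, though derived from daily
mortality studies, is applied to annual baseline mortality with monthly-mean
Δx: under a constant fractional effect this equals aggregating daily impacts.
Whether month-specific baseline mortality should be used for winter O₃ is not
resolvable here; annual y0 is used throughout.

## Segmentation

Multi-state runs superpose member plumes; `region_grow` separates them.

* **Seeding** (`select_seeds`): each member state's seed is the maximum-|Δx|
  cell within its emission footprint dilated by one cell; ties break to the
  smallest (i, j). A zero surface over the footprint falls back to the
  maximum-weight footprint cell (logged, not fatal).
* **Growth**: one frontier per seed, 8-connectivity. Every frontier cell is
  prioritized by the composite |Δx| at that cell; the globally largest pops
  first. Because priority is magnitude-based rather than
  distance-from-seed-based, negative cells are claimable like positive ones
  and a small state's region can extend to its plume's full reach.
* **Contested cells**: all claims on a cell carry the same priority (the
  cell's own |Δx|), so any cell reached by two frontiers before it pops is
  contested; it is labeled OMITTED rather than arbitrated. This forms a thin
  watershed band between plumes and deliberately sacrifices a small share of
  impact to guarantee clean attribution — a documented downward bias.
* **Background**: cells with |Δx| below the background floor (default
  1e-6 × max|Δx|, a relative floor so behavior is scale-free) are never
  claimed. Seed cells are always attributed to their own state.
* **Determinism**: pop order depends only on (|Δx|, i, j) and states are
  processed in sorted-id order, so the label map is invariant to the order in
  which members are listed.
* **QA** (`qa_run`): omission_fraction = Σ|impact| over OMITTED cells divided
  by Σ|impact| over all non-BACKGROUND cells, with per-cell impacts
  y0·β·Δx·Pop. Measuring on health impact rather than concentration mass is a
  design choice: the quantity being protected is deaths, and the 10 % gate is
  phrased against total premature deaths. A zero total is reported as
  fraction 0 with a `degenerate` flag. Runs failing the gate list all members
  in `fallback_required`; the pipeline then substitutes the single-state
  ground-truth surfaces (the synthetic analog of re-running the atmospheric
  model for one state in isolation).

The exact historical growth criterion this reconstructs is not published in
the available material; the implementation realizes the stated constraints
(contiguous per-state regions containing their seeds, signed cells included,
deliberate omission below 10 % of impact) with a deterministic best-first
rule. One consequence, established analytically: the best-first watershed
follows the *composite* surface's saddle, which for unequal plume amplitudes
is shifted by roughly σ²·ln(dA/dB)/s from the equal-ground-truth-contribution
line, so exact agreement with a dominant-contributor oracle on attributed
cells is a property of (near-)equal-amplitude plumes; with unequal amplitudes
the disagreement is confined to low-|Δx| boundary cells and the attributed
impact error stays small (tested at ±15 %). OMITTED cells carry no state label
and are excluded from oracle comparisons by construction.

## Exposure gridding

Counties carry an adult population and ten yearly mortality rates whose
arithmetic mean is used (stability). `intersect_to_grid` assumes uniform
density within a county: a cell receives pop_c · area(county ∩ cell)/area(county)
people; its y0 is the population-weighted mean of contributing counties'
averaged rates (the combination rule for fractional cells is not prescribed
anywhere authoritative; population weighting is the natural choice under the
uniform-density assumption). Zero-population cells carry y0 = 0 by convention
— they contribute nothing to the impact product. Population is conserved
exactly for rectangular tilings and to 1e-6 relative otherwise; counties
outside the domain are skipped and logged.

## Damage functions

Monthly HDF = annual-rate deaths / (monthly tons × 12) × 1,000 — deaths per
1,000 tons if that month's conditions held all year. Annual HDF = mean of the
signed January and July values (uniform year-round emissions interpretation).
Zero emissions give an undefined (NaN) value with the low-emission flag set.
Signs are retained throughout: negative January NOx→O₃ HDFs are physical.

Low-emission flagging combines two configurable rules, applied per
(sector, precursor, pollutant): the k lowest-emitting states by annualized
tons (ties broken by state id) and an absolute floor (default 1 ton/yr).
Both are needed: rank-based exclusion supports ratio reporting across a
full state set, while the absolute floor captures the pathology of a
near-zero emitter whose deaths/ton explodes (e.g. 0.05 deaths over 0.02
tons/yr → 2,500 deaths per kiloton). Whether rank exclusion should be per
pair or global is ambiguous; per-(sector, pair) is implemented, with the
count configurable. Summary percentiles (5, 25, 50, 75, 95) use linear
interpolation between order statistics and exclude flagged states; per-state
EGU:RC annual death ratios report NaN on a zero RC denominator.

## Synthetic scenario generator

The generator emulates the *structure* of chemical-transport sensitivity
output, not its physics. Ground truth per (state, sector, month, pair):

    Δx(cell) = Σ_footprint  E · w · s · g · exp(−d²/2σ²)

with E monthly tons, w footprint weight, s a seasonal multiplier, g a gain
(concentration per ton), and d the distance from the cell center to the
footprint cell displaced by a fixed advection offset. Composites are exact
sums of member ground truths, so segmentation has an analytic reference.
Plumes are deterministic given the config (the seed drives counties and state
emission scales only); amplitude is exactly linear in emissions.

Default study conditions (chosen once as a plausible desk-scale analog of a
continental 36-km domain):

* Grid 36 × 60 cells of 36 km (≈ 1,300 × 2,160 km); origin (0, 0).
* Six states in two rows of three (10 × 10-cell blocks), paired across the
  domain into three run groupings (S1+S5, S2+S4, S3+S6) so that plume tails
  overlap and segmentation is non-trivial; each grouping is run per sector
  (6 run groups), for 96 segmented surfaces (groups × 2 months × 8 pairs).
* RC sources: uniform area footprint over the state block, σ = 108 km,
  advection (72, 36) km. EGU sources: two point cells per state, σ = 144 km
  (elevated release, wider transport), advection (108, 36) km.
* Base emissions (tons/month, scaled per state by a log-spread factor drawn
  uniformly in [0.6, 1.8] from the seed): RC — PEC 300, POC 1,500, PSO₄ 50,
  NOx 800, SO₂ 200, VOC 2,000; EGU — PEC 50, POC 30, PSO₄ 150, NOx 4,000,
  SO₂ 8,000, VOC 100. Emissions are constant across months; seasonality
  enters through the multipliers, keeping HDF ratios equal to impact ratios.
* Seasonal multipliers (Jan, Jul): RC primary PM₂.₅ (2.0, 0.1) — the 20:1
  winter dominance; EGU SO₂→PM₂.₅ (0.4, 2.0) — the 5:1 summer enhancement
  from warm-season sulfate formation; NOx→O₃ (−0.5, 1.0) RC and (−0.2, 1.0)
  EGU — negative January titration, smaller for elevated EGU releases; the
  remaining pairs have mild (≤ 1.5×) seasonal contrast.
* Gains per ton reflect primary constituents coupling more strongly than
  secondary formation (2e-4 μg/m³/ton primary PM₂.₅ vs 1.5–3e-5 secondary;
  4–5e-5 ppb/ton for O₃).
* 48 rectangular counties tile the domain (divisor pair of n closest to the
  domain aspect ratio); adult populations log-uniform in [2e4, 3e6]; ten
  yearly mortality rates uniform in [0.008, 0.015] /yr.

What the generator does **not** emulate: real state geographies, meteorology
and wind fields, chemistry (plumes are static Gaussians), emission
seasonality, intra-county population structure, and inter-annual variability.
Passing tests therefore demonstrate the correctness of the attribution,
exposure, impact and normalization machinery under known ground truth — not
the fidelity of any atmospheric simulation. Headline burden totals from the
original continental-scale application (tens of thousands of deaths) are not
reproducible at this scale and are not targeted; the pipeline's testable
claims are structural: omission below 10 % per run, exact conservation and
linearity, seasonal sign/ratio recovery, and segmentation recovery of known
per-state impacts.

## Numerical choices and degenerate inputs

* Field CSV round-trips use %.17g (exact for doubles); NetCDF I/O goes
  through xarray's scipy backend (classic NetCDF3), dims (row, col), variable
  `delta_x`, metadata as global attributes.
* Footprint weights must sum to 1 ± 1e-9; annual impact records equal the sum
  of their halves to 1e-9 relative; split re-sums are exact (pure masking).
* Zero-emission plumes are all-zero fields, not errors; zero-impact QA totals
  are degenerate-flagged; zero within-state totals return NaN.
* Percentile definition: NumPy's default linear interpolation, verified
  against an independent sort-and-interpolate oracle.
* All pipeline randomness flows from the single scenario seed; no stage draws
  independent entropy, and a rerun under the same config and seed is
  byte-identical (sorted outputs, canonical JSON, hash over the scientific
  config excluding the output path).
* The default pipeline sets the low-emission rank count to 1 because the
  default scenario has six states; a realistic ~49-state run would use the
  module default of 5.

## Known limitations

* Contested-cell omission biases per-state totals slightly downward (bounded
  by the QA gate, typically ≲ 1 % in the default scenario).
* Uniform-density areal weighting misplaces population within large
  heterogeneous counties; consequences are larger for primary pollutants
  with small impact footprints.
* The half-year convention assumes two months represent the year's halves.
* No uncertainty propagation: CRFs and emissions are point estimates.
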