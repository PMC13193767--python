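# Methods

## The measurement model

A blister pack of n sealed ¹²⁵I seeds is assayed as a whole in a well-type
ionization chamber. The chamber reading M (MBq) is compared with the
manufacturer's nominal activity through the detection rate

    rate (%) = 100 · M / (A_nom · n),

where A_nom is the nominal per-seed strength (11.0 MBq for the product line
modelled here; 13.1 and 15.3 MBq variants are accepted but flagged). The
rate is far below 100% for large packs because seeds shield one another and
part of the cartridge is stainless steel; QA therefore judges each pack
against the facility's *cumulative per-n mean* rate, not against 100%.

### Decay correction

Readings taken off the calibration date are corrected to it with
`A = M · 2^(+Δt/T½)`, Δt the whole-day difference between measurement and
reference date and T½ = 59.4 d. "Corrected" always means activity at the
reference date, because the nominal value is stated for that date; the
correction is exposed as an explicit, optional pipeline step
(`compute_rates(..., correct_decay=False)`) for instruments whose isotope
setting already reports the corrected value. Days are counted as calendar
days — the assay log records dates, not times — so sub-day decay
(≤ 2^(1/59.4) ≈ 1.2%) is attributed to the measurement date convention.

## Control limits and classification

Two nested percentage bands are built around the per-n mean: acceptance
(3%) and intervention (5%), both configurable. A pack's deviation is
`100·(rate − mean)/mean`; verdicts are `within_acceptance` (|d| ≤ 3),
`investigate` (3 < |d| ≤ 5) and `intervene` (|d| > 5). A deviation exactly
at a limit does **not** escalate: the canonical borderline case — one dead
seed in a 20-pack, whose expected loss equals exactly 5% of the mean — is
precisely the fault the batch assay cannot reliably call, and the
classification mirrors that. Displayed table cells are rounded to one
decimal with ties away from zero; all arithmetic is double precision. Three
cells of the published facility table differ from ours by exactly 0.1
because they were derived from unrounded cumulative means that are not
recoverable from the published one-decimal values; we document rather than
force those cells.

## Calibration regression

Fits are ordinary least squares **on the per-n mean rates, unweighted**,
not on individual packs: evaluating the facility's published cubic at
x = 1..5 reproduces its published means to ~0.1 points, whereas a
count-weighted fit (197 five-packs vs 20 singles) would not reproduce the
published coefficients. A weighted fit remains available via the `weights`
argument. The cubic family covers the small-pack regime (needs ≥ 4 distinct
sizes; exactly 4 interpolates with R² = 1); the log-linear model
`y = a·ln x + b` (natural log) covers any span including 20-packs.
`select_model` chooses cubic only when all sizes are ≤ 5 and records both
R² values when both families fit. Solutions come from
`numpy.linalg.lstsq` (SVD), which handles the mild collinearity of the
Vandermonde design; independent oracles in the tests (closed-form
projection onto the 4th-difference vector for five equally spaced points,
and a gradient-based numeric minimiser of the SSE) confirm optimality to
1e-6 relative. R² is `1 − SSE/SST` with SST about the response mean; it is
undefined (reported as an error, or NaN inside a fitted model) for a
constant response.

## Synthetic generator

The generator emulates the facility's delivery history: by default
20/15/18/30/197/153 packs of 1/2/3/4/5/20 seeds (433 packs), all at the
11.0 MBq nominal. One pack of n seeds is drawn as

    A_i     = A_nom · (1 + ε_i),   ε_i ~ Uniform(−tol, +tol),  tol = 6%
    reading = Σ_i e_i·A_i · (1 + η),  η ~ Normal(0, σ_noise),  σ_noise = 1%

The per-seed efficiencies e_i lump neighbour-to-neighbour attenuation into
an n-dependent constant calibrated to the per-n mean table; stainless-steel
shielding is modelled explicitly only where it is structural: k = 3 of the
20 seeds sit behind steel with transmission s (default 0.1, a modelling
choice — the steel "blocks the majority of the photons" but no transmission
measurement exists). The unshielded efficiency is raised to
`e_u = n·ē/(n − k + k·s)` so the pack average equals the table mean ē
exactly for any (k, s): the generator stays calibrated by construction, and
a Monte-Carlo check confirms E[rate] = table mean for every pack size.
Pack sizes absent from the table get their mean from the log-linear fit to
the table. Faults are injectable per pack: dead seeds (zero activity,
position random or forced into a shielded slot), wrong-strength deliveries
(13.1/15.3 MBq seeds recorded against an 11.0 MBq order), and
calibration-date mismatches (the reading is decayed by the offset while the
log keeps the wrong reference date). All draws flow through one
`numpy.random.Generator` (PCG64, recorded in the config metadata), so a
delivery is a pure function of its config and reproduces byte-identical
CSVs.

### What the defaults do and do not emulate

The ±6% uniform per-seed error is the *manufacturer's tolerance bound*
treated as a worst-case spread (maximum entropy on the stated interval); a
truncated normal (σ = tol/2, resampled beyond ±tol) is available via
`activity_error_dist="truncated_normal"`. The worst-case reading has a
consequence worth stating plainly: a single-seed pack then deviates beyond
the 5% intervention band with probability ≈ 1/6, so a full 433-pack replica
averages about six intervention flags — whereas the facility's real history
recorded none. The real per-seed spread is evidently much narrower than the
tolerance bound, but no measured distribution is available, so the
defaults keep the stated worst case rather than an invented narrower one.
Passing audits on synthetic data therefore demonstrate the pipeline's
bookkeeping, not the real facility's flag rate; conversely the generator's
*mean* calibration (and everything built on means: summaries, fits, power
analysis) is faithful. The generator also does not model seed-arrangement
irregularity or per-position geometry, only their lumped effect on the
mean, and the measurement noise magnitude (1%, multiplicative, mean-zero)
is a plausible well-chamber repeatability figure, not a measured one.

## Dead-seed power analysis

Deterministically, d dead seeds remove `d·mean/n` percentage points;
verdicts compare that with the intervention tolerance `0.05·mean`:
"yes" (strictly greater — a five-pack with one dead seed loses 17.02 points
against a 4.255-point tolerance), "borderline" (equal within 1e-9 — the
20-pack case, 3.35 = 3.35), "no" otherwise. The Monte-Carlo escape
probability simulates faulty packs under the full generative model and
reports the fraction reading inside the intervention band, with binomial
standard error. Under the defaults a dead seed in a five-pack never escapes
(even all four live seeds at +6% read 15.2% low, and the 1% noise cannot
bridge that), while in a 20-pack it escapes in roughly a third of packs:
3/20 of dead seeds land in a shielded position and remove almost no signal,
and an unshielded dead seed leaves the pack only ~0.8 points past the
limit, close enough for high seeds and noise to cancel. With spread, noise
and shielding differential all switched off, the MC collapses onto the
deterministic verdict ("yes" ⇒ escape 0, otherwise 1), which the tests
assert.

## Problem sizes and numerics

Monte-Carlo checks use 10⁴–10⁵ replicates (standard errors ≲ 0.05
percentage points on means, ≲ 0.005 on probabilities), chosen so the whole
suite runs in seconds at double precision. Escape judgments add a 1e-9
epsilon to the band edge so exactly-borderline packs are not flagged by
float rounding. Per-n summary means are clamped into [min, max] against
1-ulp rounding of the accumulated sum. Degenerate inputs are rejected with
typed errors (`InvalidParameterError`, `InputFormatError`,
`InsufficientDataError`, `ConfigurationError`) rather than propagating NaNs.

## Known limitations

- Stainless transmission (0.1) and reading noise (1%) are modelling
  choices, not measurements; conclusions that depend on their magnitude
  (the 20-pack escape probability above all) are indicative, not
  predictive.
- The per-seed error distribution is a worst-case bound; see above.
- The analysis covers batch assays only; identifying *which* seed is dead,
  single-seed assays, and imaging-based seed-count verification are out of
  scope.
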