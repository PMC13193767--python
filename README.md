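# seedassay

Batch-assay quality assurance for iodine-125 brachytherapy seeds.

Permanent prostate implants use blister packs of 1–20 sealed ¹²⁵I seeds that
cannot be opened without breaking sterility, so facilities verify delivered
source strength by a *batch assay*: the whole pack is measured at once in a
well-type ionization chamber and compared against the manufacturer's nominal
activity. `seedassay` implements the full analysis around that measurement:

- **decay correction** of chamber readings to the calibration (reference)
  date, `A(t) = A₀·2^(−t/T½)` with T½ = 59.4 d for ¹²⁵I;
- the **detection rate** statistic,
  `rate (%) = 100·M / (A_nom · n)` for a reading *M* (MBq), nominal per-seed
  strength *A_nom* and pack size *n*;
- **control limits**: acceptance (3%) and intervention (5%) bands centred on
  the facility's cumulative per-pack-size mean rate, with pack
  classification and batch audits;
- **calibration regression** of detection rate versus pack size — an OLS
  cubic `y = ax³ + bx² + cx + d` for the 1–5 seed regime and a log-linear
  model `y = a·ln x + b` once stainless-shielded 20-seed packs are included
  — with R² and prediction;
- **dead-seed detectability**: the expected rate reduction from a dead seed
  (`mean/n` percentage points each), the deterministic verdict against the
  intervention band, and a Monte-Carlo *escape probability* under per-seed
  activity spread, reading noise and shielding;
- a **calibrated synthetic generator** of blister-pack measurement logs
  (per-seed activities within the ±6% manufacturer tolerance, per-seed
  efficiencies calibrated so the expected rate matches the per-n mean
  table, three stainless-shielded seeds per 20-pack, injectable faults).

## Worked example

Fit both calibration models to the facility's cumulative mean detection
rates (102.5, 92.1, 87.5, 86.4, 85.1, 67.0 % for packs of 1, 2, 3, 4, 5, 20
seeds):

```python
>>> from seedassay import FACILITY_MEAN_RATES, fit_cubic, fit_log
>>> small = [(n, m) for n, m in sorted(FACILITY_MEAN_RATES.items()) if n <= 5]
>>> cubic = fit_cubic(small)
>>> cubic.coefficients
(-0.49999999999997136, 6.050000000000074, -25.150000000000148, 122.12000000000012)
>>> round(cubic.r_squared, 4)
0.9999
>>> log = fit_log(sorted(FACILITY_MEAN_RATES.items()))
>>> log.coefficients
(-11.404049392525021, 101.56004518589722)
>>> round(log.r_squared, 4)
0.9854
```

The cubic describes the small-pack regime almost perfectly (R² rounds to
0.9999): the rate declines with pack size as neighbouring seeds shield each
other, flattening towards five seeds. Adding the 20-packs pulls the data off
the cubic — their stainless cartridge section hides roughly three seeds —
and the log-linear model takes over (slope ≈ −11.4 % per ln-seed).

An end-to-end QA run on a synthetic delivery replica (433 packs matching
the facility's history):

```
$ seedassay report --seed 1 --out-dir out/
seedassay report (433 packs)

per-pack-size summary (cumulative mean %):
  n= 1  count= 20  mean= 102.1  min=  96.7  max= 108.3
  ...
  n= 5  count=197  mean=  85.1  min=  80.7  max=  89.7
  n=20  count=153  mean=  66.9  min=  64.9  max=  69.4

dead-seed power (1 dead seed):
  n= 5  expected_reduction=17.0 pct-pts  detectable=yes  escape_p=0.0000
  n=20  expected_reduction=3.4 pct-pts  detectable=borderline  escape_p=0.3718
```

A dead seed in a five-pack removes 17.0 percentage points — four times the
4.3-point intervention tolerance — and is always caught. In a 20-pack the
expected loss (3.35 points) exactly equals the intervention tolerance, and
the Monte-Carlo run shows the fault escaping detection in ~37% of packs
(shielded positions, or live seeds near +6% cancelling the deficit), which
is why 20-packs cannot be cleared without a single-seed assay.

The exit status of `seedassay report` is 0 only when no pack breaches the
intervention band, so the command can gate a clinical QA workflow. Other
subcommands: `simulate`, `rates`, `limits`, `fit`, `predict`, `deadseed`.

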