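# Methods

## Measurement models and quantifiers

### Dilution chain

All quantities are reported per gram of freeze-dried powder. The shared
physical chain is: powder rehydrated at `ml_per_g` mL of suspension per gram
(default 10.0, i.e. 11 g to 110 mL, a 1:10 w/v rehydration — the rehydration
volume is a package default, configurable, since protocols state the mass but
not always the volume), then fold-diluted before measurement. ddPCR and flow
records carry a fold `dilution_factor ≥ 1`; plate records carry a fractional
`dilution_level ≤ 1`. The simulator and the quantifiers use the same
`DilutionChain`, so quantification is the exact inverse of simulation up to
sampling noise.

### ddPCR

The occupancy estimator is λ̂ = −ln(1 − p) with p = positives/accepted, and
concentration λ̂/V_d copies per µL of reaction. Choices:

- **Droplet volume** V_d = 8.5 × 10⁻⁴ µL, the nominal droplet volume of the
  QX200 class of instruments; configurable per record.
- **Copies per cell** fixed at 1 (assays target single-copy unique
  sequences); configurable for multi-copy targets.
- **Merging** pools positives and accepted droplets across replicate wells
  before inversion, matching vendor merged-well semantics and minimising
  variance. Mixing dilution factors or droplet volumes within a merge is an
  error. At small λ pooling and averaging per-well estimates coincide (the
  inversion is locally linear); tests verify the agreement.
- **Confidence intervals** are Wilson-score intervals on p (better behaved
  than Wald at extreme p) mapped through the monotone λ transform and the
  dilution chain; level configurable, default 95%. Measured empirical
  coverage over λ ∈ [0.05, 3] at 3 × 20,000 droplets is 93–97%.
- **Saturation** (p = 1): the point estimate is censored (NaN), the interval
  becomes one-sided (finite lower bound, infinite upper), and the well is
  flagged. Wells with fewer than 10,000 accepted droplets (industry
  convention) are flagged `below_min_droplets` but not discarded.
- **Efficiency fits** regress measured copies on theoretical copies
  (reference × dilution fraction, anchored at fraction 1) by ordinary least
  squares *with* intercept — the through-origin variant is available via
  `include_intercept=False`. Efficiency is 100 × slope with a 90–105%
  acceptance window.

### Plate counts

Plates outside the inclusive 25–250 countable window are excluded; an empty
selection is a diagnosed, flagged outcome ("too numerous to count" / "too few
to count"), not an exception. The batch estimate is the ISO 7218-style pooled
weighted mean Σc / Σ(v·d) across countable plates, rather than the lowest
countable dilution alone; per-plate CFU/g values are retained because the
replicate-CV analysis needs the raw scatter, not just the batch mean.

### Flow cytometry

Instrument calibration (beads, fluorescence thresholds) is abstracted into an
analysed-volume factor: inputs are already-gated live/dead/total event counts
per analysed volume. The total gate equals live + dead exactly, enforced at
record construction (tolerance 1.5 events for rounding at gate boundaries).

## Agreement statistics

- CVs use the sample standard deviation (n − 1) over replicates divided by
  the mean, ×100, on the **linear** scale — log transformation deflates the
  CV and is deliberately not offered. Fewer than two replicates, or a zero
  mean, yields a flagged missing value (NaN).
- Method-level summaries are the mean ± sd of per-batch CVs, stratified as
  All / NCFM / Non-NCFM / per-strain.
- Pairwise comparisons use per-batch replicate means (one value per batch);
  batches missing in either method are dropped pairwise. Method 1 is the
  abscissa and the minuend of the relative difference, so "Plate vs
  PCR.live" with PCR.live reading high gives a negative mean difference.
- Bland–Altman differences are relative: d = (M1 − M2)/((M1+M2)/2) × 100,
  bounded in [−200, 200] by construction; limits of agreement are
  mean(d) ± 1.96 sd(d) (sample sd, n − 1; the multiplier is the conventional
  1.96 at the default 95% level, the exact normal quantile otherwise).
  The statistic is antisymmetric under swapping the methods. Pairs with zero
  average are excluded with a warning.
- No multiple-testing correction is applied anywhere, matching standard
  practice for descriptive method-comparison summaries.

## The simulator

The generator emulates a 50-batch production study across six strains
(20 NCFM, 9 Bi-07, 8 Lp-115, 8 HN019, 3 Bl-04, 2 La-14) with 17 plate
replicates and triplicates for ddPCR (per arm) and flow. Protocol
descriptions give both 17 plate replicates and "triplicate" plating without
reconciling them; the default is 17, configurable. Whether the 17 plates sit
at one dilution or are spread across dilutions is likewise unstated; the
simulator plates every level of a three-decade series so the quantifier must
apply the countable window itself.

Per batch, ground truth is a live concentration drawn log-uniformly on
(5 × 10¹⁰, 5 × 10¹¹) cells/g — a realistic potency range for freeze-dried
probiotic concentrates — and a dead concentration equal to live × a
lognormal dead fraction (mean 0.15, relative sd 0.3). The dead-fraction and
carryover parameters are calibration knobs of the simulator, not measured
quantities.

Measurement models:

- **Plate**: Poisson colony counts with mean live_conc × plated
  grams-equivalent × a lognormal replicate factor (relative sd 0.15).
  Replicate error is multiplicative lognormal because counts are positive
  and the spread is ~15%; no error law is prescribed by the protocol.
- **ddPCR**: effective template is live (+ 0.2 × dead in the viability arm,
  the fraction of dead-cell template surviving the dye treatment; + dead in
  full for the untreated arm); positives per well are binomial with success
  probability 1 − e^(−m) plus a 1% lognormal well-to-well error on m.
- **Flow**: a symmetric 2% misgating fraction mixes live and dead gates;
  each gate concentration carries an independent 3% lognormal error; total
  is live + dead exactly.

Randomness: one explicit study seed; each batch and stage draws from a
substream keyed by (seed, CRC32(batch_id), stage), so outputs are
bit-identical under a fixed seed and independent of batch ordering.

What the simulator does **not** emulate: DNA-liberation yield, primer
kinetics, droplet fluorescence amplitude ("rain") classification, stain
chemistry, colony morphology, batch-to-batch process drift, or inter-method
systematic offsets beyond the viability-carryover term. Consequently,
passing tests demonstrate the correctness of the quantifiers and statistics
and the qualitative noise ordering (plate ≫ flow > ddPCR), not the
quantitative magnitudes of real-world method disagreement: simulated
Plate-vs-PCR.live mean relative differences are around −2 to −3%, smaller
than is typical on production data, because the only systematic offset
modelled is the 0.2 × 0.15 carryover product.

## Problem sizes and numerical choices

- The estimator recovery study uses 20,000 droplets × 3 wells and 300–500
  replicates per occupancy, enough to resolve a 2% bias bound (Monte-Carlo
  standard error of the mean ≲ 0.05%) while keeping the suite quick.
- The qualitative study reproduction uses 20 independently seeded 50-batch
  studies; the CV ordering margin (≈20% vs ≈2.5% vs ≈1.2%) makes failures
  vanishingly rare, so 19/20 is a conservative pass bar.
- `simulate_ddpcr_wells` uses `expm1` for 1 − e^(−m) to stay accurate at
  small occupancy; `quantify_well` uses `log1p` for −ln(1 − p).
- Degenerate inputs fail loudly at construction (negative counts, positives
  exceeding accepted droplets, zero analysed volume, fold dilutions < 1) or
  produce flagged NaN values where the protocol treats them as missing data
  (uncountable plate series, single-replicate CVs, zero-mean CVs).

## Known limitations

- The original study's per-replicate table is distributed only as
  supplementary material without a public accession; the pipeline reads any
  CSV in the same long form (`batch_id, strain, method, replicate,
  count_per_g`), but the reported-number reproduction can only run when a
  user supplies that file at `data/study/measurements.csv`.
- Repeated-measures extensions of Bland–Altman (replicate-level pairing
  with within-batch correlation) are not implemented; pairing is by batch
  means, with a config hook for per-replicate pairing left to future work.
- The flow model abstracts the instrument entirely; FCS parsing and gating
  are out of scope.
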