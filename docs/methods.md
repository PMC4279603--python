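# Methods

## Plate model

One physical 96-well plate carries, per gene (transgene and reference gene,
48 wells each): a standard curve of 5 known-copy levels in triplicates
(15 wells), one no-template control, and 32 replicate wells of the sample
DNA, filled from two independent DNA isolations with 16 wells each
(2×48 − 2×15 − 2×1 = 2×32). One experimental run is re-analysed under
several instrument baseline/threshold settings; each setting is one Cq table
over the identical wells. The layout (well roles, isolation membership,
nominal GM content, conversion factor) comes from a YAML config because
vendor exports do not encode isolation membership; Cq tables are canonical
delimited text (`Well,Target,Task,Cq,Quantity`), with `Undetermined` kept as
an explicit missing marker and never coerced or dropped at parse time.

## Quantification

Calibration regresses Cq on log10(copies) by ordinary least squares
(scipy.stats.linregress), separately per gene and per setting, fitting
replicate standards as individual points. Regressing Cq on log-copies (not
the reverse) matches the convention of the instrument software whose
extrapolation the analysis mirrors; for a balanced design the slope is
identical to a fit of level means, only R² differs. Copies follow as
10^((Cq − intercept)/slope); the slope also yields the efficiency
diagnostic 10^(−1/slope) − 1.

A combination of wells is quantified as the **ratio of means**:
factor × mean(transgene copies) / mean(reference copies) × 100. Wells are
unpaired between genes on this design, so per-well ratios have no basis;
ratio-of-means also makes the all-wells case collapse to a single value, the
plate's one reportable number. The zygosity / mass-fraction approximation is
a single user-supplied multiplicative factor (default 1 — plain copy
ratio); it is material knowledge, not computable from the plate.

## Resampling plan

For each replicate setting 2×k (k = 2…16), `n_combinations` (default 5000)
tuples are drawn; a tuple takes k wells without replacement from each of the
four (gene, isolation) pools, independently across pools and tuples
(duplicate tuples among the 5000 can occur — exhaustive enumeration is
intractable at k = 8 already, C(16,8)⁴ ≈ 2.8×10¹⁶). "2×k" means k wells from
EACH isolation, i.e. 2k wells per gene per combination.

The plan is a pure function of (seed, pool sizes, ks, n_combinations):
per-k substreams come from `SeedSequence(seed, spawn_key=(k,))`, and the
k-subsets are the first k ranks of a uniform random matrix. Indices are
stored sorted within each subset so that equal subsets evaluate to
bit-identical means — at k = pool size every tuple is the full pool and the
population variance is exactly zero, with no floating-point residue. The
identical plan is applied to every setting; under the `exclude` policy for
undetermined wells, pools are shrunk by the union of wells undetermined in
*any* setting, preserving cross-setting comparability. The plan exports to a
plain-text table and re-imports bit-identically, which is what makes a
report reproducible years later.

## Statistics panel

The 5000 values of a cell are treated as the whole population, so all
moments use divisor n (population SD, never n−1) and the skewness is the
plain third standardised moment. Binning uses equal-width classes (default
20) spanning [min, max] of the population — class labels drift with the
data, as they should; an all-equal population falls back to unit-width
classes with a single occupied one.

The χ² check against Gaussian(mean, SD) uses exact interval probability
masses (CDF differences, computed through the survival function right of the
mean so far-tail masses keep full precision) with the marginal classes
extended to ±∞, times n. Sparse marginal classes (expected < 10) are
deliberately **not** merged — the simplified construction this package
standardises on — which makes the test anti-conservative in the far tails;
its p-value (upper-tail, displayed as %) is a descriptive fit index here,
not an inference tool. Degrees of freedom default to n_classes − 3 (mean
and SD are estimated from the data), configurable to n_classes − 1; the
choice shifts p but not χ² itself.

The cut-off summary finds the largest count threshold c such that classes
with count ≥ c jointly hold at least 95 % (configurable) of all values; ties
at the threshold are all included (the dashed-line semantics of the
histogram). It reports middle class (U_last + U_first)/2 and half range
(U_last − U_first)/2 over the included classes' upper limits — a robust
"middle ± spread" readout that ignores stray outlier classes.

`min_replicates_for_rsd` returns the smallest k whose relative SD is ≤ 15 %
(configurable) in **all** settings. 15 % is a deliberate margin below the
25 % relative repeatability SD that EU method-validation requires: a plate
whose intra-plate spread alone exceeds 15 % will struggle to stay below 25 %
under repeatability conditions.

## Synthetic plates

The generator emulates the Cq-level behaviour of the full plate with known
ground truth. Per sample well: template copies are Poisson-drawn at the
nominal mean (transgene mean = reference copies × GM% / 100; ~20 copies at
the defaults of 0.1 % and 20 000 reference copies — the Poisson draw is the
mechanism behind the right-skew of low-replicate distributions, which
Gaussian Cq noise alone cannot produce), then
Cq = slope·log10(copies) + intercept + isolation effect + N(0, cq_noise_sd).
Defaults: slope −3.3219 (perfect doubling), intercept 37 cycles,
cq_noise_sd 0.2 cycles (well-behaved assay scatter), isolation_effect_sd
0.1 cycles drawn once per isolation and applied to both genes' wells of that
isolation — a DNA-concentration effect of the extraction, which is why it
largely cancels in the copy ratio. Standards are generated noisily from
their nominal copies; NTCs are undetermined; a Poisson draw of 0 copies
yields an undetermined Cq, exercising the missing-Cq policy. Additional
baseline/threshold settings are emulated as independent N(0, 0.05 cycles)
per-well perturbations of the same base run (settings re-interpret one run;
they are not independent plates) — the jitter magnitude is a free parameter,
not an estimate of any instrument's behaviour.

What the simulator does *not* model: amplification-curve (fluorescence)
level effects, inhibition, pipetting-volume drift, systematic efficiency
differences between standards and samples, or structured (non-exchangeable)
isolation differences. Passing tests on synthetic plates therefore
demonstrate the correctness and internal consistency of the statistical
machinery under a realistic noise model, not the behaviour of any particular
assay or instrument.

## Test and verification sizes

Unit and property tests run on reduced problem sizes (hundreds of
combinations, 2–4 replicate settings) chosen to exercise every code path;
the end-to-end acceptance checks use the full defaults (5000 combinations,
ks 2…16, five settings) over a 50-seed ensemble for the trend and recovery
properties — trends (RSD non-increasing in k, skewness declining from 2×2 to
2×8, population mean within 15 % of the 0.1 % truth at 2×8) are asserted as
ensemble majorities, not per-seed certainties, because single seeds
legitimately fluctuate. The resampler is verified against exhaustive
enumeration on pools of 3 wells (81 possible tuples) within 3 Monte-Carlo
standard errors; skewness and χ² against independent brute-force evaluations
(math.fsum / math.erfc) to 1e-10.

## Numerical and design notes

- A constant population reports SD exactly 0 (guarding against the last-ulp
  residue of floating-point means); its skewness and χ² entries are NaN in
  the sweep rather than errors, so degenerate k = 16 cells don't abort a
  grid.
- Binning intervals are closed on the left, the last class closed on both
  sides (numpy.histogram convention).
- The χ² check refuses fewer than 4 classes and any class whose expected
  count underflows to zero even with open tails.
- NTC wells must be undetermined (or beyond a configurable Cq cut) and never
  enter fits.
- Undetermined sample wells: default policy `exclude` (dropped from the
  pools, identically for all settings); `zero_copies` is available for
  detection-aware studies where a non-amplification genuinely means zero
  template.
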