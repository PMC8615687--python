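# Methods

## Scope and data model

The package analyses targeted shotgun-lipidomics (MRM) data at the
sum-composition level: each analyte is a lipid class plus total acyl/alkyl
carbons and total double bonds (plus a hydroxylation flag for carnitines).
Individual sn-1/sn-2 fatty acids, isomers and stereochemistry are outside
the data's resolution and are never modelled. Eight classes are covered:
diacyl and plasmalogen PC and PE, their lyso forms, carnitines and TAG.

Input is a long-format table of counts-per-second with one row per
(sample, technical replicate, analyte), where analytes are either panel
species or spiked internal standards. Protein normalization of the input
material is assumed to have happened upstream: the table is taken at equal
protein input per sample.

## Normalization and aggregation

Every species intensity is divided by the intensity of its lipid-class
internal standard in the same injection, which cancels injection-to-
injection scaling (the pipeline is exactly invariant to multiplying all
intensities of one injection by any c > 0). The default standards map
assigns one standard per class; carnitines split between a short-chain
(octanoyl-d3; ≤ 10 acyl carbons, including free and acetyl-carnitine) and a
long-chain standard (palmitoyl-d3; > 10 carbons). Only one PE standard
exists, so all three PE classes share it. Both the map and the carnitine
threshold are configurable; the split at 10 carbons is the package's own
choice, placed midway between the two standards' chain lengths.

Technical replicates are averaged arithmetically (never by median) into one
ratio per biological sample. Missing replicates are tolerated with a logged
warning and the replicate count is recorded per cell; a cell with zero
replicates is an error unless the caller opts into dropping it.

## Differential statistics

*Percent of reference.* Per species, each sample's ratio is divided by the
reference-group mean (×100); the non-reference group's mean of these
relative values is the effect, their SEM its uncertainty. This is the
simplest construction that yields "105.1 ± 0.7%"-style class outputs at
n ≥ 5 per group, and it recovers injected multiplicative effects exactly on
noise-free data.

*Per-species test.* Classical pooled-variance two-tailed Student's t on the
raw group values (df = n₁+n₂−2), delegated to scipy; Welch is available
behind a flag. Degenerate zero-variance cases are resolved explicitly:
equal means → t = 0, p = 1; unequal means → p = 0, flagged and logged.
No multiple-testing correction enters the classification; a
Benjamini–Hochberg column is emitted for the reader only.

*Direction call.* A species is UP/DOWN "beyond SEM" when its percent of
reference exceeds 100 ± the class mean of the per-species SEMs — the
volcano plots' vertical lines. This retains consistently shifted species
that miss per-species significance at small n. The calls partition species
and are monotone in the percent for a fixed threshold.

*Class summary.* Mean ± SEM over member species' percents with a two-tailed
one-sample t-test against 100. The mechanism behind a single class-level p
is genuinely open; the one-sample t over species is this package's
documented choice, stated in the output schema.

*Fisher direction test.* Increased/decreased counts per experiment (sign of
percent − 100 over all species by default; beyond-SEM-only behind a flag,
as the counting rule is not canonical) form a 2×2 table tested with the
two-sided Fisher exact test: the sum of hypergeometric probabilities of all
tables with the observed margins whose probability is ≤ the observed
table's. Probabilities are compared as exact integers (numerators over a
common denominator), so the ≤ comparison involves no floating-point
tolerance; scipy's implementation serves as an independent cross-check in
the tests.

*p display.* p-values are stored at full precision and displayed rounded to
a configurable number of decimals, so very small values print as "0.000".

*qPCR.* The 2^−ΔΔCq utility computes ΔCq = Cq(target) − Cq(housekeeping)
per sample and ΔΔCq as the difference of group means.

## Composition statistics

mol% is defined within a lipid class (a species' share of the class total
per sample, ×100); because each class has its own internal standard the
normalized ratios are not comparable across classes and cross-class mol% is
deliberately undefined. Saturation categories are SFA/MUFA/PUFA by total
double bonds (0/1/≥2); chain-length bins are inclusive carbon windows
(PC/PE classes 32–36, lyso classes 16–20; none for carnitines and TAG), all
configurable. Categories partition each class, so category mol% sums to 100
per sample to 1e-9. Saturation ratios with zero denominators become flagged
missing values and are dropped pairwise from group statistics with a logged
count.

Carnitine energy ratios use the saturated species only (C18:0, C16:0) in
the numerators by default — the unsaturated chains are biologically distinct
species — with a flag to include C16:X/C18:X. The acetyl-carnitine (C2)
denominator must be present and positive.

## Matrix-effect QC

Because the standards are spiked at constant amounts, group differences in
their raw intensities measure ion suppression/enhancement by co-extracted
matrix rather than biology. The report gives the signed percent change of
the group-mean intensity per standard, (mean_b/mean_a − 1)×100, and the mean
of the absolute changes as the headline number. Group means (rather than
per-sample ratios) were chosen for stability at n = 5; whether the headline
should average signed or absolute changes is ambiguous in the field, and the
signed values are always reported alongside.

## Synthetic data generator

The generator emulates the study design the analysis assumes: two groups
(first label = reference) of 5 biological samples, technical triplicates,
the 240-species default panel with class counts 43/39/22/41/14/35/37/9
(PC_AA/PC_AE/LPC/CAR/TAG/PE_AA/PE_AE/LPE). Panel composition is
deterministic: a small set of known assay species is placed explicitly and
the rest fills plausible sum-composition grids (PC/PE 30–48 carbons, 0–6
double bonds; lyso 14–22; carnitines C0–C18 with OH variants; TAG 44–56).

All noise is multiplicative log-normal with mean 1 (σ_log = √ln(1+CV²),
μ_log = −σ²/2, so arithmetic means are unbiased): baseline abundance per
species (log-sd 1.0 across the panel, giving realistic order-of-magnitude
spread of ratios around 1), one shared biological draw per (sample, species)
at CV 0.10 — which is what makes averaging technical replicates meaningful —
and independent technical draws per injection at CV 0.05. A non-reference
sample's true value is baseline × class effect × optional per-species
jitter; the true percent of reference (100 × effect × jitter) is attached as
ground truth. Standards are generated at a constant spiked intensity times
an optional per-standard matrix factor in the non-reference group, times
technical noise.

Randomness uses one master seed with per-analyte substreams keyed by a hash
of the canonical name, so adding/removing panel species never reshuffles
other species' draws and equal seeds give byte-identical CSV output.

What the generator does **not** emulate: isotope patterns and peak
interference, heteroscedasticity across the intensity range,
batch/run-order drift, missing-not-at-random dropout near the detection
limit, and correlated biology between species of one class. Passing tests
therefore demonstrate correctness of the computations and calibration under
the stated noise model, not robustness to all features of real MRM data.

## Validation choices and problem sizes

* Type-I calibration pools per-species t-tests from 42 independent null
  simulations of the 240-species panel (10,080 tests), which keeps a single
  run ~10 s on one CPU; the expected fraction at p ≤ 0.05 is 0.05 and the
  mildly skewed log-normal noise at n = 5 lands slightly below it.
* Parameter recovery averages the recovered diacyl-PC class effect over 100
  seeds at default noise against an injected 1.05.
* Matrix-effect recovery averages 100 seeds at technical CV 0.02 against an
  injected 2% suppression; the measured quantity involves only the standard
  rows, so a reduced species panel is used for speed.
* Fisher and t-test primitives are checked against independent oracles
  (exact-rational enumeration over all 2×2 tables with margins ≤ 12;
  the closed-form pooled-variance formula on 1,000 random group pairs).

## Known limitations

* Sum-composition only; no isomer resolution, no LIPID MAPS mapping, no
  MRM transition (Q1/Q3) bookkeeping.
* Semiquantitative throughout: ratios to class standards, not absolute
  concentrations.
* The class-level p-value mechanism and the Fisher counting rule are
  package choices where the field's conventions are underdetermined; both
  are flagged in the output schema and configurable where sensible.
* No correction for multiple testing in the headline classification
  (deliberate, to keep the beyond-SEM reading of volcano plots); use the
  emitted Benjamini–Hochberg column when a corrected view is needed.
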