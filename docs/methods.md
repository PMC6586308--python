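# Methods

## Scope and data model

The pipeline starts at *sized peak tables*: per-sample lists of
(marker, dye, fragment size in bp, height in RFU) rows as exported by CE
fragment-analysis software after internal-standard sizing (LIZ-600). Raw
trace processing, dye spectral calibration, and allelic-ladder development
are out of scope. All loci are tetranucleotide repeats: one repeat unit = 4
bp. Alleles are written `R` (full repeats) or `R.m` with m ∈ {1,2,3} extra
bases; ordering is by implied length 4·R + m.

The assay panel carries 19 mouse markers and two human markers (D8S1106,
D4S2408) used solely as a contamination screen; human markers never enter
mouse profiles, matching, or concordance. The `core18` panel revision drops
marker 11-1, whose products show a ±1 bp "shoulder" from incomplete
adenylation; under the full panel, 11-1 calls are always flagged
`shoulder_risk`.

## Binning

Bins map size windows to alleles. Anchored bins sit exactly at the measured
calibrant sizes. Extrapolated bins extend the ladder in steps of one repeat.
The step size is the locally calibrated per-repeat spacing — the spacing
implied by the two nearest anchors when at least two exist — and exactly 4.0
bp for single-anchor markers; CE mobility makes the true spacing drift
slightly from nominal, which is why local calibration is preferred where
possible. Each microvariant class gets its own ladder; a class with no anchor
of its own is offset from the nearest anchored ladder by the microvariant
base difference. Ladders cover the marker's known allele range plus an
`extension_limit` (default 10 repeats) beyond the outermost anchor on both
sides — wide enough that a single anchor at allele 22 still yields a bin for
allele 28, six repeats out.

Numerical choices: default bin half-width 0.5 bp (the common fragment-
analysis convention; the value used by the consortium laboratories' software
is not public, so it is exposed as a parameter). A query exactly equidistant
between two bins resolves to the smaller allele and warns. Queries outside
every window return `off_ladder` with the nearest allele as a suggestion.
With half-width ≤ 0.5 bp, microvariant and full-repeat ladders cannot capture
each other's queries (they are ≥ 1 bp apart), so ladder independence is
automatic at the default.

## Calling

Per marker: peaks below `min_height_rfu` (default 100) are dropped — if a
marker thereby loses all peaks it is flagged `low_signal`. The floor applies
both to allele eligibility and to the peaks entering stutter-ratio
computation; `min_height_for_alleles=False` restricts it to ratio computation
only, since practice varies. Surviving peaks are paired: a peak within
`stutter_match_tol_bp` (default 0.5 bp) of a taller peak ± 4 bp is a stutter
candidate at position −1/+1; when several parents compete at the same
position the tallest governs (yielding the smallest, most-filterable ratio).
Disposition is ratio-only and strict: −1 candidates are alleles iff ratio >
0.20, +1 iff ratio > 0.10; a candidate in both positions must pass both. A
kept allele that also sits in a stutter position is flagged
`stutter_overlap`. Called peak sizes then pass through the bin set;
extrapolated and off-ladder calls are flagged.

Mixtures are never resolved: stutter filters are invalid for multi-
contributor samples, so gross sister-allele height imbalance (min/max height
ratio < 0.3, an artifact-level default, not an empirical claim) is flagged
`imbalance` for review. Any called allele at a human marker classifies the
sample `human_detected`, with the markers and alleles as evidence.

## Stutter statistics

Stutter ratio = stutter height / parent height. Filter recommendations are
mean + 3·SD using the sample (n−1) SD — the estimator is not specified in
common practice write-ups, and n−1 is the conservative choice; single-
observation groups return the mean flagged `low_n`. Only minus-position
observations from diploid samples feed filters (plus-stutter is summarized
separately; aneuploid lines have unrepresentative balance).

For the instrument comparison each ratio is divided by its (marker, allele)
group mean — repeat length is the dominant variance source — then averaged
per (marker, instrument). The Friedman statistic is the tie-corrected
chi-square on within-marker ranks, implemented in-package because the
two-instrument case is needed (SciPy's requires ≥3 treatments); it is
cross-checked against SciPy for ≥3 treatments and against an exhaustive
within-block permutation oracle for 2 treatments. The exact permutation
p-value is available for ≤5 treatments × ≤12 blocks; otherwise the
chi-square (k−1 df) asymptotic is used, with p = 1 at statistic 0.

## Matching and concordance

Master's percent match uses set semantics (a homozygous locus contributes
one allele) and the questioned profile's allele count as denominator, so the
measure is asymmetric; both directions are exposed, and reports round to the
nearest integer percent while retaining the raw value. Markers uncalled on
one side contribute only the called side's alleles to totals. Relatedness
classes: > 85% same-or-derivative, > 80% related, else unrelated
(configurable). The nearest-neighbor distance is the per-marker symmetric
difference of allele sets, summed.

Agreement proportions follow the calls-made weighting: a marker score is the
sum of per-call proportions divided by the number of calls made at the
marker across labs, and the line mean likewise over all calls. Concordance
is identity of call sets across labs at every marker; means are reported to
3 decimals. The consensus profile (majority rule, > 50% of labs) is used
only to count expected calls. Reason codes are restricted to a–e (low
signal, stutter-ratio error, ratio at threshold, missed allele, artifact).

## Synthetic data generator

The generator emulates what the pipeline consumes, not raw fluorescence:
per true allele a sized peak (Gaussian sizing noise, SD 0.15 bp — typical CE
precision), lognormal height (mean 2000 RFU, CV 0.25), and stutter peaks at
±4 bp whose ratio is linear in repeat count with Gaussian noise, clamped to
[0,1]:

    ratio = clip(intercept + slope·repeats + N(0, σ) + instrument_offset, 0, 1)

Defaults: minus-stutter intercept 0.01, slope 0.005/repeat, σ 0.01;
plus-stutter 0.005, 0.001/repeat, σ 0.004. These were chosen once as
realistic for tetranucleotide chemistry — they put marker-level mean+3SD
filters in the 12–23% range over the panel's known allele ranges, the
magnitude regime of published recommendations — and are parameters, not
claims: the true distributional forms for this chemistry are not published.
Instrument offsets default to −0.01 for the 3130xl/3500xl class versus 0 for
3730/3730xl, an absolute reading of the observed ~1-percentage-point
platform difference. Dropout, marker-level low signal (multiplicative height
factor), and artifacts (pull-up onto another dye's marker, dye blob, spike,
and the 11-1 ±1 bp shoulder) are off by default and injected by rate.

Interlaboratory studies are simulated at the call level: per lab,
per-call Bernoulli errors (missed allele, bin shift, stutter miscall,
marker-level low signal, artifact), each logged with its ground truth and
reason code.

What passing tests on synthetic data do **not** show: robustness to real CE
baseline/morphology effects, true inter-run mobility drift, mixed-sample
deconvolution (explicitly out of scope), or the actual multi-laboratory
stutter distributions — the published filter magnitudes ship as a reference
fixture, not as a reproduction target, because the underlying raw multi-lab
observations are not public.

## Problem sizes in tests

Monte-Carlo checks use sizes chosen for tight statistical margins at
interactive runtimes: 200 clean replicates for the generate→call→match
closed loop (pass bar ≥ 99% self-match), 60 replicates for Friedman power at
the −0.01 offset (bar ≥ 80% rejection at α = 0.05, actual power ≈ 1 at these
settings), ≥ 200 observations per marker for filter recovery within ±10%
relative, and 500 random profile pairs against the brute-force matching
oracle.

## Known limitations

- Fragment sizes for anchors are synthetic (offset + 4·repeats + microvariant)
  because real amplicon flanks are primer- and instrument-specific; all such
  stand-ins are labelled synthetic.
- The "99.6%" style consensus figures quoted in study write-ups mix two
  nearby definitions (per-call mean vs correct-call fraction, both ≈ 0.997
  for the NIH/3T3 table); this package reports the per-call mean.
- Stutter linearity in repeat count is the simplest monotone model;
  microvariant alleles with shorter uninterrupted repeats are known to
  stutter less than the model predicts.
- No genotype-frequency match probabilities; percent match is descriptive.
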