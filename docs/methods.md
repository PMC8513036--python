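# Methods

`glycolda` reimplements, as a tested pipeline, a serum glycomics biomarker
workflow for alpha-1-acid glycoprotein (AGP): anthranilic-acid (AA) labeled
N-glycans are separated by HILIC into sialylation clusters, isomers are
characterized by negative-mode MS/MS, per-isomer peak areas are converted
to relative abundances, and a small panel of Fisher-ranked features drives
a linear discriminant classifier evaluated by repeated random-subsampling
cross-validation.  The original clinical cohort (18 high-risk melanoma
patients, 19 healthy controls, 102 detected glycan isomers) is not publicly
deposited, so a synthetic-cohort generator reproduces its statistical
structure for testing; nothing in this package estimates anything about
real patients.

## Mass arithmetic

Monoisotopic residue masses (Da): HexNAc 203.07937, Hex 162.05282, NeuAc
291.09542, dHex/Fuc 146.05791; water 18.01056; CO2 43.98983.  The AA label
adds a fixed +121.05276 Da (2-aminobenzoic acid attached by reductive
amination: +AA − H2O + H2), verified against the published reducing-end
Y-ion series.  Negative-mode ions are [M − zH]^z−; m/z is computed by
subtracting one hydrogen atom (1.007825 Da) per charge, neglecting the
electron mass (0.00055 Da, below the 0.01 reporting precision).  This
convention — rather than subtracting a bare proton — is frozen because it
is the one that reproduces the full published two-decimal ion table,
including the unfucosylated Y1 at 341.13 (the proton convention yields
341.135, which rounds to 341.14).  Comparisons against printed tables use
round-half-away-from-zero at two decimals.

Two published values cannot be reproduced exactly under any deprotonation
convention, because they are internally inconsistent with their own ion
series: the core-fucosylated Y3/Y4 printed as 1014.37 and the
antenna-series Y4/Y5 printed as 1395.51 differ from their printed series
neighbours by 162.06, while one hexose residue is 162.0528 Da.  Theory
places them at 1014.38 and 1395.50; both agree with print to within one
unit of the last printed digit, and the tests assert exactly that.

## Topology and fragmentation

Glycans are rooted residue trees over the canonical complex-type template:
Man3GlcNAc2 core, GlcNAc–Gal antennae on the two branch mannoses (1+1,
2+1, 2+2 placement for 2–4 antennae), N-acetyllactosamine repeats
extending the last antenna when the composition exceeds four antenna
units.  Which arm carries the extra antenna is a template assumption; no
downstream computation depends on it.  Sialic acids carry linkage tags
(α-2,3 / α-2,6 / unknown) and fucoses position tags (core / antenna).

Glycosidic cleavages produce B/C (non-reducing side) and Y/Z (reducing
side, label retained) ions; multi-cleavage Y/Z ions are generated for up
to three pairwise-independent cuts, matching the deepest published label
(a triple-cleavage Y ion).  Cross-ring enumeration is deliberately
restricted to the two linkage diagnostics actually used in this workflow:
0,4A2−CO2 at m/z 306.12 (α-2,6) and B2−CO2 at m/z 408.15 (α-2,3), both
recomputed from residue masses rather than stored.

Isomer assignment returns evidence, not verdicts: each flag is backed by
matched ions (default tolerance 10 ppm, a config knob; the instrument
resolution was 17,500 FWHM and no tolerance was published).  Core
fucosylation requires a fucose-retaining Y1, with Y2 corroboration raising
a confidence field — mirroring the published case of a low-intensity
isomer called from a reduced ion set.  Antenna fucosylation requires the
fucose-free Y1 and Y2 together with at least one larger fucose-free Y ion,
reflecting the preferential loss of the more weakly bound antenna fucose.
Note that two-decimal literature m/z values can sit up to ~15 ppm from
theory at low mass (0.005 Da at m/z 341), so tests built from printed
values use a 20 ppm tolerance; matching against measured or simulated
peaks uses the 10 ppm default.  An intensity floor for diagnostic calls
exists as a knob (`min_intensity`) but defaults to 0 since no threshold
was published.

## Quantification

Per sample, each isomer's area is expressed as a percentage of the summed
areas (closure to 100), which cancels injection and response differences.
Feature families: isomer percentages, per-glycan sums, and within-glycan
isomer ratios (i/j in elution order).  Ratios are identical whether
computed from raw or relative areas, since the per-sample total cancels.
Zero-denominator ratios are floored at half the smallest nonzero isomer
percentage in the matrix and flagged; zero-area isomers are kept as 0%.
Group summaries report class means, melanoma/control fold change, and
per-class RSD with the n−1 standard deviation.  Closure makes features
negatively correlated by construction; the generator reproduces this so
the statistics are tested under realistic compositional dependence.

## Discriminant analysis

Fisher's index is the one-way ANOVA variance ratio, F = [Σ n_g(μ_g −
μ)²/(G−1)] / [Σ(x − μ_g)²/(n−G)]; with two classes this is the square of
the two-sample t statistic.  Features are ranked by F with deterministic
lexicographic tie-breaking.  Zero within-group variance with separated
means yields an infinite sentinel.  The published study reported only
"the ratio of between and within-group variances", so the degrees-of-
freedom convention is documented here rather than inferable from its
table, whose F values cannot be recomputed without the raw cohort.

The classifier solves S_w w = μ_mel − μ_ctrl with S_w the pooled
within-class scatter, shrunk as (1−λ)S_w + λ·diag(S_w) with λ = 10⁻³
(25 training samples × 10 features can be ill-conditioned; the source
procedure is silent on regularization).  The threshold is the midpoint of
the projected class means — equal priors, reasonable at 18/19 class
balance — and a sample exactly on the threshold is called melanoma (the
screening-oriented tie rule).  A small-sample rule requires the number of
predictors to be below one-third of the cohort size; it is enforced at
selection time against the full cohort (k < n/3, i.e. k ≤ 12 at n = 37),
not against the 25-sample training folds, because the original procedure
itself fits 10 variables on 25 training samples.

Validation follows the "leave-1/3-out" scheme: 25 of 37 samples drawn
uniformly without replacement (unstratified by default; stratified
optional), the 12 held-out samples predicted, 10 repetitions, confusion
counts pooled — 120 predictions at the defaults.  Draws missing a class
are redrawn up to a bounded retry count.  By default the feature panel is
fixed once on the full cohort before CV, replicating the original design;
`nested=True` re-selects features inside each training fold, which removes
selection leakage and is the honest generalization estimate (the
shuffled-label null test uses nested selection for exactly this reason).
Variable ablation refits the model ten times, each time omitting one
panel feature, and reports resubstitution confusion counts.

Report metrics (sensitivity, specificity, PPV, NPV, accuracy; melanoma
positive) are recomputed from integer confusion counts and rounded to one
decimal, half away from zero.  Two published cells disagree with their own
printed counts (cross-validation sensitivity 94.6 vs 52/55 = 94.5;
classification PPV 94.7 vs 15/16 = 93.8); this package always reports the
count-derived values.  Undefined metrics (zero denominator) are reported
as not available, never as 0.

## Synthetic cohorts

The generator's defaults are the study conditions: 18 melanoma + 19
control samples over a shipped catalog of 102 isomers across 28 sialylated
complex-type compositions, with isomer counts satisfying every published
inventory constraint (five N4H5SF peaks, three N4H5S2 peaks, at most eight
isomers per glycan).  Baseline abundances — dominated by bi- and
triantennary di/trisialylated species — and RSDs are synthetic
placeholders, clearly marked as such, since the true values were never
published.

Raw areas are drawn per isomer as: class-adjusted mean × per-sample
response scale (lognormal, sd 0.3) × shared per-glycan factor (lognormal,
CV 0.25) × isomer residual (lognormal by default, gamma alternative, CV
from the catalog: 20% for the ten panel isomers, 30–45% elsewhere, giving
total isomer-level RSDs of roughly 32–50%).  The shared per-glycan factor
models common-mode variation (regulation, extraction, XIC integration)
that cancels in within-glycan ratios — the premise that makes isomer
ratios useful features — so ratios are more stable than raw levels, as in
replicate glycomics data.  Closure is *not* imposed on raw areas; the
relative-area step has to recover it, which makes the per-sample scale a
real test rather than a no-op.

Melanoma effects are multiplicative on isomer means: the designated panel
glycans at 1.8× (fucosylated up) and 0.55× (nonfucosylated counterpart
down), donor→acceptor shifts of 25–30% of a glycan's earlier-eluting
isomer toward the later-eluting one (the α-2,6 shift), and mild 0.85–1.3×
effects on peripheral glycans to reflect the reported
fucosylation-proportional trend without letting them dominate the panel.
The ten designated features (four isomer ratios, three isomer levels,
two glycan sums and one more ratio) mirror the published panel structure.
Ground truth ships with each cohort and suffices to recompute expected
relative-abundance fold changes analytically, including the closure
correction.

What passing tests do and do not show: the generator demonstrates that the
pipeline recovers planted effects of the published direction and magnitude
under realistic compositional noise at the study's sample size — it cannot
validate the clinical claim itself, and per-feature effect magnitudes are
configuration, not estimates.  Real data additionally contain
retention-time drift, batch effects, heteroscedastic integration error and
detection dropouts, none of which are simulated.

## Problem sizes and numerics

The test suite runs the full synthetic study (37 samples × 295 features),
a 200-sample null cohort for the shuffled-label check, and 400-sample
cohorts for moment-recovery checks; property tests use seeded/derandomized
generation.  Brute-force verification of the discriminant direction scans
20,000 angles on two-feature instances.  Linear solves use
`scipy.linalg.solve` on symmetric matrices; singular scatter after
shrinkage raises with advice to increase λ.  Determinism: all randomness
flows through `numpy.random.default_rng` seeded from the config, so equal
seeds give byte-identical tables, spectra and reports.

## Known limitations

- Topology templates are canonical; genuinely ambiguous branch placements
  (noted in the source for highly branched species) are not enumerated.
- Only the two published cross-ring diagnostics are generated; exhaustive
  A/X ion enumeration is out of scope.
- No chromatogram simulation, peak integration, RT prediction or raw
  vendor-file handling; the pipeline starts at the annotated peak table.
- Binary classification only; no probability calibration or ROC analysis.
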