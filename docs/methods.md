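# Methods

## Scope and data model

The pipeline starts at a clones × samples matrix of log2(test/reference)
ratios from a BAC-array CGH experiment; raw-image quantification and
normalization are upstream of this package. Clones live on an ordered map
(chromosome, 0-based half-open coordinates, stylized cytoband, optional
gene annotation); the map's clone count m is the multiple-testing universe.
Missing measurements are first-class: every frequency, burden count and
test uses the *informative* denominator — the non-missing samples for that
clone in that group — which is why denominators vary from clone to clone
(23/24, 33/35, …). Sample groups are exactly two, e.g. cell lines vs
primary tumors.

## Calling

A measurement x is called a gain when x > +0.25, a loss when x < −0.25,
and additionally an amplification when x > +1.0. All comparisons are
strict; a value exactly at a cut-off stays neutral (ties are measure-zero
under continuous noise, and the choice is isolated in `call_cell`).
Amplification is a flag on top of a gain, not a fourth exclusive state, so
gain frequencies include amplified clones while amplification counts are
tallied separately. Calls are per clone; no segmentation or smoothing
across neighbors is applied. Non-finite, non-missing input is an error.

On pure noise with σ = 0.1, the gain-call rate is the Gaussian tail
Φc(0.25/0.1) = Φc(2.5) ≈ 0.62%; the test suite checks this calibration
within three binomial standard errors.

## Group comparison

Per clone and aberration type (gain, loss or amplification), the 2×2 table
of aberrant vs non-aberrant counts in the two groups is tested with the
Pearson chi-square **without** continuity correction, two-sided, 1 df.
This flavor was fixed by calibration: recomputing reference per-clone
tables from their printed counts reproduces the printed P-values to all
printed digits (e.g. 18/24 vs 1/35 → 5.68551×10⁻⁹; 13/24 vs 19/35 →
0.992806112), which neither the Yates-corrected chi-square nor Fisher's
exact test does. Fisher is offered behind a flag and serves as a
cross-oracle in the tests (rank correlation of P-values > 0.99 over random
small tables).

Degenerate tables (no aberrant sample in either group, or aberrant
everywhere) carry no contrast and are reported as χ² = 0, P = 1 with a
`degenerate` flag. Clones with zero informative samples in either group
are excluded and counted. Significance is P < α/m with α = 0.05 and m
defaulting to the full clone count of the map (4030 for the default map),
not the number of testable clones; the exact quotient 0.05/4030 =
1.2407×10⁻⁵ is used (the commonly quoted 1.25×10⁻⁵ is a rounding of this
value). All clones are reported sorted by P, so any display cut-off can be
applied downstream.

Significant clones of one chromosome and direction are merged into regions
across gaps ≤ 3 Mb (about three clones at the default spacing; the gap is
configurable and the value is a package choice, not a literature constant).

The burden contrast (number of gained/lost/amplified clones per sample) is
a two-sided pooled-variance Student t-test by default — the literal
reading of "Student t-test" — with Welch behind a flag; a summary-statistic
entry point (`ttest_from_summary`) accepts (mean, SD, n) per group because
published reports often print only summaries. SDs use the n−1 denominator.

## Synthetic cohorts

The generator emulates the study design the package targets: two groups of
24 and 35 samples on a ~1 Mb BAC array. The stylized genome keeps roughly
human chromosome proportions (autosomes + X; Y excluded, as appropriate
for a breast cohort with gender-matched reference DNA) but scales lengths
so the default 1 Mb tiling yields exactly 4030 clones. Cytobands are
fixed-width (10 Mb) bands numbered outward from a per-chromosome
centromere — adequate for naming regions, not a real ideogram.

Each sample draws, in a fixed documented order (contamination → planted
events → passengers → noise → missingness, one seeded generator):

- **Contamination** c ~ Uniform(0, 0.10), one global value per sample,
  mimicking microdissected bulk tissue with residual normal cells below
  10%. The uniform law is a stand-in; only the ≤ 10% bound is anchored.
- **Planted events** carried independently with the per-group prevalence;
  defaults: gain CN 3, loss CN 1, amplification CN 6. CN 6 keeps
  amplification detectable at c = 0.10 (log2(2.80) ≈ 1.49 > 1.0).
- **Passengers**: Poisson(2) private segments per sample, placed uniformly
  (chromosome weighted by length), lengths log-uniform on 1–20 Mb, gain or
  loss with equal probability.
- Overlaps within one sample resolve by precedence amplification > loss >
  gain; the resolved integer copy number per clone is recorded as truth.
- **Measurement**: x = log2(((1−c)·CN + 2c)/2) + N(0, σ) with σ = 0.10,
  clamped below at −5 (a homozygous deletion in a pure sample is −∞
  otherwise); then cells drop to missing with probability 0.02,
  independent of state.

The bundled breast cohort plants shared gains (distal 1q, 8q22) and losses
(17p, 11q23) at ~0.54–0.63 prevalence in both groups; cell-line-specific
gains (20q11, 20q13, 5p14-15) at 0.75 vs 0.03; cell-line-specific losses
(4p13-p16, 18q12, 18q21, Xq21, Xq26-q28) at 0.67–0.75 vs 0.03, anchored to
the strongest recurrent clone per region in published tables of the
emulated design; and a narrow 17q12 amplicon (the HER2-locus analogue) at
0.417 vs 0.171.

What the generator does **not** model: intra-tumor heterogeneity and
mosaicism, GC/wave artifacts, probe-specific variance, dye-swap replicate
structure, correlated missingness (e.g. whole failed hybridizations), and
real genome coordinates. Passing tests therefore demonstrate the
statistical machinery under idealized homoscedastic noise, not robustness
to array artifacts.

## Validation protocol

Beyond unit oracles, the suite checks:

- **Exactness**: printed reference P-values from printed counts, to all
  printed digits; threshold arithmetic.
- **Calling correctness**: with σ → 0 and c = 0 the call matrix equals the
  planted states exactly for CN ∈ {1, 2, 3, 6}.
- **Noise calibration**: null-cohort gain-call rate vs the Gaussian tail.
- **Family-wise error**: over 20 seeded null cohorts (4030 clones,
  24 + 35 samples, gains and losses both tested), the proportion of
  cohorts with any Bonferroni-significant clone stays within binomial
  error of α (empirically 0: the chi-square is heavily discrete at these
  counts, making Bonferroni conservative).
- **Parameter recovery**: at the emulated sample sizes the per-clone
  chi-square sits close to the α/m cut-off for contrasts like 0.67–0.75 vs
  0.03 — entire regions can miss significance when the binomial carrier
  draw lands low (e.g. 14/24 vs 3/35 → P = 3.4×10⁻⁵ > 1.24×10⁻⁵), which is
  a property of the design, not of the implementation. Recovery is
  therefore judged per region by majority across 10 seeded cohorts: each
  cell-line-specific region must contain ≥ 1 Bonferroni-significant clone
  in more than half the seeds and be localized with Jaccard > 0.5 (between
  the planted interval and the union of overlapping aggregated regions of
  the right direction) in more than half; each shared region must be clean
  in more than half. Generator prevalences were fixed from the emulated
  design before this protocol was evaluated and were not adjusted to it.

Problem sizes (20 null cohorts, 10 recovery cohorts, 200 oracle tables)
are the package's standing defaults; they keep the full suite at about a
minute while leaving the binomial error bars far from the pass boundaries.

## Numerical and design choices

- Coordinates 0-based half-open everywhere; BED input native; one
  convention avoids off-by-one in region merging.
- Missing on disk: empty cell or "NA" accepted, "NA" written.
- Ratio TSVs are written with `repr` floats and parsed with Python's exact
  `float()` (pandas' fast parser is 1 ulp off), making write→read a
  bit-exact round trip.
- P-values are printed in scientific notation with six significant digits.
- Group 1 is the lexicographically first group label ("cell_line" sorts
  before "tissue" in the bundled cohort).
- One `numpy` Generator seeded from the cohort seed drives all simulation
  draws in documented order; identical spec + seed ⇒ bit-identical outputs
  end-to-end (checked by byte comparison of a full pipeline run).
- The X chromosome is an ordinary chromosome (gender-matched reference
  assumed); Y is absent from the default map.

## Known limitations

- Per-clone testing ignores spatial correlation between neighboring
  clones; regions are a post-hoc merge, not a segmentation model.
- The Bonferroni criterion with m = 4030 is conservative for discrete 2×2
  tables at n = 24 + 35; borderline real differences (P between α/m and
  ~10⁻⁴) will be reported but not flagged.
- The chi-square is asymptotic; with expected counts near zero its P-values
  are approximate (kept deliberately, as the calibration target behaves
  this way). Fisher's exact test is available when exactness matters more
  than comparability.
- Burden t-tests assume approximate normality of per-sample counts; with
  heavy-tailed burden distributions the pooled test is only indicative.
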