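# Methods

## Model and scope

The package operates on genotype-level mean yields from a two-environment
trial: one value per genotype under non-stressed conditions (Yp > 0) and
one under stress (Ys ≥ 0), in the same units. Replicate-level structure
(blocks, factorial designs) is deliberately out of scope — means are
aggregated upstream — because every downstream quantity (the nine indices,
ranks, PCA, grouping) is a function of the (Yp, Ys) pairs alone. One trait
pair is analysed per run; multi-trait files are handled by re-running with
an explicit column mapping.

Yp = 0 is rejected at ingest since SSI, YSI and RSI divide by the
genotype's Yp; Ys = 0 is allowed (all indices remain defined). Trial-level
degeneracies degrade gracefully rather than aborting: Ȳs = Ȳp makes SSI
undefined (NaN column, warning, excluded from rank aggregation), Ȳs = 0
does the same to YI and RSI, and Ȳs > Ȳp computes SSI as-is with a warning
that its minimum-is-best reading inverts.

## Indices and relative change

All nine indices follow their standard definitions (see the README table).
RC is defined as 100·(Yp − Ys)/Yp — percent decrease versus the control —
and is signed: negative when stress increases yield. Indices are computed
in double precision from the raw ratios with no intermediate rounding;
the configurable display precision (default 2 decimals) only sets the
workbook's number format, so stored values round-trip exactly and rank
order can never depend on display rounding. RSI is used as the general
form of the relative drought index (same ratio-of-retention construction);
no separate RDI is reported.

## Ranking and ASR

Each of the 11 variables (Yp, Ys, nine indices) is ranked with rank 1 =
most favourable under its selection direction (smallest for TOL and SSI,
largest otherwise). Ties receive average (fractional) ranks — consistent
with Spearman correlation downstream — so every rank column sums to
n(n+1)/2. The ASR is the mean of a genotype's 11 ranks and the reported SD
is the sample standard deviation (n−1) of those ranks; RC is excluded
(it duplicates the ordering of YSI). A 9-column variant (indices only,
`asr_columns=9`) is provided because the aggregation set is a convention,
not a theorem; both variants leave the rank columns themselves unchanged.
Overall ordering sorts by ascending ASR, ties broken by ascending rank SD,
then input order (stable).

Exact rank equivalences hold by algebra and are asserted in tests: YSI and
RSI always produce identical rank columns (positive scalar multiple), and
when Ȳs < Ȳp the SSI column equals the YSI column (decreasing affine map
ranked in the opposite direction).

## Frequency classes

Distributions use equal-width classes spanning [min, max] with half-open
intervals [lo, hi), the last closed; the default class count is Sturges'
rule ⌈log2(n) + 1⌉, overridable via `n_bins`/`--bins` since any class rule
is a presentation choice. Undefined values are excluded with a warning and
frequencies renormalised over the defined ones; a constant vector yields a
single class of frequency 1. Class membership lists preserve input order.

## Association

Pearson coefficients are computed on raw values, Spearman coefficients as
Pearson on the direction-aware rank columns. The latter choice (rather
than textbook Spearman on values) reflects that the ranks are the object
of interest for selection: a minimum-is-best index whose ordering agrees
with a maximum-is-best one correlates at +1 here where the textbook
coefficient would be −1. This sign flip affects only TOL and SSI and is
intentional. Two-sided p-values use t = r√((n−2)/(1−r²)) with n−2 df;
pairs with undefined entries are pairwise-complete; zero-variance columns
produce NaN with a warning. Raw significance is reported (stars at 0.05
and 0.01); a Bonferroni adjustment over the 55 pairs is available but off
by default, matching common reporting practice for these matrices.

## PCA

Mode `correlation` (default) standardises columns by mean and sample SD
(n−1) and eigendecomposes the resulting correlation matrix via a symmetric
eigensolver; mode `covariance` decomposes the sample covariance of the
centred data. Scores are projections of the (standardised) data onto the
eigenvectors, which makes var(score k) = λk exactly under the n−1
convention; loadings are eigenvectors scaled by √λ; contributions are
squared eigenvector entries in percent (summing to 100 per component).
Eigenvalues are sorted descending and tiny negative values from floating
point are clamped to 0 — a genuine zero eigenvalue is always present
because YSI and RSI are exactly collinear. Sign indeterminacy is resolved
by forcing each eigenvector's largest-magnitude entry positive. Rows with
undefined entries are dropped with a warning (no imputation); constant
columns likewise. The biplot can be drawn on any component pair (j < k);
the factor rescaling arrows to the score range is recorded in the plot
spec rather than silently applied to the data.

The choice of raw standardised-data projections (rather than unit-variance
rescaled scores) is recorded in `PCAResult` conventions so it can be
flipped if calibration against an external output ever requires it; it
does not affect explained-variance fractions.

## Fernandez grouping

Groups are operationalised as the mean-split: A = (Yp ≥ Ȳp, Ys ≥ Ȳs),
B = above only without stress, C = above only under stress, D = below in
both, with boundary equality assigned to the higher-performing side. The
verbal definition of the groups leaves the threshold open; the mean-split
is the standard quantitative reading and reproduces the published group
memberships of the 9-species reference screen used in the regression test.
On the A-quadrant STI is increasing in both arguments, so every group-A
genotype satisfies STI ≥ Ȳs/Ȳp (the threshold point's STI) — asserted as a
property test.

## Synthetic trials

The generator emulates the shape of a severe-stress seedling biomass
screen, not any particular experiment's error structure. Yields are
log-normal — strictly positive, right-skewed, multiplicative effects —
with log Yp ~ N(μ, σ²) parameterised by the requested mean and CV, and
Ys = Yp·(1 − r)·exp(ε) with ε ~ N(−σε²/2, σε²), σε = σ√(1/ρ² − 1), so the
log-scale correlation between the environments is ρ and E[Ys | Yp] =
(1 − r)Yp. Defaults: n = 90 genotypes, mean Yp = 60 mg/plant, CV = 0.2,
mean reduction r = 0.25, ρ = 0.8 — the scale of a 90-entry salinity
screen of seedling shoot dry weight, where control yields span roughly
40–100 mg/plant and severe stress removes about a quarter of the biomass
on average. Randomness comes from numpy's PCG64 generator; identical seed,
identical table.

What the generator does not emulate: replicate-level measurement error,
genotype × environment interaction beyond the single correlation
parameter, and heavy-tailed outliers. Tests passing on generated data
therefore validate the algebra, conventions and plumbing of the analyses,
not their behaviour on messy field data.

The planted-group builder places genotypes uniformly in a chosen Fernandez
quadrant with every coordinate at least a `margin` fraction away from the
supplied thresholds, guaranteeing exact recoverability by construction;
it is used to verify the classifier and the STI/group-A relationship.

## Numerical and I/O choices

Yield cells are parsed with Python's correctly-rounded `float()` rather
than pandas' fast parser, whose occasional one-ulp error would break the
full-precision round-trip guarantee of the report writer. Workbook values
are stored at full double precision (display format only is rounded);
CSVs use pandas' shortest-round-trip formatting. The workbook is written
to a temporary file and atomically renamed, so a failed run leaves no
partial report. The pipeline contains no randomness, so repeated runs on
the same input are byte-identical.

## Problem sizes

The self-contained test suite and the acceptance script run on synthetic
trials of 15–90 genotypes and 100 seeded replicates for group recovery —
the scale of the screening experiments this kind of analysis targets —
and complete in seconds.

## Known limitations

- No replicate-level ANOVA, no G×E modelling, no index variants beyond
  the nine implemented.
- The Spearman matrix is defined on favourability ranks; users wanting
  textbook value-based Spearman for TOL/SSI must flip those signs.
- Fernandez thresholds are means, not medians; with skewed yields the two
  can differ materially.
- PCA eigenvectors within (near-)degenerate eigenvalue clusters are not
  identifiable; only the spanned subspace is stable.
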