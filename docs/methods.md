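# Methods

`yeastburden` implements four quantitative analysis layers used to study why
cysteine-containing proteins are costly when massively overexpressed in
yeast, plus a synthetic-data layer that generates every input with recorded
ground truth so each estimator can be tested for parameter recovery.

## Amino-acid usage vs. codon expectation (`composition`)

For a set of protein sequences, the observed frequency of each amino acid is
the pooled residue count across all sequences divided by the total number of
counted residues — i.e. the frequency in the concatenated proteome, not the
mean of per-protein frequencies. (The alternative, averaging per-protein
frequencies, weights short proteins up; pooling is the default because
"frequency in the proteome" is most naturally a residue-level quantity. The
per-protein counts are exposed via `aa_counts_table` if a user wants the
other convention.)

The null expectation is uniform sampling of the 61 sense codons of the
standard nuclear code: P(aa) = n_codons(aa)/61, so cysteine's expectation is
2/61 ≈ 0.0328. Relative usage = observed frequency / expectation. The codon
counts are derived from Biopython's standard codon table at import time
rather than hand-typed.

Conventions: a terminal `*` stop marker is stripped; nonstandard letters
(X, U, B, Z, internal `*`) are excluded from both numerator and denominator
and reported separately, keeping the 20-letter simplex well defined.
"Highly expressed" means abundance **strictly greater** than 100,000
copies/cell (the threshold is a parameter). Subset membership uses
abundance; counting within the subset is unweighted.

## Ohnolog divergence and the sign test (`ohnolog`)

For a chosen amino acid, each duplicated pair is labelled **A** if the
higher-expressed member has strictly fewer residues of that amino acid,
**B** if strictly more, `excluded_tie` on equal counts, `excluded_missing`
if either member lacks an expression value. Exactly equal expression values
are also excluded as missing: translation-rate proxies are continuous, so a
true tie is measure-zero and an observed one carries no sign information.
The four labels partition the input and are all reported, because public
pair catalogues typically lose pairs to both count ties and missing
expression data and the two exclusion modes should not be conflated.

The headline test is the one-sided exact binomial tail
P(X ≥ n_A), X ~ Binomial(n_A + n_B, ½) — the direction asks whether Class A
exceeds Class B. The two-sided option doubles the smaller tail, capped at 1.
The 20-amino-acid panel reports log2(n_B/n_A) per residue with unadjusted
p-values (the panel is descriptive; no multiple-testing correction is
applied). An empty class yields signed infinity with a `ratio_defined=False`
flag; an optional Haldane +0.5 continuity correction is available but off by
default so finite ratios are never silently fabricated.
`estimate_class_a_propensity` returns n_A/(n_A+n_B) with an exact
Clopper–Pearson interval for parameter-recovery testing.

## Morphometry (`morphology`)

Cells arrive as integer label masks from any upstream segmenter. Each
region's equivalent ellipse — the ellipse with the same normalized second
central moments — gives axis lengths 4·√(eigenvalue), the convention of
CellProfiler's `AreaShape_MajorAxisLength`/`MinorAxisLength`; elongation is
the dimensionless ratio major/minor ≥ 1. Regions below `min_area`
(default 50 px), touching the border (default excluded), or degenerate
(zero minor axis) are dropped and counted in a warning. A label split into
several connected components is still measured as one region (matching
whatever the segmenter produced) but triggers a warning.

Strain statistics follow the study design: sample `n_per_replicate`
(default 100) cells uniformly without replacement per biological replicate,
pool (default 3 × 100 = 300 cells), compare the pooled axis-ratio sample
against the control with Levene's test, and Bonferroni-adjust over the
family of strain-vs-control comparisons (`family_size`, supplied
explicitly). Levene centering defaults to the mean (classic Levene);
median centering (Brown–Forsythe) is an option. Mean cell size is reported
as mean area / control mean area. Rod-shaped (fission-yeast-like) cells go
through the same equivalent-ellipse machinery; no rod-specific length model
is used. `elongation_property_correlation` gives the Pearson r between
per-strain mean ratios and a per-molecule property (e.g. cysteine count),
with the two-sided p from the t transform. `dead_cell_fraction` is the
pooled percentage of dead cells, warning below 300 cells.

## Growth (`growth`)

The maximum growth rate (MGR) is the steepest specific growth rate: the
largest least-squares slope of ln(OD) over a sliding window (default 90 min,
≥ 3 points), converted to h⁻¹. Numerical guards: an optional per-plate
`blank` is subtracted before the log; values are clipped at `od_floor`
(default 0.01 OD) so the log stays finite; and the maximum is taken
preferentially over windows whose fit r² ≥ 0.95 **and** whose readings are
all above the clip floor — both guards suppress windows dominated by read
noise near the detection limit, falling back to the unrestricted maximum if
no window qualifies. A constant window has r² defined as 1 (zero residuals
around a perfect constant fit), so flat curves correctly return MGR ≈ 0.

Welch's t-test uses Satterthwaite degrees of freedom; degenerate inputs
follow fixed conventions (both samples constant and equal → p = 1; constant
but unequal → p = 0 with a `degenerate` flag). Growth-rate retardation is
the absolute difference MGR_control − MGR_strain (an absolute difference,
not a ratio, so dividing by a protein level carries units), and the cost
per protein unit is retardation / protein level: equal growth inhibition at
1.4× the expression level implies a 1.4-fold lower per-unit cost.

## Synthetic data (`synthetic`)

All generators are pure functions of their config (seed included); there is
no global random state.

**Proteome.** Protein lengths and abundances are lognormal (defaults:
~2,500 proteins, median length 400 residues, median abundance 3,000
copies/cell with σ_log = 2 — a yeast-scale spread). Residues are sampled
i.i.d. within a protein from a background distribution (default: the
codon-table expectation). The cysteine probability is shifted on the logit
scale by `cys_coupling` × the protein's standardized log10 abundance, and
the 19 other frequencies are renormalized to fill the remainder — the logit
parameterization keeps all probabilities valid at any coupling strength.
The truth table records each protein's realized cysteine count, length and
abundance. What this does **not** emulate: real proteomes have
length-dependent composition, domain structure and phylogenetic
correlation between proteins; passing recovery tests shows the estimators
are correct, not that real yeast data will be as clean.

**Ohnolog pairs.** Member expressions are continuous lognormal draws (ties
have probability zero, mirroring continuous Ribo-Seq rates). With
probability `tie_fraction` the pair gets equal cysteine counts; otherwise
two distinct counts are drawn from `cys_count_range` and the lower count
goes to the higher-expressed member with probability `p_class_a`. With
probability `missing_expression_fraction` one member's expression is
removed. Defaults (548 pairs, p_class_a = 228/365, tie 0.25, missing 0.10)
put the expected number of analyzable pairs near 365 of 548, the scale of
the yeast ohnolog catalogue; the split between ties and missing data is a
modelling choice since only the totals are constrained. The 19 non-cysteine
residues get i.i.d. counts for both members, so they behave as true nulls
in the 20-residue panel.

**Cell images.** Filled ellipses at uniform random centers and
orientations, axis ratio from a truncated-normal strain distribution
(≥ 1), semi-minor axis uniform in `semi_minor_range`, rasterized by the
pixel-center inclusion test with no anti-aliasing (binary-mask semantics).
Placement rejects overlaps with bounded retries and raises a capacity error
when the image is too crowded. Discretization note: moment-based axis
ratios of digitized ellipses with semi-minor ≥ 10 px are accurate to well
under 2% at generic subpixel centers; an ellipse axis-aligned at an exact
integer pixel center is a coherent worst case that can reach ~2.5% — real
segmentations never sit on that measure-zero alignment.

**Growth curves.** od(t) = initial_od + K/(1 + exp(−r(t − t₀))) with r in
h⁻¹, sampled every 10 min (plate-reader cadence) over 24 h by default, plus
Gaussian read noise (default σ = 0.005 OD). The `initial_od` term is an
additive baseline (medium + inoculum); MGR recovery on these curves uses
the blank-subtraction option so the log-slope converges to r at low OD.
Noiseless recovery is within ~2% of r; with read noise, the mean estimate
over 100 wells stays within a few percent of truth while single-well
estimates scatter by ~10% — which is why the growth workflow, like the
plate-reader experiments it mirrors, averages ≥ 3 replicates.

## Problem sizes and numerical choices

Statistical calibration checks use 200 seeded replicates (sign-test power
and CI coverage at n = 365; Levene null and power at n = 300 per group;
morphometry recovery over 200 cells; MGR recovery over 100 wells) — sizes
chosen to match the scales of the corresponding analyses while keeping the
whole suite fast. Exactness of the binomial tail is verified against
arbitrary-precision enumeration for all n ≤ 20. Tolerances asserted in
tests: 2% for digitized axis ratios (discretization bound), 1% absolute for
the noiseless exponential MGR, 10% for noisy logistic MGR recovery, 3–4
binomial standard errors for generator calibration.

## Interfaces

The package is a library: the importable functions plus the narrative
scripts in `examples/` are the interface, and standard formats go through
standard readers (FASTA via Biopython, label masks via tifffile, tables via
pandas). No console entry point is installed.

## Known limitations

- The composition layer analyzes amino-acid sequences only; codon-level
  (nucleotide) usage bias is out of scope.
- Ohnolog pairs are an input; the package does not infer duplication
  history or synteny.
- Segmentation is upstream; a mother cell and its bud segmented as one
  label are measured as one region.
- The MGR window length (90 min) suits budding-yeast doubling times;
  much faster or slower organisms warrant a different window.
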