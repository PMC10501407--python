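# Methods

## Scope and data model

The package models the structure–activity relationship of a 34-compound
dihydropteridone series (PLK1 inhibitors with anti-glioblastoma activity)
and generalizes each stage to arbitrary compound/descriptor tables.
Activities are handled on the potency scale

    pAct = 9 − log10(IC50/µM),

so the most potent compound (21E, 0.18 µM) sits at 9.74 and the least
potent (13m, 1.07 µM) at 8.97.  The source literature prints the transform
as "log(IC50) + 9", but its own predicted-activity tables (top analogs near
9.55–9.63, i.e. *better* than the parent) are only consistent with the
negated form; the package therefore defaults to `9 − log10` and keeps the
literal printed formula behind a `literal=True` switch for audit runs.
Because the published test-set markers are typographically unrecoverable,
splits are seeded uniform draws: the held-out size is the round-half-even
of `n · a/(a+b)` for an `a:b` held-out:train ratio (34 at 1:3 → 8).

## Heuristic linear modeling

`prefilter_descriptors` removes constant columns and, for every pair with
|r| ≥ 0.80 (the cap observed between the published model's descriptors),
drops the member less correlated with the response.  `heuristic_select`
then grows a model greedily: at each size the admissible descriptor (one
whose |r| with every selected descriptor stays below the cap) with the
largest fitted R² is added; ties break to the lexicographically smaller
name for reproducibility.  `fit_mlr` is ordinary least squares with
leave-one-out R²cv via the hat-matrix shortcut `e_i/(1 − h_ii)`,
`s² = RSS/(n − k − 1)` (the abstract-level "S²" of 0.0199 on 26 points is
only consistent with a variance-like quantity, so raw RSS is reported
alongside), per-coefficient t values and the overall F.  A zero-variance
response is defined to have R² = 0.  The recommended subset size is the
last k whose R² gain over k−1 reaches `stop_delta` (default 0.02; the
published selection curve is described only qualitatively, so the plateau
threshold is exposed in config).

Known limitation, deliberately not papered over: in the wide regime the
workflow emulates (n = 34, p = 500), the largest *spurious* marginal
correlation among ~494 noise columns is ≈ 0.5 (null sd 1/√33 ≈ 0.17, max
over ~500 draws), larger than any true descriptor's marginal correlation.
Greedy forward selection therefore interleaves noise columns, every added
descriptor keeps buying ΔR² > 0.02 through k = 8, and the recommended size
exceeds the planted size.  This is a property of greedy subset selection
at n ≪ p, not an implementation defect; the corresponding recovery test is
kept at its stated level and fails honestly.

The published six-descriptor equation itself is carried verbatim
(`reference_hm_model`), with its printed statistics attached as metadata
(`stats_source="published"`), never recomputed: the commercial descriptor
matrix behind them is not available.

## Gene expression programming

Genomes are fixed-length Karva strings: each gene has a head of length h
(functions or terminals) and a tail of length t = h·(a_max − 1) + 1
(terminals only), which makes breadth-first decoding total — any head
mutation still yields a syntactically valid tree, the property that
distinguishes GEP from tree-based genetic programming.  Multigenic
chromosomes decode gene-by-gene and are joined by a linking operator
(default `+`).  The loop per generation: evaluate fitness, stop on target
or generation cap, copy elites unchanged, roulette-select on fitness,
then apply point mutation (rate 0.044), IS/RIS/gene transposition (0.1
each) and one-point/two-point/gene recombination (0.3/0.3/0.1) — standard
GEP practice where the source is silent; all rates are config.  Default
architecture: population 50, 3 genes, head 8.

Arithmetic follows an explicit UNDEFINED contract: `/` or `inv` with
|denominator| < 1e−12, or any non-finite intermediate, is undefined and
propagates to the root; an individual with any undefined prediction scores
fitness 0.  This deliberately replaces the common "protected division
returns 1" hack, which rewards pathological denominators.  Fitness is
`max(0, 1 − RSS/TSS)` — not squared correlation, so a sign-flipped
expression scores strictly below the true one, and a constant tree scores
0.  Tree evaluation is vectorized over sample rows (NaN marks undefined
rows), which is what keeps a 500-individual, 200-generation run in
seconds.  The function-set slot printed as "Inverse / Inx" is read as 1/x
(`inv`); a natural-log variant is available in `LN_FUNCTIONS`.  Random
numeric constants are not generated (the published model contains none),
but the expression grammar accepts literals because the published equation
itself contains `1/(...)` terms.

Because constant-free trees cannot reach an absolute response level of
~9, the pipeline's GEP stage standardizes the response before evolving and
reports R², which is invariant under that affine map.

The published nonlinear equation is shipped as a transcription and parsed
with conventional precedence (unary functions tightest; `*`,`/`
left-associative over `+`,`−`).  Two of its printed quirks are preserved
and tested: the self-cancelling `(MECN − MECN)` subterm (the equation is
constant in MECN) and the `1/(TEIZP − NFA)` pole (undefined when the two
descriptors coincide).

## CoMSIA-style field analysis

Molecules are aligned rigidly to a template by Kabsch superposition (SVD
with determinant correction) over a mapped scaffold of ≥ 3 non-collinear
atoms.  A cubic grid with 2 Å pitch extends 4 Å beyond the union bounding
box; per-axis count is `floor(extent/spacing) + 1` (a point molecule gets
5³ = 125 points).  At each grid point the similarity index for field F is

    A_F(q) = − Σ_atoms w_probe · w_F(atom) · exp(−α r²),  α = 0.3 Å⁻²,

with no distance cutoff.  Atom weights: steric r_vdW³ (Bondi radii),
electrostatic partial charge (Gasteiger-style when read through RDKit,
or from a per-atom property table), hydrophobicity from an element-typed
lookup, donor/acceptor from simple rules (N–H/O–H donate; N, O accept).
The probe is the conventional unit probe (radius 1 Å, charge +1,
hydrophobicity +1, donor/acceptor +1).  Columns with standard deviation
below `min_sigma = 0.05` similarity units carry no contrast and are
masked.

PLS (via scikit-learn's NIPALS-family implementation, uncentered scaling
off; cross-checked in the tests against a hand-written NIPALS and a
closed-form univariate regression) is scanned over component counts with
leave-one-out Q²; the optimal number of components (ONC) maximizes Q²
with the smallest count on ties.  The refit at ONC reports R²,
SEE = √(RSS/(n − c − 1)) and F = (R²/c)/((1 − R²)/(n − c − 1)).  Field
contribution fractions are the per-field sums of |coefficient|·stdev,
normalized to 1 (the analogous published row sums to 1.215 as printed —
our fractions are normalized by contract).  Contour maps mark active
columns whose coefficient·stdev product lies above the 80th / below the
20th percentile of their field; grids export as OpenDX scalar files.

## Validation statistics

R²ext = 1 − Σ(yᵢ − ŷᵢ)²/Σ(yᵢ − ȳ_train)² over the test set (may be
negative).  The rm² family uses the standard forms: r² is the squared
Pearson correlation of predictions and observations; r0² its through-origin
analogue; rm² = r²(1 − √(r² − r0²)) with the radicand clamped at 0.  The
direction of the through-origin fit is a genuine convention ambiguity, so
both variants (predictions-on-observations and the reverse) are computed
and their mean is the "overall" value.  Y-randomization permutes the
response n_iter (default 20) times, refits with the model structure fixed
(same descriptor subset / component count; a strict mode re-running
selection exists but is not the default, for cost), and reports
R²p = r²·√(r² − mean r²_scrambled), clamped, with the full scrambled list.
All three pass at the conventional > 0.5 threshold.

## Synthetic data: what it emulates, what it does not

`generate_descriptor_matrix` draws standard-normal columns and imposes
equicorrelated collinearity blocks via the Cholesky factor of
(1−r)I + r·11ᵀ (placed on filler columns after the planted subset), then
standardizes empirically.  The default preset mirrors the study regime:
34 compounds, 500 descriptors, a six-descriptor planted truth with
coefficient magnitudes proportional to the published ones, three blocks of
5 at r = 0.9, noise fixed so the true model's population R² ≈ 0.67, and
activities affinely mapped onto the fixture's pAct span [8.97, 9.74].

`generate_aligned_molecules` builds pseudo-molecules sharing a fixed
3-atom scaffold plus 4–10 uniformly placed decoration atoms with sampled
charges (±0.5 e), hydrophobicities (±1) and Bernoulli(0.3) donor/acceptor
flags.  The default planted coefficient map consists of smooth Gaussian
blobs (σ = 2 Å) in the hydrophobic (favored) and steric (disfavored)
fields — echoing the dominant fields of the real model — projected onto
the span of contrasts the generated field matrix realizes.  The projection
is essential to the generator's purpose: a coefficient component
orthogonal to that span produces no activity variation and is invisible
to any fitter at any sample size, so planting it would make "recover the
ground truth" unsatisfiable by construction.  An unprojected sparse-spike
plant remains available (`plant="spikes"`) as a deliberately
unidentifiable stress case.  `noise_fraction` scales noise relative to the
noiseless activity sd (default preset 0.2).

What passing tests on these plants show: the estimators recover planted
structure of the kind they assume, at the study's sample sizes, under
Gaussian noise.  What they do not show: behavior under real descriptor
distributions (heavy tails, mixed scales, structural redundancy of actual
quantum-chemical descriptors), real conformational variation, or real
field physics — no claim is made that synthetic Q²/R² levels transfer to
laboratory data.  Published statistics of the original models (linear R²
0.6682/R²cv 0.5669/s² 0.0199; GEP 0.79/0.76; field-model Q²/R²/SEE/F and
R²ext/rm²/R²p = 0.65/0.64/0.61) are carried as metadata constants, never
reproduced, because they depend on commercial descriptor/field software
whose outputs were not published.

## Candidate design

Analog enumeration is an explicit mechanism, not a reconstruction: the
original 200-analog design round never disclosed its substituent choices,
so `enumerate_candidates` applies a user-supplied modification library
(descriptor-delta vectors for 2D models; pure structure-edit functions for
the 3D model) to a template, with seeded draws and `template.k` ids.
Ranking is by the designated primary model (3D field model when present,
else the evolved expression, else the linear model), descending, ties
broken by id; candidates a model cannot score are logged and excluded,
and prediction never mutates model state.

## Numerical choices and degenerate inputs

* Partition sizes: round-half-even; empty partitions are errors.
* OLS rank deficiency: error naming the dependent columns.
* Division guard: |denominator| < 1e−12, applied identically in scalar and
  vectorized evaluation.
* PLS component cap: min(max_components, n − 2, active columns).
* Tie-breaks: descriptor selection → lexicographic name; ONC → smallest
  component count; ranking → candidate id.
* Seeds: every stochastic routine takes an explicit integer seed and is a
  pure function of it; the pipeline threads one seed through all stages
  and echoes it in every artifact with the config hash and version.

## Problem sizes used in checks

Recovery simulations run at the sizes the workflow emulates: 20 preset
seeds for descriptor-selection behavior (34 × 500), 10 seeds of a
500-individual/≤200-generation evolution for the additive-sine law
(n = 50), one 50-molecule field plant for coefficient recovery, and
10 × 20-permutation Y-randomization runs (n = 50, p = 5).  The full
pipeline preset completes in a few seconds; the complete test suite and
the acceptance script each run in about a minute on one CPU.
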