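# Methods

## Forward model

Each chromosome 7 carries a variable number of ~106-kb duplicons containing
NCF1B, NCF1 or NCF1C. A diploid genome is summarised by the copy-number trio
`(b, n, c)` with total `T = b + n + c`. Quantitative pyrosequencing of a PCR
product that amplifies all copies indiscriminately measures, at each PSV
site, the fraction of templates carrying each allele. Assuming equal
amplification and incorporation yield per copy:

* exon-2 GT fraction: `f_GT = (b + c) / T` (both pseudogenes carry the GT
  deletion, NCF1 carries GTGT);
* exon-9 A fraction: `f_A = (b + n) / T` (NCF1C alone carries G);
* ΔGT/GTGT ratio: `r = f_GT / (1 - f_GT) = (b + c) / n`, undefined for
  `n = 0` (the CGD-like genotype).

Raw pyrogram peak heights `h1, h2` convert to a fraction
`f = h1 / (h1 + κ·h2)`, where κ (default 1.0) is a per-assay multiplicative
calibration absorbing yield differences between a 2-bp and a 1-bp
incorporation. The vendor software's proprietary peak model is not public;
a one-parameter skew is the minimal calibration consistent with reporting
final allele ratios only.

`f = (f_GT, f_A)` is invariant under `(b, n, c) → (kb, kn, kc)`: fractions
identify a trio only up to scale. This degeneracy is intrinsic to any
assay that measures proportions of a mixed template pool.

## Integer calling

`call_trio` minimises the Euclidean distance in fraction space between the
observed profile and the forward model over a finite grid. Fraction space is
preferred to ratio space because additive measurement noise is approximately
homoscedastic there, while the ratio transform inflates variance by
`(1 - f)^-2` (≈9 at the 4:2 class).

* **fixed_two mode (default)**: `n = 2`, pseudogene counts 0..6 each. This
  grid is collision-free (verified exactly with rational arithmetic), so
  noiseless profiles invert uniquely.
* **free mode**: `n` in 1..4. Scalar multiples collide exactly; ties within
  1e-9 go to the smallest total `T`, then lexicographically smallest
  `(b, n, c)` — so `(2, 4, 6)`'s profile is called `(1, 2, 3)`.
* **no-call**: best residual above τ (default 0.04). τ was set so profiles
  roughly half-way between grid points (residual ≥ 0.042 at the densest part
  of the n=2 grid) are flagged, while class-mean-level deviations of measured
  panels (≤ 0.02 in fraction space) call confidently.
* NaN fractions (failed pyrograms) propagate to a no-call rather than raise.

Margins: brute force over the grid (exact criterion
`|u|² > 2r(|u1| + |u2|)` for every competitor offset `u` and per-coordinate
perturbation radius `r`) shows every `T ≤ 6` trio tolerates ±0.015 — one
noise SD — on both fractions without changing its call. No uniform ±0.03
guarantee exists: from `T = 6` upward, neighbours along the scale-degeneracy
direction (e.g. `(2,2,2)` vs `(3,2,2)`, 0.067 apart) can capture worst-case
corner perturbations. This is why calling accuracy degrades gracefully with
genome size and why the no-call threshold matters for large-T genomes.

`classify_ratio` performs the coarser one-dimensional assignment of a
measured ΔGT/GTGT ratio to the nearest class `p:2` (p = 0..6); exact
midpoint ties go to fewer pseudogene copies (favouring the smaller genome).

## Pedigree haplotype deduction

A haplotype here is an arm configuration `(b_h, n_h, c_h)` of duplicon
counts on one chromosome (per-arm bound 3 by default, accommodating every
arm pattern the calling grid can produce). A non-founder inherits exactly
one haplotype from each parent; recombination inside the ~300-kb locus and
de novo duplications are not modelled — an inconsistent individual is
*reported*, never repaired (an optional mode searches for the smallest set
of ≤ k individuals whose removal restores consistency).

The solver enumerates each individual's candidate pairs from its trio,
prunes them by iterated nuclear-family compatibility (Lange–Goradia-style
genotype elimination), then certifies each surviving candidate by exhibiting
a full consistent assignment via backtracking. `deduce_haplogenotypes`
therefore returns exactly the pairs participating in at least one globally
consistent assignment (validated against a brute-force global enumeration on
small pedigrees).

Transmission constraints alone rarely force unique arms: a lineage that is
0:2:2 in every generation is explained equally well by (0,1,1)+(0,1,1) and
by (0,1,0)+(0,1,2) throughout. `parsimonious_assignment` selects among
consistent assignments the one using the fewest distinct haplotypes in the
whole pedigree (deterministic tie-break), which recovers the balanced-arm
interpretation conventionally drawn in pedigree figures.

## Population statistics

Summaries report per-paralog sample means and SDs (n−1), ratio-class
frequencies, and gene-pool shares (share of each paralog among all gene
copies). Pairwise comparisons default to the pooled-variance Student t-test
(two-sided), computable from raw values or from published summary
statistics; Welch is available because the populations' printed SDs differ
notably (0.4 vs 0.6). No multiple-testing correction is applied by default,
mirroring uncorrected pairwise reporting; Bonferroni is opt-in. The t
machinery is delegated to scipy.stats and cross-checked in the tests against
a by-hand evaluation of the pooled formula.

## Expression

The exon-2 cDNA assay sees only transcripts retaining (mutant or wild-type)
exon 2 — the GT-containing pool. Within it, shares are identified directly:
`p_N` = GTGT fraction (exon-2 cDNA), `p_C` = G fraction (exon-9 cDNA),
`p_B = 1 − p_N − p_C` by subtraction. Since `p_B` inherits both assays'
errors, values in `[−tol, 0)` (tol = 0.02, typical pyrosequencing noise) are
clipped to zero with renormalisation; larger negatives raise an
inconsistency error. Per-copy activity normalises shares by copy fractions:
`a_i = (p_i / g_i) / (p_N / n)`, so `a_N ≡ 1`.

qPCR uses the standard-curve method: least squares of Ct on log10(quantity)
over serial dilutions; efficiency `E = 10^(−1/slope) − 1`; unknowns
interpolate as `Q = 10^((Ct − intercept)/slope)`. Fold changes divide each
replicate's target quantity by the same replicate's reference-gene quantity
*before* averaging (ratio-of-means would leave no replicate-level variance
for a t-test); the normalisation makes the result invariant to plate-wide Ct
offsets. The ΔΔCt shortcut is intentionally not provided.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* **Populations**: two independent haplotype draws per individual from a
  population pool; fractions = forward model + truncated (clipped) Gaussian
  noise, `σ_f = 0.015` by default. Through the delta method
  (`dr/df = (1−f)^−2 = 9` at the 4:2 class) this reproduces a ratio-scale
  spread of ≈0.14, the level observed in measured panels. Peak heights are
  re-derived from the noisy fractions with a per-assay intensity CV of 0.05.
* **Presets** are *conventions, not estimates*: true haplotype frequencies
  are unknown and not identifiable from diploid class frequencies. Pools for
  the three reference populations were fit once, by least squares, to the
  published per-individual statistics — means ± SDs of NCF1B and NCF1C and
  the diploid ratio-class spectra. The Caucasian-like preset matches its
  published means and SDs exactly and the 4:2 share (0.561); the
  African-American-like preset matches means/SDs almost exactly (4:2 share
  0.64 vs 0.72). The published Mexican statistics are *jointly unattainable*
  under random mating of integer haplotypes: a 50% heterozygote class
  violates `P_het ≤ 2√(P_hom1·P_hom2)`, and an SD of 0.4 around a mean of
  1.0 copies lies below the √0.5 ≈ 0.707 floor for a sum of two independent
  integer draws. The Mexican-like preset therefore matches the means exactly
  with spread at its lower bound. Tests consequently check convergence of
  simulated spectra to *pool-implied* values, not to the published
  percentages.
* **NCF1 count**: presets carry one NCF1 per arm (diploid n = 2). Published
  population means of 2.1 suggest occasional three-copy genomes, but the
  per-individual evidence is not available; the caller's free mode handles
  n ≠ 2 if needed.
* **Pedigrees**: founders drawn from the pool; each child inherits one
  uniformly chosen haplotype per parent (gene dropping); truth is retained
  for oracle tests.
* **Expression**: paralog copy i contributes weight
  `g_i · rate_i · ρ_i` to the GT-containing pool, where ρ is the fraction of
  pseudogene transcripts retaining the defective exon 2 (ρ_N = 1; default
  ρ_B = ρ_C = 0.25, making a 4:2 genome's pseudogene pool half of one NCF1
  copy pool — the pattern observed in cDNA). Alternative-exon transcripts
  are represented only as the missing mass `1 − ρ`. Condition multipliers
  (scalar or per-paralog) scale output between conditions; Cts are generated
  from the true inverse standard curve (slope −1/log10 2 by default) plus
  Gaussian cycle noise (SD 0.1).
* All randomness flows from one seed; identical seeds give identical tables.

What passing on synthetic data does **not** show: robustness to
amplification bias between paralogs, PCR competition, non-Gaussian pyrogram
artefacts, population substructure (the real Mexican data visibly violate
Hardy–Weinberg expectations), or de novo rearrangements.

## Problem sizes

The pipeline is exercised at the scale of the study it models: cohorts of
32/30/24 individuals for population comparison (with 1000 replicates for the
power check of the NCF1C contrast, and N = 500 per population for accuracy
estimation), three-generation pedigrees of 12–14 members, and qPCR designs
of 2 conditions × 5 replicates. Complete runs of the test suite and analysis
scripts take well under a minute on one core.

## Known limitations

* Scale non-identifiability means fixed_two calls are wrong for genuine
  n ≠ 2 genomes; free mode resolves ties by parsimony (minimum total
  copies), which is a convention, not evidence.
* Ratio-class classification from the exon-2 assay alone cannot separate
  trios sharing `b + c`.
* The pedigree solver's deduction is exponential in the worst case; it is
  intended for family-sized problems (tens of members), not population
  cohorts.
* Calibration factors default to 1.0; real indel assays likely need
  κ ≠ 1, estimable from homozygous-reference controls.
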