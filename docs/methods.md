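# Methods

## Scoring model

A site sequence is scored against its TF's PSSM as the sum over motif
positions of `log2(p_i(base)/b(base))` in bits.  The log base is a free
convention: strength is a ratio of scores, so every threshold decision is
scale-invariant; bits were chosen as the field's default.  `p_i` is
floored at a pseudocount of 1e-3 before the log so that a base never
observed at a position yields a large negative contribution instead of
minus infinity.  The background `b` is uniform (0.25) by default and can
be overridden with genome-wide mononucleotide frequencies.  Gap positions
of a motif and `N` bases contribute zero.  Strength is the score divided
by the maximum attainable score, computed over non-gap positions of the
whole motif (not per position).  A site is functionally conserved when
strength >= 0.6; the boundary is closed ("at least 60%").  Annotated
sites are scored on their annotated strand; promoter scanning evaluates
both strands and reports forward-strand offsets.

PSSM similarity (used to delimit an in-vitro-confirmed motif subset at
Pearson r > 0.7) is the maximum correlation of the flattened probability
matrices over all ungapped alignments with overlap >= min(Na, Nb) - 2
(and at least 3 columns), with the second matrix also reverse-
complemented.

## Conservation calls

Within-species conservation requires every strain of the panel to carry a
functionally conserved site sequence.  Strain sequences are rebuilt from
single-nucleotide variants passing the sequence-quality filter
(confidence p < 1e-3, strict); indel records are dropped at load and
counted.  Strains without a genotype call at a position are assumed
reference.  Each strain is re-scored (conservation does not require
sequence identity).  Sites whose reference sequence itself fails the
threshold are flagged `reference_below_threshold` and excluded from
conservation analyses by default.

Between-species conservation requires a conserved call in at least 2 of 3
species, from per-site orthologous sequences supplied as input (alignment
is out of scope); a missing or length-mismatched sequence counts as not
conserved.  An edge is conserved when >= 1 of its sites is; an edge with
no observed sites is undefined (error), since edges exist only where
binding was observed.

SNPs/bp counts *distinct polymorphic non-gap positions* (not alleles)
over the non-gap motif length; overlapping sites and gap bases are
excluded.  The flanking control measures the same quantity over the <= 10
bases downstream of the site in its annotated-strand orientation,
excluding bases inside any known site; zero retained bases yields an
excluded sentinel.  Gained sites are motif hits present in a strain's
promoter at (offset, strand) positions without a reference hit.

## Feature annotation

Sites are assigned to the nearest gene whose TSS is downstream of the
site in that gene's reading orientation within 1000 bp; a site between
two divergently transcribed genes in range of both is assigned to both
and contributes one analysis row per assignment (a flag collapses to the
nearest assignment for sensitivity analysis).  Distance is measured from
the site midpoint (the paper-style reference point is not determined by
the data; the midpoint is the symmetric choice) and floored at 0 when the
site overlaps the TSS.  Subtelomeric means the site's nearer edge is
strictly within 40 kb of a chromosome end.  NFR membership requires the
site to intersect a nucleosome-free interval that itself overlaps the
150 bp window before the assigned TSS.  Overlap is >= 1 shared base with
any other site, same or different TF.  Copy-number classes are 1/2/3/4-5/
6+ and promoter TF-count classes 1..5/6-7/8-9/10-12/13+.  TFs not
uniquely assigned to one hierarchy layer are `unassigned` and excluded
from hierarchy analyses only.

## Statistics

Proportions carry 95% Wilson score intervals.  2x2 tables use the
cross-product odds ratio with the Haldane-Anscombe 0.5 correction only
when a cell is zero, tested by chi-square, switching to Fisher's exact
test when any expected count is below 5.  Trends in ordered or discrete
covariates are tested by analysis of deviance of a binomial GLM (the
deviance difference against a chi-square), with distance as a
third-degree polynomial.  Equal-population binning never splits tied
values across an edge, so bin sizes are only approximately equal under
ties.  No multiple-testing correction is applied, matching the raw
reporting style; an optional helper computes seeded label-shuffling
empirical p-values.  Per-TF screens require >= 4 distinct distances for
the distance analysis, >= 2 values for discrete covariates, and every
globally observed category for categorical covariates.

## Integrated model

The design matrix codes distance as three orthogonalized polynomial
columns (QR on centered powers, scaled to unit SD so planted coefficients
are sample-size independent; predictions are basis-invariant and that
invariance, not any particular routine, is the tested contract),
hierarchy as orthonormal linear `(-1,0,1)/sqrt(2)` and quadratic
`(1,-2,1)/sqrt(6)` contrasts with the linear contrast increasing from
bottom to top, and the remaining covariates as 0/1 indicators or raw
counts.  The GLM is fitted by IRLS to a relative deviance change below
1e-8 (max 50 iterations); standard errors come from the inverse of the
weighted information matrix.  Linearly dependent columns are aliased
(dropped) via pivoted QR before fitting, as R's `glm` does; complete or
quasi-complete separation raises a diagnostic error rather than
returning a spurious fit.

Backward stepwise selection starts from all main effects and their
first-order interactions (multi-column terms interact as blocks).  Each
round drops the single least significant droppable term with drop-p >=
0.05; interactions are considered before main effects and a main effect
is droppable only when no retained interaction contains it.  Cross-
validation is outcome-stratified ten-fold with a mandatory seed; the AUC
standard error is the fold SD over sqrt(k).  AUC is the Mann-Whitney
probability with ties counted 1/2.

## Synthetic data generator

The generator emulates the study system at desk scale.  Defaults: 3
chromosomes x 300 kb, 2,000 genes, 40 TFs, 10,000 planted sites, 36
strains, 3 species.  PSSMs have one strict-majority base per informative
column with per-column information content drawn from 0.8-1.6 bits
(solved by bisection on the column entropy); motifs of >= 9 bp may carry
one uninformative gap column.  Genes are laid out with divergent pairs
(30% of genes), tandem neighbors and subtelomeric genes; strand patterns
are arranged so face-to-face promoters occur only where divergent pairs
were requested.  Promoters are the 1000 bp upstream of each TSS; planted
sites are sampled from their PSSM until they pass the 0.6 threshold,
cover the copy-number classes up to 6+, occasionally overlap a partner
site deliberately, and reserve a clean 10 bp downstream flank.  Half of
the promoters receive an NFR interval inside the 150 bp window.

Conservation is planted through a logistic model: for each site,
`eta = beta_true . x` over the model's own design columns, with
per-comparison intercepts; `p_within = logistic(-0.12 + eta)` and
`p_between = logistic(-4.08 + eta)`.  The intercepts were calibrated once
so the marginal rates under default conditions sit near the study
system's 92% (within) and 29% (between); the default effect directions
follow the real system (stronger, promoter-proximal, divergent,
top-of-hierarchy, essential-TF and regulator-target sites more conserved;
subtelomeric, TF-redundant and epistatic-partner sites less conserved),
while magnitudes are free parameters of the harness, not claims about
yeast.  Outcomes are Bernoulli draws that the generator then *realizes in
sequence*: lost-within sites receive greedy score-breaking substitutions
(always quality-passing) in 1-3 strains; retained sites receive nothing,
a benign substitution that provably keeps strength >= 0.6, or a
would-break substitution with failing quality that exercises the filter
branch; species copies are broken in exactly enough species to invert or
satisfy the 2-of-3 rule, with benign drift on retained copies.
Mutations for overlapping site pairs are restricted to unshared motif
positions so outcomes stay independently realizable (the vanishingly rare
unrealizable case flips the recorded outcome and is counted).  Background
SNPs are sprinkled outside site bodies at 3e-4 per strain per bp (about
10% of records drawn with failing quality), and a configurable fraction
of promoters receives a gained consensus instance in one strain.  The
self-consistency contract — pipeline calls re-derived from sequences
equal the truth table for 100% of sites — is enforced by the acceptance
suite.

What the generator does not emulate: strain phylogeny and linkage
(strains mutate independently), realistic yeast karyotype and gene
structure, binding-site evolution by drift (losses are planted, not
evolved), and regional mutation-rate variation.  Passing tests therefore
demonstrate correctness of the measurement machinery, not biological
claims about real yeast data.

## Problem sizes and numerics

The acceptance suite runs the full study at 10,000 sites (seed 17),
parameter recovery at 20,000 sites across 20 seeds, stepwise calibration
across 100 seeds at n = 20,000, and 500-replicate null calibrations of
the deviance tests — sizes chosen to make the statistical contracts sharp
while keeping the whole suite in the minutes range on one CPU.  Ties in
AUC count 1/2; deviance comparisons clamp tiny negative chi-squares to
zero; the IRLS tolerance and the 1e-9 aliasing threshold are the only
numeric knobs.

## Known limitations

- The integrated model's start set (main effects + all first-order
  interactions) can be rank-deficient or separable on small datasets;
  aliasing handles exact collinearity, but genuinely separable data
  raises an error by design.
- The exact Wilson interval has true coverage 0.974 at n = 30 and
  p = 0.1 or 0.9 (computable in closed form), i.e. it over-covers at
  extreme proportions; the calibration suite documents this.
- Within-species calls assume strains without a genotype call match the
  reference, which understates divergence in low-coverage panels.
- The integrated model is fitted on per-assignment rows, so a site in a
  divergent promoter contributes two rows sharing one outcome, and each
  row carries its own TSS distance.  On simulated data whose outcomes are
  planted at the site level this duplication plus the distance mismatch
  is mild misspecification: stepwise selection then retains some
  interaction terms that the site-level generative model does not
  contain.  The stepwise calibration tests therefore use independent
  rows; the per-assignment convention is kept in the pipeline because it
  mirrors the analysis design, not because it is statistically neutral.
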