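# Methods

## Model

`splicesel` works entirely at the substitution level.  Each splice-site
position is treated as a locus in the weak-mutation (origination–fixation)
regime: the population is monomorphic, a mutation from allele Z to allele X
arises at per-Ks rate `mu[Z, X]` and fixes with probability proportional to
the Kimura factor, so the substitution rate is

```
rate(Z -> X) = mu[Z, X] * r(f[X] - f[Z]),     r(S) = S / (1 - exp(-S)),
```

with `f` the vector of scaled fitnesses in 4·Ne·s units.  `r` is strictly
increasing, `r(0) = 1`, and `r(S) - r(-S) = S`, so the ratio of a class
substitution frequency to its neutral expectation identifies S uniquely.
This matches the inference target exactly: a Wright–Fisher individual-based
simulator would add polymorphism dynamics that the frequency-ratio
estimator never sees.

Assumptions worth keeping in mind: a constant fitness landscape per
position over the whole tree; independence across positions (no linkage or
draft); mutation rates constant across lineages; per-locus mutation rate
small relative to 1/Ne.

## Fitness landscapes at splice-site positions

At each non-invariant donor position (−3…−1, +3…+6) and acceptor position
(−24…−3 except −4, +1), the one or two consensus (Cn) alleles share the
maximal fitness and every nonconsensus (Nc) allele sits `S` below it
(`S_profile`, default −2; negative values mean Cn is favored).  The
canonical GT/AG dinucleotides are hard-coded immutable, and acceptor −4
evolves neutrally because no consensus exists there.  With
`site_specific_fraction > 0`, that fraction of sites has the fitness
maximum reassigned, independently per position, to one uniformly chosen Nc
allele with advantage `site_specific_S` (default 2) over all other alleles.
This is the minimal mechanism that makes the resident Nc nucleotide — not
the Nc class — the conserved unit, which is what the c_nuc > c_set
conservation signature detects.

The default consensus table is the canonical U2-type consensus
(donor MAG|GTRAGT; acceptor pyrimidine tract + C at −3, G at +1).  Tables
derived from observed frequency spectra override it; the second-most
frequent nucleotide joins the Cn set when its frequency is ≥ 0.35 (a
configurable choice — only "one or two most frequent" is fixed by the
definition of Cn).

## Mutation model and branch lengths

The default mutation matrix is symmetric HKY-like with
transition/transversion ratio kappa = 2, normalized so that one Ks unit
equals one expected neutral substitution (the normalization contracts the
mutation-only stationary distribution with the per-allele exit rates, so it
holds for asymmetric matrices too).  Stationary frequencies solve pi·Q = 0;
for symmetric mutation they satisfy detailed balance with
pi(X)/pi(Z) = exp(f[X] − f[Z]).  Branch matrices are matrix exponentials.

The simulated trio mirrors a primate-like design: reference-to-sister Ks
0.06 (split placed halfway) and reference-to-outgroup Ks 0.13.  The deeper
panel defaults to 16 species on a geometric ladder from Ks 0.05 to 4.0;
each species evolves from its predecessor over the distance increment, so
marginal distances from the reference are exact and states are correlated
through shared path length.  Because the process is reversible and at
stationarity, conditioning the panel on the extant reference state is
exact.  A real phylogeny branches rather than chains, so between-species
correlations are slightly stronger here than on a star-like tree; the
conservation statistic only reads the distance-ordered prefix, which the
ladder represents faithfully.

## Neutral controls

Two control pools are simulated per ensemble under the identical mutation
process with all fitnesses equal: an intronic-like pool (used for intronic
splice-site positions) and a fourfold-degenerate-site-like pool (used for
exonic positions).  Each control position carries a synthetic neutrality
score drawn from N(0, 0.9); filtering at |score| < 0.6 therefore retains
about half of the positions, emulating the share that a phyloP-style filter
removes in practice, without biasing the retained rates (all simulated
controls are genuinely neutral).  The filter sense is configurable because
either reading of a score cutoff is defensible on real tracks; retaining
small |score| is the default since that is the reading that yields
neutrally evolving positions.  Each pool defaults to 100x the site count,
which keeps the control sampling error well below the splice-site sampling
error and justifies the decision to neglect control error in the
selection confidence intervals.

In real-data mode the pipeline consumes a pre-extracted control table
(triplet states, scores, provenance); extraction of controls from raw
genome tracks is out of scope.

## Polarization and counting

The reference/sister ancestor is reconstructed against one outgroup.  The
Fitch parsimony rule (`parsimony_ancestor`) resolves the 3-taxon tree
exactly, returning "ambiguous" on ties and missing data.

For counting, the default is the outgroup-corroborated ("strict") subset
of the parsimony solution: a column is used only when sister and outgroup
agree, and their shared state is the ancestor.  The reason is statistical
rather than cosmetic.  Conditional on the true ancestor, the three branches
evolve independently, so under strict polarization the probability that a
column is retained depends only on the sister and outgroup branches — never
on the reference-branch event being counted — and the class frequencies are
unbiased up to the rare double-parallel case in which sister and outgroup
both substitute to the same wrong state.  Under plain Fitch counting,
retention and ancestor assignment depend on the reference state, and the
resulting losses and misassignments scale linearly with the outgroup branch
length and differ between selected sites and neutral controls; at the
default branch lengths this distorts the recovered 4·Ne·s by several times
more than the strict scheme does.  The residual double-parallel
contamination grows with the product of the sister and outgroup branch
lengths and is dominated by selection-favored parallel Nc-to-Cn changes; it
attenuates recovered |4·Ne·s| by a few per cent at the default distances
(visible in the acceptance-script recovery values), the same kind of
parsimony artefact that maximum-likelihood reconstruction is known to
reduce.  Both schemes are available (`polarization: strict | parsimony`);
ambiguous columns are excluded from numerator and denominator alike, and
per-offset mass conservation (counts + ambiguous + excluded = records) is
enforced by test.  An externally produced ancestral-state table (e.g. from
a likelihood reconstruction) can be supplied in real mode through the
control/count TSV contracts.

Substitutions are polarized on the reference branch only.  CpG exclusion
removes positions lying in a CG dinucleotide of the reconstructed ancestral
sequence (both members of the pair); for single-position controls the
simulated ancestral neighbors provide the context.  The simulator's
CpG handling is deliberately minimal: a context flag plus an optional
`cpg_rate_multiplier` that inflates C→T/G→A rates in ancestral CpG context,
enough to verify that exclusion restores clean estimates — it is not a
mechanistic deamination model.

## Frequencies, expectations, tests

For a position with consensus set Cn,

```
q(Cn->Nc) = sum_{Z in Cn, X not in Cn} #(Z->X) / sum_{Z in Cn, all X} #(Z->X)
```

and symmetrically for Nc→Cn.  Within-class substitutions count as
opportunities but not exits, so q estimates the per-branch class-exit
probability.  The neutral expectation replaces each ancestral class member
Z by the control rate of the identical nucleotide toward the complementary
class, weighted by the ancestral composition at that position.  Observed
versus expected counts are compared by a two-sided Fisher exact test on the
{substituted, conserved} × {sites, controls} table, with the control side
at its own sample size (composition-weighted expected exits rounded to
integers).  Per-offset p-values are reported raw; a Benjamini–Hochberg
column is added to the output tables as a labeled convenience.

Confidence intervals for q are exact central Clopper–Pearson intervals
(beta-tail inversion).  `estimate_selection` maps q and its CI endpoints
through the inverse fixation ratio, treating the control rate as exact; a
zero lower endpoint maps to an open-ended −inf bound, serialized as ±inf
rather than clipped.

## Conservation depth

For one alignment column and a target nucleotide set, the depth L is the
distance of the farthest species such that every species at smaller or
equal distance carries a target nucleotide.  Missing data terminate the
prefix; species tied at the failing distance are excluded together with it;
columns of depth 0 are included in means (they are informative about
non-conservation).  c_nuc targets the specific reference nucleotide,
c_set the whole Cn or Nc set of the position; expectations come from
neutral control columns matched by reference nucleotide and weighted by the
observed composition, and c = (obs − exp)/exp.  CIs are percentile
bootstrap over columns (default B = 1000), resampling observed and control
columns jointly in each trial.

## Numerical choices

- `fixation_ratio` switches to the series 1 + S/2 + S²/12 for |S| < 1e−6
  (removable singularity; relative error < 1e−12 near 0) and uses expm1
  elsewhere; overflow for very negative S underflows cleanly to 0.
- `invert_rate_ratio` uses Brent's method on [−100, 100], doubling the
  bracket if the target ratio falls outside; round-trips to better than
  1e−8 over S ∈ [−20, 20].
- Categorical sampling in the simulator uses scalar cumulative thresholds
  with float32 uniforms — a 4-letter alphabet needs three comparisons, and
  the ~1e−7 threshold granularity is irrelevant at simulation scale.
- Derived random streams are named children of the master seed (stage,
  offset, fitness group), so ensembles are bitwise reproducible and
  individual stages can be re-drawn independently.
- Strength tertiles and covariate strata are assigned by stable-sort
  position, giving exactly balanced groups with deterministic tie-breaking
  by input order.

## Problem sizes

The test-suite and acceptance-script study sizes are 5×10⁴ sites per
ensemble for recovery and null checks (with 100× control pools), 400–800
sites × 7 offsets for panel-based conservation, B = 400–1000 bootstrap
trials, and 10⁴ replicates for Clopper–Pearson coverage.  At these sizes
the pooled 4·Ne·s estimate has a standard error near 0.035, small enough to
resolve the nearly neutral range 1 < |4·Ne·s| < 4 comfortably.

## What the synthetic data do and do not show

The generator emulates: triplet alignments with invariant canonical
dinucleotides, class-structured selection with optional site-specific Nc
preference, nucleotide-matched neutral control pools with a realistic
score-filter attrition, CpG context flags, and distance-ladder panels.

It does not emulate: indels or alignment error, splice-site gain/loss,
context-dependent mutation beyond the optional CpG multiplier, rate or
Ne variation across lineages, linked selection, or branching (rather than
nested) panel phylogenies.  Passing tests therefore demonstrate that the
estimators are correct and near-unbiased under the stated model — not that
real-genome nuisances (alignment artefacts, mutation-rate heterogeneity,
ancestral polymorphism at short branches) are handled; on real data those
enter through the quality of the inputs and controls supplied.

## Known limitations

- Parsimony polarization with a single outgroup attenuates |4·Ne·s| by a
  few per cent at primate-like distances even under strict polarization
  (see above); estimates at larger divergences should be read accordingly.
- The expected-frequency construction assumes the control rate of a
  nucleotide transfers across sequence context; only CpG context is
  adjustable.
- Conservation expectations are matched by reference nucleotide identity,
  not by flanking context or regional mutation rate.
- The drift-load summary multiplies three point estimates and inherits
  their errors multiplicatively; it is an order-of-magnitude quantity.
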