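# Methods

## The model

`codonlrt` asks, one codon at a time, whether a protein-coding site evolves
under selective constraint.  Evolution at a codon column is modelled as a
continuous-time reversible Markov chain on the 61 sense codons of the
universal genetic code (Muse–Gaut/MG94 parameterisation): a change of exactly
one nucleotide occurs at a rate proportional to the stationary frequency of
the target nucleotide (F1x4), multiplied by ω = dN/dS when the change is
nonsynonymous.  Codons differing at more than one position have rate zero;
stop codons are not states of the chain.  The generator is rescaled so that
the expected *synonymous* substitution rate at stationarity is exactly 1,
which makes every branch length an expected number of synonymous
substitutions per codon site (dS).  Synonymous divergence thereby acts as the
internal clock against which amino acid conservation is judged — the feature
that distinguishes this test from conservation scores that need an externally
supplied neutral rate.

There is deliberately no transition/transversion parameter and no codon
frequency model richer than F1x4: per-gene alignments are small, and the test
statistic needs a model identifiable from hundreds, not millions, of codons.
The nucleotide frequencies are counted from the gene alignment itself (with a
0.5 pseudocount per nucleotide so degenerate toy alignments keep all codons
reachable).

Likelihoods are computed by Felsenstein pruning with per-site rescaling.
Gap, `N` and otherwise ambiguous codons enter as all-ones partial vectors
(standard missing-data treatment), so a fully missing column has likelihood 1
and a masked tip is exactly equivalent to pruning that tip from the tree.
Transition matrices come from a spectral decomposition of the π-symmetrised
generator, so `exp(Qt)` costs two 61×61 products per branch.

## Per-gene fitting

For each gene, branch lengths and a single gene-wide ω are estimated jointly
by maximum penalized likelihood over the whole alignment: a few coarse
coordinate-ascent sweeps (a bounded scalar search over ω, one global
branch-scale move, then each branch in turn) followed by an L-BFGS-B polish
over log-parameters, converged when the objective improves by less than 1e-6,
with up to 3 random restarts.  Search bounds are ω ∈ [1e-6, 50] and branch
lengths ∈ [1e-8, 50]; fitted lengths above 3 dS are then set to 3, and the
reported log-likelihood is re-evaluated (unpenalized) at the capped values so
the reported number matches the reported tree.

Two estimation details deserve explanation:

**Branch-length penalty.**  On divergent trees (total dS ≈ 20 on 12 taxa)
the likelihood is nearly flat *upward* in deep branch lengths — past
saturation the data cannot distinguish dS 2 from dS 5 — and unpenalized ML
inflates them (in our simulations, total dS 27–38 when the truth is 20, for
well under one log-likelihood unit).  The fit therefore subtracts
0.1 · (total dS) from the objective: a weak exponential shrinkage whose scale
was chosen to sit an order of magnitude below the curvature of identifiable
branches and an order of magnitude above the saturation plateau slope.  It
leaves identifiable fits essentially untouched (ω̂ moves from 0.206 to 0.207
on a 6-tip, 500-codon gene) while keeping total dS near truth on saturated
trees.  This is the same concern the hard cap at 3 addresses — spuriously
high dS — handled inside the estimator; the cap is still applied afterwards.

**Joint nuisance.**  The per-site test conditions on the jointly estimated
branch lengths.  The tempting alternative — re-estimating lengths with ω
pinned at 1 so the nuisance is fitted under the null — is rejected
deliberately: on a constrained gene the ω = 1 refit absorbs the constraint
signal into shorter branches (an all-constrained gene collapses from total
dS ≈ 19 to ≈ 2), destroying the very yardstick the test needs.  The price of
the joint plug-in is that single-gene length estimates drift along
near-flat likelihood directions at high divergence, which makes the per-site
test's type-I error fluctuate around its nominal level from gene to gene
(see Known limitations).

## The per-codon test

At a codon of interest the null model fixes ω = 1 (dN = dS) and the
alternative maximises ω ∈ [1e-6, 50].  The profile likelihood in ω can be
bimodal — a saturation shelf as ω grows competes with a constrained optimum
near zero — so the search brackets the global optimum on a log-spaced grid
before refining with a bounded scalar search (xatol 1e-8).  Branch lengths
are held at the gene fit's capped values in both hypotheses.  The
statistic 2(lnL_alt − lnL_null), floored at 0 to absorb optimizer noise, is
referred to χ² with 1 degree of freedom.  The plain χ²₁ (not a 50:50
boundary mixture) is used because ω = 1 is interior to the alternative's
range — relaxation (ω > 1) is detectable, making the test two-sided in ω.
Two caps are applied before the results become classifier features:
p-values below 1e-16 are set to 1e-16 and site ω̂ above 10 is set to 10
("constraint").

Each variant is tested twice.  *Unmasked*: the alignment as-is.  *Masked*:
the entire query sequence replaced by missing data, so the likelihood cannot
be biased by the reference allele (the masked likelihood equals the
query-pruned likelihood exactly).  Columns where fewer than two sequences
carry a sense codon are uninformative and return a flagged result with
p = 1 rather than an exception.

No heuristic site filters are applied (no minimum species count, no removal
of dN > dS sites): that information enters instead as features of the
logistic models, via Rn and An — the number of alignment rows whose amino
acid at the column equals the query reference and the alternate amino acid
respectively.  Unmasked counts include the query row itself (so Rn ≥ 1
whenever the query codon is a sense codon); masked counts exclude it.
Variants whose amino acid change requires more than one nucleotide change
are fully supported, since the test operates on the codon column.

## Deleterious-probability models

Two fixed logistic models convert a test result into a probability of being
deleterious:

    unmasked:  log(p/(1−p)) = −2.407 − 0.2139·log10(p) − 0.2056·constraint
                              + 0.07368·Rn − 0.1236·An
    masked:    log(p/(1−p)) = −2.453 − 0.1904·log10(p) − 0.1459·constraint
                              + 0.2199·max(Rn,An) − 0.2951·|Rn−An|

with log10(p) bounded below by −16 and constraint by 10 through the caps.
The masked feature transform (max and absolute difference) makes the
features computable without trusting which allele is the reference.
`fit_logistic` re-estimates coefficients on new labelled data by IRLS
(tolerance 1e-8), falling back to a ridge fit (penalty 1e-6, flagged) under
perfect separation; `cross_validate` reports stratified 10-fold AUC with
folds assigned round-robin after a seeded shuffle within each class.

For nucleotide-level conservation scores (GERP-style), the per-codon
combination rule uses the score at the codon position(s) through which the
amino acid substitution is reachable by a single nucleotide change
(averaging when several positions qualify — the rule's source does not
resolve multiplicity, and averaging is the symmetric choice), and the mean
of the first two positions' scores otherwise.

The ensemble combiner is a logistic regression on the raw, unstandardised
scores of several approaches; rows with any missing score are dropped (and
counted) rather than imputed.  Only the logistic combiner is provided —
fancier ensemble learners are out of scope.

## Evaluation machinery

Sensitivity is the proportion of phenotype-altering (positive) variants
called deleterious; specificity the proportion of putatively neutral
variants called neutral.  ROC curves enumerate all distinct-score
thresholds; AUC is trapezoidal, which with midrank tie handling equals the
Mann–Whitney statistic exactly.  Score orientation is declared per approach.
Thresholds are chosen as the most permissive cutoff whose specificity meets
the target (default 0.95), breaking ties by sensitivity.  Confidence
intervals are percentile intervals from 2,000 stratified bootstrap
replicates — positives and negatives resampled separately so every replicate
preserves the original class counts; AUC differences between approaches use
the same resampled variants for both score sets (paired).  Degenerate
replicates (undefined AUC) are redrawn and counted.

Call matrices at each approach's 95%-specificity threshold feed: proportions
of deleterious calls per minor-allele-count class (classes 1, 2, 3–4, 5–8,
>8 on an 80-chromosome panel; missing calls excluded from numerator and
denominator); cumulative agreement (fraction of variants called by ≥ k
approaches, complete rows only); a pairwise disagreement distance (counts of
discordant non-missing calls); and average-linkage hierarchical clustering of
approaches with bootstrap support — the fraction of variant-resampled trees
containing each clade — rendered as Newick with support labels.  The linkage
and the percentile interval family are this package's choices; nothing in
the protocol pins them.

## The simulator

`simulate` is the test harness: codon alignments evolved forward on a fixed
tree under the same MG94 generator, with a per-site ω map.  Default study
conditions: a 12-tip pure-birth tree scaled to total dS = 20 (the middle of
the 10–50 range where synonymous divergence is informative but not
saturated), uniform nucleotide frequencies, half the sites constrained with
ω drawn uniformly from [0.01, 0.2] and half neutral (ω = 1), and a 5%
per-codon gap-injection rate in non-query homologs so sparse columns occur.
The root codon is drawn from the stationary distribution and evolution
proceeds by exact transition probabilities, so stop codons are impossible by
construction and tip frequencies converge to F1x4 on long branches.

Benchmark panels place "deleterious" variants at constrained sites and
"neutral" variants at ω = 1 sites; alternate amino acids are drawn among
single-nucleotide-reachable neighbours of the query codon (falling back to
any other amino acid with a `multi_nt` tag).  Minor allele counts on the
80-chromosome panel follow a discretised neutral spectrum (∝ 1/i) for
neutral variants and a strongly singleton-skewed ∝ 1/i² for deleterious
ones.  Synthetic multi-approach score tables add a shared latent noise term
so the correlation between approaches' errors is controllable.

What the simulator does *not* emulate: indels and alignment error,
ascertainment bias of curated mutant databases, gene-family composition,
site-to-site rate variation beyond the two-class ω mixture, and codon usage
bias beyond F1x4.  Passing tests therefore demonstrate internal correctness
and statistical behaviour under the model's own assumptions, not performance
on real curated data.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale, the
package's own choice of study sizes: calibration uses 1,000 neutral codons
on the default tree; power uses 200 codons at ω = 0.02; parameter recovery
uses a 500-codon gene on 6 taxa at total dS = 6 (branch lengths are simply
not identifiable at saturation — that regime is what the penalty and cap are
for); the end-to-end benchmark uses 50 + 50 variants on a 500-codon gene;
bootstrap coverage uses 200 datasets of 200 + 200 scores.

Degenerate inputs are handled explicitly: all-missing columns return
likelihood 1; columns with < 2 sense codons return flagged p = 1 results;
stop codons in homologs are set to missing with a logged warning (an
explicit stop in a likelihood call is an error naming species and site);
perfect separation in logistic fitting falls back to ridge with a flag;
variants whose stated reference amino acid disagrees with the query codon
are flagged, not rejected.  Ties at the specificity target resolve toward
higher sensitivity; the p-value floor, constraint cap and branch cap are
exact assignments, not clamps with tolerance.

## Known limitations

Branch lengths on deeply diverged 12-taxon trees are estimated with large
variance in their saturated directions (the penalty and the cap bound the
damage, they do not remove it).  Because the per-site test plugs these
estimates in, its realised type-I error fluctuates from gene to gene around
the nominal level — approximately calibrated on average, but a gene whose
total dS is badly under- or over-estimated yields a locally hot or cold
test.  With more taxa the effect shrinks; at a dozen taxa it is visible.
The χ²₁ reference is asymptotic in alignment depth and slightly optimistic
in the extreme tail on shallow alignments.  The printed
logistic coefficients are taken as fixed constants; refitting them on real
curated data is out of scope, as are the upstream homolog search and
alignment steps and the external predictors whose scores the evaluation
machinery consumes.
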