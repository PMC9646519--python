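# Methods

This note documents the statistical model, the synthetic data the
package is validated on, and the numerical choices made where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Setting and assumptions

The method targets amplicon libraries: pools of variants that differ
from a known reference gene by a few point substitutions and deletions.
Its two working assumptions are

1. nanopore sequencing error is partly *systematic* — reproducible per
   position, miscalled symbol and sequencing strand — and can therefore
   be characterised once, on reads of the wild-type reference, where
   every mismatch is an error by construction; and
2. the Qscore distribution observed for the wild-type base at a
   position is a usable stand-in for the Qscore distribution a true
   variant base would show at that position. The error model is built
   from a single true sequence, so this approximation is unavoidable;
   it works because correct calls carry visibly higher Qscores than
   errors, even though the two distributions overlap.

The method is restricted to close neighbours of the reference with
independent point mutations. Insertions are carried through the data
structures with their original basecaller qualities but excluded from
the model and the consensus (they are rare, under ~1%, and there can
never be enough training data to fit every possible insertion).
Structural variants and joint errors across neighbouring positions are
out of scope.

## The error model

For each cell — reference position *p* with base *r*, observed
non-reference symbol *n* ∈ {3 alternative bases, deletion}, strand — the
wild-type count table gives the Qscore histograms of erroneous calls of
*n* and of correct calls of *r*. Fitting a logistic regression of the
correct fraction on Q directly would classify nearly every mismatch as
an error, because the training set contains no true mutations. The
reweighting step injects the a-priori plausibility of a real mutation:

* `p_prior_right(r→n)` converts the relative mutagenesis spectrum
  `m_{r→n}` (e.g. an epPCR kit datasheet) and the expected per-read
  load `⟨m⟩` into a per-site mutation probability, normalised so that
  `Σ_cells counts_ref(r)·p_prior_right(r→n) = ⟨m⟩` holds exactly (tested
  to 1e−12). The spectrum may optionally include per-base deletion
  rates `m(r→del)`; without them the deletion prior is zero, which
  makes the recalibrated weights *unable to accept a true deletion* —
  fine for substitution-only protocols, a documented limitation
  otherwise.
* `p_prior_error(p,n,s)` is the empirical, Qscore-independent error
  fraction of that cell in the wild-type set. Cells with zero training
  coverage are flagged as undefined (NaN), never silently zero-filled.

Each class's Q histogram is normalised to a distribution and multiplied
by its prior, giving `P_wildtype(Q)` and `P_mutation(Q)`; the response
is the posterior `N_correct(Q) = P_wt/(P_wt + P_mut)`, the probability
that a call of *n* with Qscore Q is a genuine mutation. The formulas
are prior × likelihood products: the product form is the only reading
under which the quantities stay probabilities and the normalisation is
meaningful. `N_correct` is exactly monotone: non-increasing in
`p_prior_error` and non-decreasing in `p_prior_right` at every Q
(property-tested).

### Per-cell regression

Response: per-integer-Q `N_correct` (no re-binning of Phred values);
weight: the bin's share of the reweighted mass `P_wt + P_mut`, scaled
to the cell's total observation count so the binomial fit sees
effective counts on the original scale; covariate: Q; logit link. The
maximiser is found by a damped Newton iteration on the weighted
binomial log-likelihood (step-halving, coefficient bound 200,
convergence tolerance 1e−12). A hand-rolled solver is used because a
full training run fits thousands of cells; it is verified in the test
suite against statsmodels' binomial GLM and against a derivative-free
grid-refinement/Nelder–Mead maximum-likelihood oracle to ≤1e−6 in
predicted probability. Per-read Bernoulli rows and per-Q-bin binomial
rows have identical likelihoods for this design, so the binomial-row
form is used.

### Fallback chain and statuses

Every one of the `L × 4 × 2` cells must be scorable, so degenerate
cells fall through a chain, recorded per cell:

* `ok` — converged two-parameter fit (negative slopes are kept but
  counted in the model metadata; nothing forbids a genuinely inverted
  cell);
* `fallback_constant` — the cell has data but the response is flat or
  perfectly separated; the constant maximum-likelihood predictor is
  used (an all-correct cell predicts 1−ε);
* `fallback_pooled` — no per-cell data; one regression pooled over all
  positions for the same (symbol, strand);
* `fallback_prior` — pooling also impossible; the Qscore-free posterior
  `p_prior_right/(p_prior_right + p_prior_error)`.

All predictions are clamped to `[ε, 1−ε]`, ε = 1e−6, avoiding zero
weights and log-domain overflow downstream. The minimum training set
for a trustworthy fit is not sharply defined; the trainer warns (never
fails) below a floor of 50 wild-type reads.

## Scoring and consensus

Reference-matching calls keep the basecaller confidence
`p_Guppy = 1 − 10^(−Q/10)`; mismatches and deletions are evaluated in
their cell at the reported Q. Deletions receive the minimum Qscore of
their nearest non-deletion neighbours *in read-event order* (qualities
of consecutive calls are correlated); a run of deletions shares the min
of its two flanks, and a run at a read end takes its single neighbour.
Reverse-strand events are stored reference-oriented and scored with the
reverse-strand cell at the same position and symbol — the strand split
refers to sequencing direction, not symbol complementation.

The consensus of a read group sums, per position and symbol, the weight
of every covering read — 1 ("none"), `p_Guppy` ("guppy") or the
recalibrated probability ("single") — and takes the argmax. Ties prefer
the reference symbol, then A<C<G<T<deletion; conservative toward the
reference and deterministic. Positions covered by no read take the
reference base and are flagged. Deletions inside homopolymer runs
(maximal runs of ≥2 identical reference bases), whose in-run placement
is an arbitrary aligner choice, are first normalised to the run's 3′
end on the forward strand — for the recalibrated method only, since the
normalisation measurably degrades the unrecalibrated ones; a flag
overrides the default. Mean read quality is computed in the
error-probability domain, `−10·log10(mean 10^(−Q/10))`, matching the
basecaller's summary convention used by the length/quality read filter
(defaults 1,700–2,100 nt, mean Q strictly greater than 10). Only
primary alignments contribute an event stream, so each amplicon read
votes once; coordinates are 0-based half-open internally and 1-based in
all reports (mutation labels like `G23A`, `del1320`).

## Synthetic data

The generator emulates the features of real nanopore amplicon data that
the method depends on, with a complete per-read truth ledger:

* **Systematic error profiles**: per position and strand, a total error
  rate jittered around `base_error_rate` (default 0.05, in the middle
  of nanopore's documented 6–15% per-base error), split between a
  deletion share (default 0.4) and a random per-strand bias over the
  alternative bases. A configurable number of hotspot positions get
  `hotspot_rate` (default 0.40) concentrated (85%) on one systematic
  miscall shared by both strands, deletion-typed with probability 0.7.
  The defaults make hotspots strong enough to corrupt a low-coverage
  majority vote — the regime the method exists for; profiles away from
  hotspots stay below the 0.5 cap.
* **Overlapping Q distributions**: correct calls emit Q from a
  discretised normal (mean 20, sd 4), errors from one 6 lower (mean 14,
  sd 4), support 1–50. Both are goodness-of-fit-tested in the suite.
* **epPCR-style libraries**: per variant, a Poisson(⟨m⟩) mutation
  count, uniform positions, substitution identities proportional to the
  spectrum row of the template base, and unique random 36-nt barcodes.
  The default spectrum is A/T-biased with a transition preference, the
  shape typical of mutagenesis-kit datasheets.
* **Reads** are generated directly as reference-frame event streams, so
  alignment is exact by construction; an optional SAM writer exercises
  the parser end-to-end and removes aligner stochasticity from tests.
  Homopolymer deletion placement at generation time is uniform within
  the run, so the 3′-normalisation is non-trivially exercised.

What the generator does **not** emulate — k-mer-context error models,
insertion-rich error modes, read-length variation, chimeras, signal-
level artefacts — bounds what passing tests show: they validate the
statistical machinery on data whose error structure matches the model's
assumptions, not performance on any particular real flow cell.

The standard study conditions used by the acceptance checks are a
300-nt random gene, 5 hotspots, 500 wild-type training reads, 30
variants × 20 reads, ⟨m⟩ = 2, seed 1 — sized so the full pipeline runs
in seconds while leaving each position's training coverage (~250 per
strand) realistic for a flongle-scale run.

## Determinism and numerical edge cases

All randomness flows through `numpy.random.default_rng` seeds; repeated
runs with one seed are bit-identical, including SAM output. Model files
round-trip exactly (coefficients serialised with full precision and
re-parsed with round-trip float parsing). Degenerate inputs are
explicit errors: an empty FASTA, a read of only deletions, an empty
read group, an all-zero spectrum, conflicting barcode assignments.
Undefined statistics (skewness with no mismatches, spectrum correlation
with under 3 observed categories) return NaN with a logged flag rather
than a fabricated value; a perfectly even mismatch-count vector has
skewness 0 by symmetry.

## Known limitations

* Deletion acceptance requires a deletion prior; with a substitution-
  only spectrum the recalibrated consensus cannot call true deletions.
* The prior treats mutations as independent and uniform over sites
  given the spectrum; position-specific priors (e.g. from short-read
  sequencing of the library) would slot into `p_prior_right` but are
  not implemented.
* Cells never observed in training fall back to pooled or prior-only
  predictors; scoring there is honest but weakly informed.
* The homopolymer normalisation handles deletions only; insertions in
  runs are ignored along with all other insertions.
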