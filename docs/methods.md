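# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic experiments show.  Symbols follow the package's API names.

## Ground truth

Core columns of a reference alignment are binary (weight 1); the true
accuracy of a computed alignment is the recovered fraction of core residue
pairs, and the true coreness of a computed column is the fraction of its
residue-residue pairs that are core pairs.  Degenerate cases are fixed as
follows: a reference with no core pairs has accuracy 1 by convention (there
is nothing to get wrong); a column with fewer than two residues has
coreness 0 (no pairs exist); gap-containing pairs are never counted in the
coreness denominator.  Sequences are matched between computed and reference
alignments by ungapped string, falling back to sequence id among
duplicates, which makes the quantities robust to row reordering.
Difficulty bins are ten equal-width, half-open intervals over accuracy,
with bin 9 absorbing accuracy 1.0.

## Column representation

A profile spreads each residue's secondary-structure confidence triple
(helix, strand, coil — renormalized to sum to 1) over its three states and
adds the gap frequency on the gap state ξ; profiles sum to 1 by
construction.  Windows are 2w+1 consecutive profiles with `w = 1` by
default; the class patterns are enumerated for w=1 and generalize as
center-run strings, but only w=1 is exercised by defaults.  Columns beyond
the alignment edge are padded with pure-ξ profiles: ξ is the natural value
of an absent column, and padding lets every column yield a window.
Windows whose label pattern is NCN or CNC are discarded from training; at
test time such windows are scored like any other query (prediction never
sees labels).  Column labels come from thresholding true coreness at 0.5,
strictly (`coreness > θ` is core); the threshold is configurable.

## Alphabets

Substitution-score tables grow as |Q|², and the LP's triangle constraints
as |Q|³, so reduced amino-acid alphabets matter.  Three are provided: the
full 20-letter alphabet (61 states), a Dayhoff-style 6-class grouping
(19 states, the default for training), and a hydrophobic/polar/charged
3-class grouping (10 states) for smoke runs.  Profiles on a reduced
alphabet simply pool residue confidences within a group.

## The bootstrap distance

Neighborhoods for the first round of training can be built with a default
distance whose positional score mixes a substitution dissimilarity on the
amino acids with the identity function on secondary-structure types,
`γ·subst + (1−γ)·[ss differs]`, γ = 0.5 by default (the weight is a free
choice; 0.5 treats both signals equally).  The substitution matrix is
PAM200 (from biotite), rescaled per matrix to a dissimilarity in [0,1] by
`(s_max − s)/(s_max − s_min)` with the diagonal forced to 0; group-level
scores average the member-pair scores.  The gap state scores 0 against
itself and 1 against any residue state — maximal dissimilarity, since a
gap aligned to a residue is exactly what core columns forbid.  Positions
are weighted with the center column at twice the weight of a flank,
normalized to sum to 1.  The shipped protocol ultimately uses random
neighborhoods (below), so the bootstrap distance only matters for the
`default` and iterated modes.

## The linear program

Variables are one score per unordered state pair per class and position
(symmetry is structural, not a constraint), a target error `e_VW` per
(sample, target) pair, one impostor error `f_W` per sample, and the
threshold τ.  Constraints: `e_VW ≥ d_c(V,W) − τ`, `f_W ≥ τ − d_b(V,W) + 1`
for every impostor (completely-non-core samples act as impostor anchors
against the core classes), `σ(p,p) ≤ σ(p,q)`, `σ ≥ 0`, `σ(ξ,ξ) = 0`,
`τ ≥ 0`, and the state-level triangle inequalities per class and position.
The objective blends the per-class, per-sample, per-target average of `e`
(weight α) with the per-class, per-sample average of `f` (weight 1−α) —
the f-average runs over all six classes including ⊥ — plus a vanishing L1
term (1e-7) on the scores.  That last term is a deterministic tie-break:
the error objective is flat along directions that inflate scores no
constraint references, and the tie-break selects the minimal-score optimum
and keeps the simplex out of those flat directions (it perturbs the
optimum by under 1e-4 at typical scales; the reported objective removes
it).  α defaults to 0.5.

The ⊥ impostor anchors use the seeded sample S_⊥ rather than every
completely-non-core window: the full set is enormous and its average is
well approximated by a sample, which keeps the LP at desk scale.

Triangle rows are the size bottleneck (Θ(|Q|³) per table).  For alphabets
up to ~25 states they are generated eagerly; beyond that, lazily — solve,
add the most violated triple per (p,r) per table, re-solve until none
exceed 1e-6.  Both routes end at the same optimum; the audit
(`audit_solution`) re-checks every constraint family outside the solver
and verifies the error variables equal their max-expressions.

Feasibility is unconditional: σ = 0, τ = 0 satisfies everything with
target error 0 and impostor error 1, so the optimum lies in [0, 1−α].

Training-set sizes default to 200 windows per structured class with a
200-window total sample, 2 targets, and 20 impostors per class.  These are
the sizes the test suite and the reproduction script run at; they keep a
single solve in the low minutes on one CPU while leaving the learned
metric's held-out AUC well above the acceptance bar.  All are
configurable upward.

## Neighborhood modes and iteration

Three modes build targets/impostors: `default` (NN search under the
bootstrap distance), `model` (NN under a given learned distance), and
`random` (seeded uniform sampling without replacement).  Iterated training
rebuilds neighborhoods under the previous iteration's distances.  On our
synthetic suites, as on real data, iteration fits the training sample ever
better without improving held-out performance, so the shipped protocol is
a single solve with random neighborhoods and no iteration.

## Distance-to-coreness transforms

Calibration examples are the sample windows, queried against the training
pools with themselves excluded from their own class's pool.  The empirical
curve averages true coreness at each distinct observed distance over all
exact ties plus ℓ examples below and above (ℓ = 100 at full scale, 20 at
the script's scale, truncated at the ends).  The logistic
`f(x) = κ + (λ−κ)/(1 + exp(−a(x−β)))` has κ and λ pinned to the minimum
and maximum smoothed coreness, and (a, β) fit by `scipy` least squares
under an explicit monotonicity bound on the sign of `a` — decreasing for
f_core, increasing for f_non.  Constraining the sign rather than asserting
it avoids any ambiguity about how the sign convention interacts with the
κ/λ pinning, and matches the shapes the curves actually take.  Fewer than
four usable curve points (or a flat curve) yields a flagged degenerate
constant transform.  Predictions are clamped to [0,1]: with noisy pinned
extremes a fitted logistic can marginally overshoot.  τ plays no role at
prediction time — prediction is pure regression on the nearest structured
distance.

## Nearest-neighbor search

Both a vectorized brute-force scan and an exact vantage-point tree are
provided; the tree refuses to build over tables that violate the triangle
inequality beyond 1e-6 (falling back to the scan with a warning), chooses
vantage points deterministically, and prunes only on strict bound
exceedance so results — including insertion-order tie-breaking — match the
scan exactly.  Batch prediction uses the vectorized scan, which is faster
at desk-scale pool sizes; the tree's value is asymptotic and its contract
is verified against the scan in the tests.  Merging per-class results
breaks distance ties by the canonical class order CCC, CCN, NCC, CNN, NNC.

## Accuracy estimator

Feature conventions: identity-family features and blockiness are ratios of
per-column pair counts; augmented variants weight numerator and
denominator column terms by predicted coreness (a ratio of weighted sums —
with all weights 1 they reduce exactly to the unaugmented features).
Blockiness packs disjoint column intervals with gap-free,
uniform-secondary-structure blocks of at least two sequences (no minimum
width by default; configurable), solved exactly by dynamic programming and
checked against exhaustive enumeration in the tests.  BLOSUM62 is rescaled
to [0,1] over its 20×20 entries.  The amino-acid identity feature uses the
10-class partition {LVIM, C, A, G, ST, P, FYW, EDNQ, KR, H}.  The
secondary-structure agreement window spans ±2 residues along each
sequence with weights (1,2,4,2,1)/10, renormalized at sequence ends.
`F_AC` counts windows with predicted coreness ≥ κ (κ = 0.5 by default)
over the normalizer `L(S)`, whose candidate terms are one length aggregate
times at most two pairwise ratios from distinct groups (identity,
quotient, relative difference — 72 terms); its default coefficients and
the estimator's are the shipped fitted values.  Refitting the normalizer
minimizes the L1 residual by LP; refitting the estimator uses non-negative
least squares on within-benchmark accuracy differences against feature
differences, which targets the ranking an advisor needs while staying
fully specified and deterministic.  Advising picks the argmax estimate
(ties: lowest candidate index) and is scored by bin-averaged true
accuracy over non-empty difficulty bins.

## Synthetic data

The generator emulates what makes core columns learnable: core columns are
gap-free and conserved (consensus residue with probability 0.9, helix or
strand secondary structure constant per core run), non-core columns carry
gaps at rate 0.4 and near-uniform residues with mostly-coil structure in
Poisson-length runs (mean 6).  Core runs have length ≥ 2, so the excluded
NCN/CNC patterns are rare.  Confidence tracks are Dirichlet draws peaked
at the label (sharpness 10 — peaked but not one-hot, like a secondary
structure predictor's output).  Computed alignments of prescribed accuracy
displace residues out of selected core columns into fresh single-residue
columns inserted alongside; each displacement destroys a known number of
core pairs, so the realized accuracy is controlled to well within ±0.05
and recorded exactly.  Candidate setting `p_j` on benchmark `i` realizes
accuracy level `(i+j) mod n_levels`: no fixed setting is best everywhere,
and the default setting `p00` spans all ten difficulty bins across a
12-benchmark suite.

What passing on this generator does *not* show: real benchmarks have
phylogenetic correlation between sequences, indel histories, structure
prediction errors correlated along the chain, and core columns whose
conservation is far weaker; the synthetic separation between core and
non-core is sharper than reality, so held-out AUCs here overstate what the
same protocol achieves on curated benchmark collections.  The pipeline,
not the numbers, is what transfers.

## Default problem sizes

The test suite and the reproduction script run: 12 benchmarks, 6 sequences
of ~60 reference columns, 10 accuracy levels; reduced (6-class) alphabet;
|T_c| = 200, |S| = 200 total, k = 2 targets, ℓ = 20 impostors; 500
held-out test windows from a held-out benchmark fold (folds balanced over
difficulty bins, round-robin); curve smoothing ℓ = 20.  These sizes were
chosen as the smallest at which every class pool fills comfortably and the
fold split still leaves diverse held-out windows.

## Known limitations

- The learned distances do not enforce `d_c(W,W) = 0`; self-distance of a
  mixed profile is generally positive.  This is intentional — the
  regression only needs relative distances — but it means a training
  window queried against its own pool does not return distance 0.
- `fit_normalizer` with a single benchmark has many optima; the LP solver's
  deterministic pivoting picks one reproducibly.
- Serialization stores training windows inside the regressor JSON, which is
  compact at desk scale but would be large at 4000 windows per class.
- Ambiguity codes: U and O map to C and K at parse time; B, Z, X, J are
  rejected (profiles over expanded residue sets are not supported).
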