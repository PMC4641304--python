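# Methods

## Feature model

A protein of length N is represented by its substitution matrix
representation (SMR): row i is the BLOSUM62 score row of residue i, so
the matrix is N×20 with integer-valued entries in [−4, 11]. BLOSUM62 is
embedded as a constant in the canonical NCBI half-bit form with the
fixed alphabet `ARNDCQEGHILKMFPSTWYV`; any other matrix in NCBI text
format can be substituted. Ambiguity codes (B, Z, J, X, U, O, `*`) are
accepted on input and map to an all-zero SMR row — neutral, preserving
positional structure — rather than being dropped or expanded to
weighted averages; the count of such residues is logged. This choice
keeps the transform deterministic and avoids inventing substitution
scores the matrix does not define.

The SMR is compressed with the orthonormal 2-D type-II DCT
(`scipy.fft.dctn`, `norm="ortho"`). Orthonormality (Parseval) makes
coefficient magnitudes comparable across sequence lengths. The
descriptor keeps the "first 400 coefficients", which we realize as the
top-left 20×20 low-frequency block flattened row-major:

* row-major flattening of the DCT matrix and truncation at 400 entries
  is *identical* to this block whenever the matrix has ≥ 20 columns, so
  the convention is the natural reading;
* the block is well defined for every post-filter sequence (length ≥ 50
  > 20); shorter sequences (possible when the length filter is
  disabled) are zero-padded.

Alternative scan orders (zigzag, column-major) are not implemented;
column-major truncation would discard all but one amino-acid channel
and zigzag has no advantage for a 20-column signal.

A pair feature is the concatenation [d_A, d_B] in the pair's listed
order (no symmetrization — order handling is genuinely unspecified for
this method; a `swap_augment` option emits both orders for users who
want order-free training).

## Classifier

WSRC is instance-based: `fit` only stacks the pair vectors as columns
and ℓ2-normalizes them. For a test vector y (also ℓ2-normalized, which
makes ε scale-meaningful and the decision scale-invariant):

1. locality weights wᵢ = 1 / exp(−‖y − xᵢ‖²/2σ²) ≥ 1 (the reciprocal
   of a Gaussian similarity; σ = 1.5 by default). The reciprocal
   direction is the one that preserves the nearest-neighbour-like
   locality property — penalizing *near* atoms instead would invert it.
   `weight_mode="similarity"` exposes the raw similarity as the weight
   for comparison, without endorsement;
2. the weighted stable ℓ1 program min Σ wᵢ|αᵢ| s.t. ‖y − Xα‖ ≤ ε is
   solved (ε = 5·10⁻⁵ by default);
3. per-class residuals r_c = ‖y − X δ_c(α̂)‖ are computed with the
   coefficients masked to class c, and the smallest residual wins (ties
   to the smaller class label, i.e. non-interacting). For binary
   problems the continuous score is r₀ − r₁, which thresholds at 0 to
   the hard decision.

### The ℓ1 solver

The weighted program is reduced to unweighted basis pursuit denoising
by the substitution β = Wα (equivalently, rescaling column i by 1/wᵢ),
then solved with a LASSO homotopy (LARS) path: the regularization
parameter descends from its maximal value while the active set is
tracked; within each path segment the solution is linear in λ and the
residual norm is a quadratic function of the step, so the exact point
where the residual crosses ε is obtained in closed form. The returned
solution is therefore the exact optimum of the constrained problem
(verified against an independent convex-programming solve to ~1e-11 on
random instances), not an iterative approximation. A step guard of
5000 path iterations protects against degenerate cycling; steps below
1e-13 are treated as ties.

Degenerate inputs: ‖y‖ ≤ ε returns α = 0 (converged). If ε is smaller
than the distance from y to the column space of X, the constraint is
infeasible; per the module contract the minimum-residual least-norm
solution (pseudoinverse solve, cached per model) is returned with
`converged=False`. This is the *typical* regime when the training set
is much smaller than the 800-dimensional feature space — the classifier
then degenerates to class-masked least-squares reconstruction, in which
the locality weights have no effect (the least-squares minimizer is
unique, leaving the ℓ1 term no freedom). With training sets larger than
the feature dimension, as in realistic use, the sparse path is active.

After a converged solve, the coefficients are polished by least squares
on their support before the residuals are computed (`refit=True`).
Without polishing, the inequality constraint pins the optimum to the
boundary, so even a test vector *identical* to a training atom ends
with residual exactly ε instead of 0; the support-restricted refit
removes this ε-sized bias while leaving the selected atoms unchanged.
The refit never worsens the residual and is skipped if it would.
`solve_weighted_l1` itself reports the unpolished solution, whose
objective is the true optimum of the weighted ℓ1 program.

## Evaluation

Accuracy, sensitivity, precision and MCC are computed from integer
confusion counts in exact rational arithmetic; any metric with a zero
denominator is reported as missing (`None`), never as 0 — this matters
for all-positive cross-dataset test sets, where MCC and AUC are
undefined (precision, when its denominator is positive, is reported
even though it is uninformative there). AUC uses the Mann–Whitney
identity with ties counted one half (scikit-learn), with the stepwise
ROC points exported separately.

Cross-validation is stratified by default: fold assignment sorts pairs
canonically by pair id, then deals each class round-robin after a
seeded shuffle, continuing the deal across classes so overall fold
sizes differ by at most one. Assignment therefore depends only on the
seed and the pair ids, not on input order. Stratification prevents
degenerate single-class training splits on small balanced sets; a flag
disables it. Aggregates are mean ± *sample* (n−1) standard deviation
over folds, the convention matching "xx.xx ± yy" summaries at k = 5.

## Synthetic benchmark

The generator emulates curated PPI benchmarks structurally: balanced
positive/negative pair sets, two fresh proteins per pair, lengths
uniform on [50, 600] (the curation floor of 50 upward), uniform residue
background. With probability `signal_strength` an interacting pair
receives one common motif (default length 12; 30 makes a
comfortably detectable benchmark) written into both partners at random
positions. Motifs overwrite rather than insert, so both classes have
identical length distributions and the planted signal is the only
class difference; at `signal_strength = 0` the classes are exchangeable
by construction.

Motif residues are drawn from a fixed leucine-rich, interface-like
composition (`INTERFACE_MOTIF_FREQUENCIES`) rather than from the
background. This is deliberate and load-bearing: a motif drawn from the
background distribution is statistically identical to the window it
replaces, so its descriptor footprint is uncorrelated between the two
partners and no composition-based method can detect it — pilot runs
confirmed chance-level cross-validation in that design, with only
nonlinear cross-half statistics carrying signal. Compositionally biased
motifs mirror real interfaces (hydrophobic patches, coiled-coil
segments) and give the planted signal a consistent low-frequency
footprint the SMR–DCT descriptor resolves.

What the generator does *not* emulate: homology and shared-protein
(hub) structure across pairs, realistic residue backgrounds, negative
sampling by subcellular localization, and network topology. Passing
tests on this benchmark therefore demonstrate that the pipeline
recovers a compositional interaction signal under controlled
conditions — not that it attains the accuracies reachable on curated
biological datasets, where recurring proteins make the sparse-coding
regime (n > m) active and much more favourable.

Typical behaviour at the default study sizes, recomputed by the test
suite and `scripts/acceptance.py`: with full-strength 30-residue motifs
and 200 pairs, 5-fold CV accuracy falls around 0.70–0.88 (mean ≈ 0.78)
across generator seeds, with AUC near 0.9; with the signal off it stays
at chance. Problem sizes throughout (200-pair CV runs, 20-matrix DCT
checks, ≤ 8-atom solver cross-checks) were chosen to keep the full
suite around a minute while leaving the statistical checks
well-powered.

## Known limitations

* The exact weighting formula and the scan order behind "first 400
  coefficients" in prior art are unrecoverable; both are documented
  conventions here (reciprocal similarity; row-major low-frequency
  block) with alternatives exposed as options.
* Multi-class prediction is supported by the residual rule but only
  binary problems are exercised and scored.
* Sequence-identity redundancy filtering of real datasets is dataset
  preparation, not part of the method, and is out of scope.
* In the small-n regime the method is effectively a collaborative
  (least-squares) representation classifier; locality weighting only
  differentiates predictions when sparse coding is feasible.
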