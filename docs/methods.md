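# Methods

This note records the models, algorithms, numerical choices and known
limitations of `discosca`, in the order a data analysis would use them.

## Data model and preprocessing (`discosca.blocks`)

K ≥ 2 blocks **X**_k (I_k × J) are *linked* by sharing their column mode;
every method consumes the row-wise concatenation X_c.  The shared mode is
always the columns internally; files whose rows are shared are transposed
on input (an explicit flag, never guessed, so that a square matrix cannot
be silently misread).

The preprocessing chain mirrors standard practice for component analysis
of omics blocks, each step optional and composable:

- **Below-detection imputation** — missing cells (empty/`NA` fields, or an
  explicit numeric code) are set to half the smallest detected positive
  value *of the whole block*.  The minimum is blockwise, not rowwise,
  because a detection threshold is a property of the platform, not of the
  individual analyte.
- **Square-root transform** for right-skewed nonnegative intensities.
- **Per-row centering and scaling to unit sum of squares**, so abundant
  variables do not dominate and loadings become correlations.  Constant
  rows are an *error*, not a silent drop: removing rows behind the
  caller's back desynchronizes row identifiers between runs.
- **Block weighting** — divide by √I_k, or scale the block to unit total
  SS — so a large block cannot dominate the joint fit.

No NaN survives preprocessing; centering refuses un-imputed input.

## GSVD (`discosca.gsvd`)

Computation follows the CS-decomposition route: thin SVD
X_c = P Σ Wᵀ at numerical rank Q, split P row-wise into P₁/P₂, SVD
P₁ = U₁ C Zᵀ, then G = P₂Z has orthogonal columns whose norms are the
s_q (P₁ᵀP₁ + P₂ᵀP₂ = I), and V = W Σ Z.  Numerical details that matter:

- **Rank**: number of singular values above eps·σ_max·max(I₁+I₂, J),
  eps = machine precision, overridable.  Values written to text files at
  10 significant digits re-read as numerically full-rank matrices — the
  full GSVD of such data legitimately has Q = min(I₁+I₂, J) components.
- **s from column norms**: s_q is taken as ‖G_q‖ rather than
  √(1 − c_q²), which loses half the significant digits to cancellation
  when c_q ≈ 1.
- **Orthonormality of U₂**: G's columns are orthogonal only to machine
  precision; a QR re-orthonormalization (signs aligned to G) makes
  U₂ᵀU₂ = I exactly while moving each column by O(eps).  Components with
  s_q = 0 have an arbitrary u₂q; it is filled by orthonormal completion
  when I₂ allows.  When Q > I₂ at most I₂ columns of U₂ can be
  orthonormal — the remainder stay zero.
- **Tied (c, s) pairs**: exactly tied c values leave the factors
  non-unique (any rotation within the tied group fits).  We canonicalize
  by rotating each tied group so its V columns are orthogonal with
  descending norm — each component in turn explains maximal concatenated
  variation, the same convention the DISCO re-rotation uses.  Components
  whose c² ties another's within 1e−6 additionally carry a stability
  flag, because with noise the returned vectors within such a group are
  still effectively arbitrary.
- **Signs**: the largest-magnitude entry of each v_q is made positive.

VAF accounting: component q accounts for c_q²‖v_q‖² of block-1 SS (exact,
because U₁ has orthonormal columns), s_q²‖v_q‖² of block-2 SS, and
‖v_q‖² of the concatenated SS.  Because V is not column-orthogonal, the
reconstruction SS of a *subset* of components is not the sum of their
per-component shares; the per-component shares themselves are exact.
Components are ordered by descending concatenated VAF, which is the
standard way of choosing a rank-R GSVD approximation — and the reason the
naive GSVD disappoints on common structure: the full decomposition is not
a least-squares fit, so its leading components may approximate the data
poorly.  The adapted GSVD decomposes the rank-R truncated-SVD
approximation of X_c instead (its first step is precisely an SCA), so its
total VAF per block equals the rank-R SCA total by construction.

Classification bands for c²: common = [0.4, 0.6], distinctive =
[0.95, 1] and its mirror [0, 0.05], both configurable; anything else is
`undetermined`.  The bands are deliberately conservative — "close to 0.5"
is a judgment call, and the defaults only label clear-cut components.

## SCA (`discosca.sca`)

The least-squares rank-R simultaneous component model is the truncated
SVD of X_c.  One canonical orientation is used internally: the shared
factor P = V_R is column-orthonormal and all scale sits on the block
factor T = U_R S_R.  With P orthonormal, the SS a component accounts for
within block k is exactly the squared norm of that block's column of T —
the additivity the DISCO deviation measure relies on.  (The opposite
orientation, orthonormal concatenated scores, is a formatting concern for
output, not a modelling one.)  A tie between the R-th and (R+1)-th
singular values is flagged and warned about: the retained subspace is
then not unique.  The scree table (per-component per-block VAF, ordered
by concatenated VAF) may extend past the numerical rank; the extra
components show zero VAF.  No automatic elbow detection is attempted —
the table is the deliverable, the choice of R is the analyst's.

## DISCO rotation (`discosca.disco`)

The rotation objective ‖W ∘ (T B)‖²_F over orthogonal B is non-convex;
it is minimized by iterative majorization: with Z = (1−W) ∘ (T B₀), the
orthogonal-Procrustes update B ← polar(TᵀZ) never increases the
objective (rank-deficient TᵀZ is completed to a full orthogonal B via the
SVD's full factors).  Choices:

- **Starts**: B = I plus 10 random orthogonal restarts from a seeded
  stream (default; configurable).  The identity start is usually the
  winner because the SCA solution is already close to the rotated one,
  but restarts guard against the occasional bad local optimum.
- **Convergence**: two regimes.  At a genuinely nonzero optimum,
  iteration stops when the decrease falls below 1e−10 of the starting
  value.  When the objective is heading to zero (the target exactly
  attainable, e.g. noise-free data), that test would stop at ~1e−11 of
  the start, so the iteration instead polishes until the objective is
  below 1e−15 of the start.  Cap: 1000 iterations, then a warning with
  the trajectory and the best iterate.  Deliberately misfit targets
  probed by `select_target` often crawl in flat optima; their
  convergence status is a column of the selection table rather than a
  stream of warnings.
- **Within-group re-rotation**: components sharing a status give
  identical target columns, so the criterion cannot separate them.  Each
  group is re-rotated to the principal axes of its block-factor
  subspace, so the first component explains maximal variation and each
  next one the maximum of the residual; signs make the largest block-
  factor entry of each component positive.

Deviation of a rotated solution from its target, per component:
distinctive — the proportion of variation accounted for in the block the
component should be absent from (that block's own SS as denominator);
common — the absolute difference of its VAF proportions between the two
blocks.  The targetwise score is the *maximum* componentwise deviation,
and `select_target` retains the minimum over all (R+1)(R+2)/2 status
assignments.  Ties within 1e−9 prefer fewer distinctive components, then
the lexicographically smaller (d₁, d₂) — parsimony first.

For K > 2 (an extension beyond the two-block setting the measure was
defined in): distinctive-type deviation is the maximum VAF over the
absent blocks; common-type is the maximum pairwise VAF difference over
the present blocks.  `enumerate_targets` enumerates only common and
single-block-distinctive statuses; present-in-a-proper-subset targets
must be built explicitly.

A structural caveat uncovered while validating the selection rule: in
noise-free data, per-block VAF proportions sum to one in each block.  A
target mixing common components with distinctive components in only *one*
block therefore cannot be realized at zero deviation — equal common
proportions would leave the lone distinctive block no share — and the
generating target can even tie with the all-common target on max
deviation, in which case the parsimony tie-break selects all-common.
Selection is exact for balanced targets (distinctives in both blocks, or
none, or no commons); for unbalanced truths the rotation to the true
target still recovers the structures, but the deviation measure alone
cannot certify the target.  The test suite asserts exactly this split.

## Synthetic benchmark data (`discosca.synthetic`)

Blocks are generated from X_k = U_k S_k Vᵀ + E_k with U₁, U₂, V
Haar-uniform orthonormal (QR of standard-normal draws with the sign fix)
and diag(S_k)² equal to the imposed per-component VAF profile, so each
component's signal SS in each block hits its imposed share exactly and a
zero entry makes the component structurally absent there.  E_k is white
Gaussian rescaled so SS(E_k) = nf/(1−nf) · SS(signal_k); the noise then
carries the nominal fraction nf of each block's variation in expectation
(default 0.20), with signal–noise cross terms making the realized
fraction stochastic (± ~0.02 at the default sizes).

The three shipped condition profiles — all-distinctive, a 2+2+2 mix, and
all-common, at blocks of 144×28 and 44×28 with six components — are the
default study conditions, with per-component shares transcribed from a
two-decimal table; a feasibility slack of 0.02 on the per-block sum
absorbs that rounding (the all-common block-2 column sums to 0.81 against
a signal budget of 0.80).  Equal imposed shares across blocks give a
common component (near-)equal singular values in both.

What random bases do and do not change: with isotropic noise, every VAF
and congruence statistic is invariant in distribution under left- and
right-orthogonal transformations of the blocks, so drawing U₁, U₂, V
uniformly at random is equivalent to deriving them from any fixed
empirical data set of the same dimensions.  What the generator does *not*
emulate: heteroscedastic or correlated noise, heavy-tailed intensities,
missingness, and non-orthogonal true processes.  Passing benchmarks here
shows the estimators recover the model they assume; it does not certify
behavior under correlated platform noise.

The study driver runs, per condition: a representative pair's
per-component VAF table (components matched to the generated ones by
congruence on V), and mean matched congruences for V, U₁, U₂ over
replications, replication j seeded deterministically as base_seed + j
with fresh bases each time.  DISCO is rotated to the generating target
(the study isolates estimation quality from target selection); the naive
GSVD contributes its six components with highest concatenated VAF.  At
these sizes 100 replications of all conditions take a few seconds, so no
scaling-down of the published protocol was needed.

## Recovery metrics (`discosca.metrics`)

Tucker congruence is the cosine between component vectors — sensitive to
rotation, blind to positive scaling, so congruences are identical for
U_k and U_k S_k estimates.  Matching maximizes the mean |φ| over column
pairings via the Hungarian assignment (deterministic and globally
optimal; exhaustive search over permutations would give the same answer
for the ranks used here), then reflects signs so matched φ ≥ 0.  Matching
is per structure (V, U₁, U₂ separately).  Truth components with zero
signal in a block are excluded from that block's U_k score — their basis
vectors are arbitrary — and a truth with fewer columns than the estimate
is matched against the best-fitting estimate subset.

Cluster separation (`label_separation`): over all labelled row pairs, the
Pearson correlation between the cross product of their loading vectors
(closeness in the solution space) and the binary indicator same(0)/
different(1).  Computed literally, tight well-separated clusters give a
*negative* signed correlation (same-label pairs have the high cross
products); since the sign convention in reported uses of this statistic
is ambiguous, the function returns the signed value and, on request, its
magnitude alongside.

## Command line (`discosca.cli`)

Thin wrappers only; every computation is a library call.  TSV in/out with
identifiers, numbers at 10 significant digits; each run writes a JSON
summary (versions, config echo, fit statistics, wall clock) sufficient to
reproduce it; all randomness flows from a single `--seed`.  Exit codes:
0 ok, 1 user error, 2 computational failure; files written by a failed
run are removed.  An optional YAML key/value config file fills in
defaults; explicit flags win; unknown keys are rejected.

## Known limitations

- The GSVD is implemented for K = 2 only; no multi-block GSVD variant
  with distinctive components exists to implement.
- No oblique or simple-structure (varimax-type) rotations.
- The K > 2 deviation measure is our extension (above), not an
  established definition.
- `enumerate_targets` is exhaustive; for large R with K > 2 the
  enumeration grows quickly and targets are better specified explicitly.
- The generator's isotropy assumption (above) bounds what the benchmarks
  can claim about real platform noise.
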