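# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Survey structure and containers

A staged protocol is a tree of categories → variables, each variable tagged
with the calibration stage (1-based) of its first release. The packaged
default protocol has 7 categories (SOI, CL, MPDE, SI, LTCL, LTMP, EDS), 55
variables and 5 stages; 28 variables appear at stage 1. Variable order is
the protocol order throughout, which makes every matrix index and every
output table deterministic.

Pairwise comparison matrices are validated on construction: positivity,
unit diagonal, and reciprocity a\_ij·a\_ji = 1 within 1e-9, with violations
reported by cell. Entries are *not* restricted to the discrete
{1/9, …, 1/2, 1, 2, …, 9} scale by default — the survey instrument's exact
rating scales are not published, so the standard 1–9 ratio scale is an
assumption here, and the discrete-scale check is opt-in
(`PairwiseComparisonMatrix.validate_scale`).

## Priorities and consistency screening

Priorities are the normalized principal right eigenvector, computed by
power iteration from the uniform vector (cap 10 000 iterations, tolerance
1e-12). By Perron–Frobenius the limit is unique and strictly positive for
any positive reciprocal matrix. Whether the motivating survey derived
priorities by eigenvector or another method is not stated in the available
material; the eigenvector is the canonical ANP input and is documented here
as this package's choice. The row-geometric-mean derivation is provided as
an alternative (`row_geometric_mean`); the two agree in the consistency
limit, with a gap that shrinks proportionally to CR (about 0.2·CR
empirically), which the test suite checks.

Consistency uses CI = (λ\_max − n)/(n − 1) and CR = CI/RI(n) with Saaty's
published random-index table for n = 1…15 (0, 0, 0.58, 0.90, 1.12, 1.24,
1.32, 1.41, 1.45, 1.49, 1.51, 1.48, 1.56, 1.57, 1.59). Orders above 15
raise an explicit error. Order-2 matrices are reciprocally determined and
always consistent; CR is defined as 0 for them. Screening: CR ≤ 10 % is
acceptable, 10 % < CR ≤ 30 % is flagged for review (the original survey
resolved these by interview; this package only flags), and a modeler with
*any* matrix above 30 % is excluded.

Aggregation across judges uses the element-wise geometric mean of the
matrices (the only rule that preserves reciprocity, which is re-imposed
exactly from the upper triangle) before priority derivation; the arithmetic
mean of per-judge priority vectors is available behind
`aggregate_priorities`. Group-level tables always pool per-judge priorities
(mean ± sd), because the survey reports per-judge variability.

## DEMATEL

The direct-influence matrix is normalized by s = max(max row sum, max
column sum) — the common DEMATEL convention; the source study's
supplementary derivation is unavailable, so the convention is documented
rather than attributed. The scaling bounds the spectral radius below 1 for
any matrix with a strictly dominant scaling; this is verified numerically
and violations (e.g. permutation-like patterns) raise rather than produce a
divergent series. T = N(I − N)⁻¹ sums all direct and indirect influence
paths; the test suite checks it against a truncated Neumann series (400
terms, so the truncation error is far below the 1e-8 comparison tolerance
even at spectral radius 0.9).

Profiles report G (row sum), R (column sum), net influence G − R, dominance
G + R, and the outgoing share G/(G + R). Categories are classed by the sign
of G − R; |G − R| ≤ 1e-9 is reported as "neutral" — a class degenerate
(e.g. perfectly symmetric) inputs need even though real surveys do not.
Pooling across modelers computes each modeler's T first and averages the
profiles (sd with denominator n − 1), not the T of the averaged direct
matrix, matching the mean ± sd reporting of per-judge influence levels.

## ANP integration

The category weighting matrix is the column-normalized T (the standard
DEMATEL→ANP hybrid): entry (i, j) is the influence-derived weight of source
category i on target category j, with a uniform fallback for zero columns.
Inner dependence among variables *within* a category is not modeled — the
survey collects variable-level comparisons per category and influence only
between categories — so the supermatrix block (target t, source s) is the
target category's local priority column scaled by the cluster weight
w[t, s]. Every column then sums to one by construction, and
column-stochasticity is asserted at each step.

The limit is computed by repeated squaring until every row is constant
across columns (spread < 1e-9), with column renormalization each step to
kill floating-point drift. Periodic chains (which cannot arise from
positive influence matrices but can from degenerate inputs) are detected by
cycle search over successive powers and resolved by the Cesàro average over
one period; reducible networks whose limit depends on the starting column
raise an error.

Under the block structure above the limit factorizes: a variable's global
importance is its within-category priority times its category's stationary
weight. This is exactly the "variable ranking normalized over the
importance score of its category" construction used by published
stage-importance tables, and it means per-stage normalized importances are
the global importances restricted to a stage: they sum to ΣP\_s within each
stage and to 1 across stages. The exact defining equation of the original
study's importance score is in unavailable supplementary material; the
chain above is this package's operationalization.

The packaged published per-variable table (means ± sd by stage) is shipped
as a fixture for stage-aggregation arithmetic only — it is an *output* of
the original survey, not something this package can recompute from raw
data. Entries printed as "<0.01"/"<0.00" are stored as 0.0 with a
`below_precision` flag. Summing its entries reproduces the printed stage
cumulative importances for stages 2, 3 and 5 exactly at display precision;
the stage-1 and stage-4 columns sum to 0.68 and 0.06 against printed totals
0.67 and 0.05 — rounding artifacts of the source table, not of this
implementation, and the package reports the sums as computed.

## Agreement statistics

Rank scores are mid-ranks of each judge's priority weights, ascending in
importance (ties share the average rank, so each judge's ranks sum to
n(n + 1)/2). The exact rank construction of the original instrument is
unpublished; mid-ranks of priorities are the documented operationalization.

Kendall's W uses the tie-corrected form
W = 12·SS / (m²(n³ − n) − m·F) with F = Σ\_judges Σ\_tie-groups (t³ − t);
with no ties it reduces exactly to the classic formula. A fully tied table
makes the denominator non-positive and raises. Significance uses
χ² = m(n − 1)W on n − 1 degrees of freedom; a judge-wise permutation test
(`method="permutation"`) is available for small panels. Under the null of
independent rankings E[W] = 1/m, which the Monte-Carlo test verifies.
Note that adding a duplicate of one judge does *not* always increase W
(duplicating an atypical judge can lower it); the invariants that do hold —
W unchanged under relabeling and under duplicating the whole panel — are
the ones tested.

Wilks' Λ = det(W)/det(W + B) is computed from within- and between-group
cross-products with log-determinants, and Rao's F approximation gives the
p-value (verified to 1e-8 against statsmodels' MANOVA). Because priority
weights within a category sum to one, a MANOVA over a full category's
weight columns is singular by construction: the CLI drops one variable per
category for the multivariate test and keeps all of them for the
per-variable ANOVA follow-ups. With ~20 judges a 55-variable MANOVA is
impossible (more features than observations); the operation requires a
reduced feature set (typically one category at a time) and raises
otherwise. Group tests run one factor at a time (model type; experience
class); no interaction model, and no multiple-testing correction across
variables by default (a Holm adjustment is available behind a flag).

## Error link (MER)

ΣP\_s is the running sum of stage importances, strictly positive from
stage 1 (a stage with zero total importance would make the ratio
undefined, and raises). MER\_s = RRMSE\_s / ΣP\_s is the primary
definition — error per unit of cumulative importance, one value per stage;
the incremental reading ΔRRMSE/ΔΣP is available as `incremental=True` and
labeled distinctly in outputs, since the published display equation cannot
be recovered from the available text. RRMSE may be a fraction or a percent;
the unit is recorded and carried through, never silently converted. Useful
identities: MER\_s·ΣP\_s = RRMSE\_s exactly; scaling RRMSE by c scales MER
by c and leaves percent changes unchanged.

## Synthetic survey generator

The generator emulates the study design, not its undeposited data:

- **Latent weights.** Shared per-category weight vectors are Dirichlet
  draws (concentration 5 by default — moderately dispersed, strictly
  positive). Each modeler's realized weights are
  normalize(α·shared + (1 − α)·idiosyncratic (+ group shift)).
  α (`agreement`, default 0.7) is the dial for between-judge concordance.
- **Ratio compression.** Every realized weight vector is power-compressed
  (w ← w^γ, renormalized) so max(w)/min(w) ≤ 9. Judgments live on the 1–9
  scale and generated entries are clipped to it; without compression the
  clipping would corrupt even the σ = 0 consistent case. Ground truth
  stores the compressed vectors, so recovery is exact by construction.
- **Judgment noise.** Upper-triangle entries are (w\_i/w\_j)·exp(ε),
  ε ~ N(0, σ²) i.i.d., reciprocity imposed from the upper triangle.
  Multiplicative log-normal noise is the standard error model for
  ratio-scale judgments and the only one for which σ = 0 gives CR = 0
  exactly. The default σ = 0.5 was calibrated once so that the mean CR of
  generated surveys sits near the 7 ± 1 % reported for the retained judges
  of the motivating survey, with no spurious exclusions.
- **Influence ratings.** A fixed ground-truth direct-influence matrix
  (climate and site-information categories as net influencers, soil,
  management and experimental-data categories as receivers, mirroring the
  study's qualitative finding) plus element-wise half-normal noise
  (`influence_noise_sd`, default 0.1).
- **Groups.** `GroupEffect` assigns modelers round-robin to shifted
  label(s) plus a reference group on one factor and adds per-category
  weight shifts before renormalization. The effect size used in the power
  test (a shift of (0.2, 0.1, −0.1, −0.1, −0.05, −0.05) on the
  experimental-climate weights) was chosen once as a clearly detectable
  but not overwhelming separation.
- **RRMSE.** rrmse\_s = mer\_target\_s · ΣP\_s(truth) + truncated Gaussian
  noise; with zero noise the error-link analysis inverts it exactly.

Ground-truth global priorities are computed analytically (shared weights ×
the stationary distribution of the truth-derived cluster weighting matrix,
via a dense eigensolver) — a different route from the supermatrix squaring
used by the pipeline, so recovery tests compare two independent
computations.

**What the synthetic tests do not show.** The generator produces exactly
reciprocal matrices from a well-specified noise model; real judges produce
discrete-scale judgments with psychological biases (anchoring, framing)
that are not multiplicative log-normal, and real group differences are not
clean additive shifts. Passing recovery and calibration tests demonstrates
the pipeline's correctness and sensitivity under the stated model, not that
the model captures human judgment.

## Problem sizes and numerical choices

Tests and the acceptance analysis run surveys of 20 modelers on the full
55-variable protocol; replication counts are 50 for recovery and 100–200
for calibration trends — enough for stable means at the tolerances tested
while keeping the default suite fast. Tolerances: reciprocity and
column-stochasticity 1e-9; power/limit iterations 1e-12/1e-9; oracle
comparisons 1e-7–1e-8; "neutral" influence classification 1e-9. Ties in
ranks use mid-ranks everywhere; degenerate inputs (all-zero influence,
fully tied rank tables, zero-importance stages, reducible supermatrices)
raise typed errors rather than returning conventional values.

## Known limitations

- The original survey's raw responses are not deposited: published
  importance values are shipped only as an aggregation fixture, and none of
  the original per-judge numbers can be reproduced.
- Several formal details of the original analysis (rating scales, priority
  derivation, rank construction, the exact display equation of the error
  rate) are in unavailable supplementary material; each is replaced by a
  documented standard choice, flagged above.
- Inner dependence among variables within a category is not modeled.
- The chi-square approximation for W is asymptotic; for very small panels
  use the permutation test.
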