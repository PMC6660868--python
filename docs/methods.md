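# Methods

## Model

An establishment's sanitary risk is a convex combination of three component
scores, each on the 1–5 scale (5 = highest risk):

    IRA = β₁·VT + β₂·VP + β₃·SOA,   β₁ + β₂ + β₃ = 1.

VT and VP are weighted means of ordinal variable scores; the per-group
variable weights sum to 1. SOA standardizes each product risk's
Severity × Occurrence × Affectation product by cube root, which is the
geometric mean of the three scores and therefore (a) stays in [1, 5],
(b) is symmetric in S, O, A, and (c) is strictly increasing in each. With
all inputs in [1, 5] and all weights convex, every component and the IRA
are closed over [1, 5], and the IRA is monotone non-decreasing in every
input — the properties the test suite asserts.

The model assumes scores arrive *pre-coded*: an inspector (or an upstream
system) has already mapped observed conditions to 1–5 via reference tables.
Reference tables are data, not code — the configuration format accepts
arbitrary condition→score maps per variable, shared across or specific to
product lines, because only a handful of tables are public.

## Banding

Published band descriptions overlap at the integers ("between 3 and 4",
"between 4 and 5"). We fix half-open intervals closed at the top:
bajo [1,2), moderado [2,3), alto [3,4), muy alto [4,5]. A boundary value
escalates to the more protective band, consistent with the model's
precautionary purpose.

## Multi-risk aggregation

How several product risks combine into one SOA component is genuinely open;
the published worked example has a single risk and cannot distinguish
conventions. Default is `max` — an establishment is as risky as its worst
product risk — with `weighted_mean` (currently unweighted) as the
configurable alternative.

## Weight estimation

**Variable weights** come from a single-component categorical PCA with
optimal scaling on a historical panel of ordinal scores (rows =
establishments, columns = variables of one scope/product-line group).
The alternating-least-squares loop:

1. object scores `z` (centered, ‖z‖² = n) from the current quantified,
   standardized matrix: `z ∝ Q·a`;
2. per variable, the best category-wise monotone approximation of `z`
   (weighted isotonic regression on the 1–5 categories; both orientations
   are tried and the better one kept, so negatively associated variables
   are representable); the fitted values are re-standardized into the
   quantified column and its loading `a_j = qⱼ'z/n`.

The loss `(nm)⁻¹ Σⱼ ‖z − aⱼqⱼ‖²` is non-increasing by construction
(asserted every iteration); convergence is declared when the relative
improvement falls below `tol` (default 1e-6; `max_iter` 500). The start is
deterministic — standardized raw scores, never a random configuration.
The published method does not state how loadings become the printed
percentage weights; we adopt **squared first-component loadings normalized
to sum 1** (a variance-contribution reading). This is a modeling choice and
the main caveat when comparing to externally published weight tables.

In the linear limit the estimator must agree with classical PCA. The exact
realization used in tests: with *two-level* columns the standardized
monotone quantification is uniquely determined by the category proportions,
so the ordinal step is idle and ALS reduces to power iteration on the
correlation matrix; weights then equal normalized squared first-eigenvector
loadings to 1e-6 (with tight `tol`). Panels with more levels are only
approximately idle, which is why the oracle-equivalence test is built on
binary columns.

**Component betas** come from a one-factor model on the standardized
(VT, VP, SOA) columns, fitted by principal-axis iteration (initial
communalities = max absolute off-diagonal correlation; reduced-correlation
eigen step; Heywood communalities clipped to 1; tolerance 1e-12 on the
communalities). Betas are squared loadings normalized to sum 1. With three
variables and one factor the model is just-identified, and on an exact
one-factor correlation structure the iteration recovers the loadings to
numerical precision. Principal-axis extraction (rather than maximum
likelihood) is the default flavor — a documented choice, not a claim about
how any published weights were obtained. Degenerate fits (no positive
leading eigenvalue, invalid loadings) fall back to configured default betas
(0.45, 0.25, 0.30 — the published example's values) with a warning rather
than failing a production run. Whether betas should be estimated globally
or per product line is left to the caller; both are expressible through
config scoping.

## Portfolio indices

IRAC is the 90th percentile of the IRA values, computed by **linear
interpolation between closest ranks** (`numpy.percentile(..., method=
"linear")`), fixed so the figure is bit-reproducible; roughly 90% of
establishments sit at or below it. Ranking is descending IRA with ties
broken by descending SOA component then lexicographic id — a deterministic
total order. The effectiveness indicator is 100 · measures / visits.

## Numerical conventions

- All arithmetic at full float precision; **half-up rounding to the printed
  number of decimals only at display/report time** (reports can render
  comma decimals; data files always use dot decimals, UTF-8, comma
  separators).
- Weight groups and betas whose sums deviate from 1 by ≤ 0.5% (rounded
  published percentages) are renormalized to sum exactly 1; larger
  deviations are fatal validation findings.
- Records missing some configured variable scores are scored on the rest
  with weights renormalized and a warning logged, rather than rejected;
  records with no assessed product risks are an error unless explicitly
  flagged incomplete.
- Betas must sum to 1 within 1e-9 at scoring time; scored profiles satisfy
  the IRA equation to 1e-9 by reconstruction.

## Synthetic data

The generator stands in for the (unavailable) real registry. Per
establishment a latent risk factor F ~ N(0,1) is drawn; each ordinal
variable score discretizes `λ·F + √(1−λ²)·ε` (ε standard normal, λ the
variable's loading ∈ [0,1]) at standard-normal quintile cut-points, so
marginal category frequencies are uniform and the Spearman correlation with
F increases monotonically in λ — known ground truth for the
weight-recovery tests. S, O and A use the same construction with their own
loading (default 0.6), so the SOA component co-moves with VT/VP as the
model assumes. Default simulation sizes in the tests (panels of 300–600
rows for weight recovery, portfolios of 1 000–5 000 for property and
recovery checks, 200 replicates for the noise-variable Monte Carlo) were
chosen as the smallest sizes at which the sampling error of the checked
quantity is comfortably inside the asserted band.

What the generator does **not** emulate: skewed or line-specific marginal
distributions, serial updating of profiles after inspections, multiple
correlated latent dimensions, or missing-data patterns of a real registry.
Passing tests therefore demonstrate correctness of the algorithms under a
single-common-factor world, not calibration to any agency's portfolio.

## Known limitations

- Only one retained component/factor; multi-dimensional risk structures are
  out of scope.
- The loading→weight rule (squared normalized loadings) is one defensible
  convention among several; externally published weights need not match.
- The per-risk `weighted_mean` aggregation currently uses equal weights;
  per-risk weighting is an extension point.
- Portfolio-level published figures that depend on a private registry
  (e.g. a corporate index value or effectiveness trends) are not
  reproducible and are covered by definition-level oracle tests instead.
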