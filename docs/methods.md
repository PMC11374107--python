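# Methods

`mixint` estimates two-way interactions among the components of a chemical
mixture in a case-control study, under heavy left-censoring of the exposure
measurements at per-chemical limits of detection (LOD). This note records
the models, the sampler algebra, the synthetic-data conditions used for
validation, and the design choices made where the design was genuinely open.

## Outcome model and robit augmentation

For subject *i* with binary outcome *Y<sub>i</sub>*, covariates
*U<sub>i</sub>* (intercept included as the first column), main-effect design
*X<sub>i</sub>* and interaction design *Z<sub>i</sub>*, the target model is
the logistic regression

logit P(Y<sub>i</sub> = 1) = U<sub>i</sub>′α + X<sub>i</sub>′β + Z<sub>i</sub>′γ.

Sampling uses the robit(ν) latent-utility representation: ξ<sub>i</sub> =
U<sub>i</sub>′α\* + X<sub>i</sub>′β\* + Z<sub>i</sub>′γ\* + ε<sub>i</sub>
with ε<sub>i</sub> ∼ t<sub>ν</sub> and Y<sub>i</sub> = 1 iff ξ<sub>i</sub> >
0. The t error is handled as a scale mixture of normals: a per-subject
mixing weight λ<sub>i</sub> ∼ G(ν/2, ν/2) makes ξ<sub>i</sub> | λ<sub>i</sub>
Gaussian, so every conditional in the Gibbs scan is conjugate. With ν = 7
the logistic distribution is closely matched by 1.5484 × t<sub>7</sub>
(sup-norm CDF gap 6.4 × 10⁻⁴ on [−10, 10], computed by
`robit_logit_gap`), which gives the coefficient calibration

robit-scale coefficient = logit-scale coefficient / 1.5484.

The sampler therefore works on the robit scale and `convert_to_logit_scale`
multiplies draws by 1.5484 before any reporting, so all reported effects
are log odds ratios. The constant is calibrated for ν = 7 only; other ν
raise rather than silently mis-scale. (The multiplication direction is
dictated by the standard-t latent error: a robit(7) fit of a logistic truth
returns coefficients smaller by the factor 1.5484, which we verified
against a maximum-likelihood logistic fit in the test suite.)

Truncated-normal draws of ξ use an inverse-survival-function transform,
x = −Φ⁻¹(u · Φ(−a)), which retains full precision however deep the
truncation, switching to Robert's exponential-proposal rejection sampler
when the standardized bound exceeds 30 (where Φ(−a) underflows). Naive
inversion of the CDF underflows already for bounds around 8.

## Exposure parameterizations

All designs are pure functions of the exposure matrix; pairs (j, k), j < k,
are ordered lexicographically, giving K = p(p−1)/2 interactions.

* **linear** — main column x<sub>j</sub>, interaction column
  x<sub>j</sub>x<sub>k</sub> (d<sub>β</sub> = d<sub>γ</sub> = 1).
* **polynomial** — per chemical (x, x²); per pair the four monomials
  (x<sub>j</sub>x<sub>k</sub>, x<sub>j</sub>²x<sub>k</sub>,
  x<sub>j</sub>x<sub>k</sub>², x<sub>j</sub>²x<sub>k</sub>²)
  (d<sub>β</sub> = 2, d<sub>γ</sub> = 4).
* **lod** — two parameters per exposure: 1{x ≥ C} (the log odds at the
  detection limit relative to below it) and 1{x ≥ C}(x − C) (the slope
  above the limit); per pair the four pairwise products
  (d<sub>β</sub> = 2, d<sub>γ</sub> = 4). A subject below the LOD on
  chemical j contributes exact zeros to every column involving j, and the
  magnitude stored in a censored cell is never read. The boundary x = C
  counts as detected. The fourth interaction column is
  (x<sub>j</sub> − C<sub>j</sub>)(x<sub>k</sub> − C<sub>k</sub>) gated by
  both indicators — the symmetric form implied by its interpretation as the
  joint above-limit slope.

The correlation filter (drop one member of each exposure pair with Pearson
|r| > 0.9) operates on the log scale, after transformation; the member to
drop is chosen by a seeded RNG so the retained set is reproducible. The
threshold and the filtering stage are arguments, not constants.

## Priors and conjugate updates

Covariate coefficients always carry N(0, 10²). Three regimes govern β and γ:

* **vague** — N(0, 10²) on every coefficient; effectively maximum
  likelihood at the sample sizes considered here (posterior means agree
  with a logistic MLE to < 0.1 at n = 2000).
* **independent shrinkage** — β<sub>j</sub> ∼ N(0, 1/(a η<sub>j</sub>)),
  γ<sub>jk</sub> ∼ N(0, 1/(b θ<sub>jk</sub>)), all of η, θ, a, b ∼ G(1, 1).
  Local scales let individual effects escape; globals pool across effects.
* **shared (heredity) shrinkage** — as above but
  γ<sub>jk</sub> ∼ N(0, 1/(b η<sub>j</sub>η<sub>k</sub>θ<sub>jk</sub>)):
  an interaction is shrunk hard whenever either parent main effect is,
  encoding the hierarchical principle softly.

Every scale update is conjugate; for example under the shared prior

η<sub>j</sub> | · ∼ Gamma(1 + (d<sub>β</sub> + (p−1)d<sub>γ</sub>)/2,
1 + a‖β<sub>j</sub>‖²/2 + ½ Σ<sub>k≠j</sub> b η<sub>k</sub> θ<sub>jk</sub>
‖γ<sub>jk</sub>‖²).

For vector blocks (polynomial, LOD) one local scale is shared by all
components of a block — the minimal extension of the scalar prior, chosen
so the heredity coupling still acts at the chemical level; per-component
local scales would decouple the four interaction components. The test suite
verifies each conditional against a grid-normalized product of its prior
and the Gaussian terms it enters (total-variation distance < 0.01 for block
dimensions 1, 2 and 4), and a Geweke-style successive-conditional
simulation on an n = 20, p = 2 model reproduces the prior coefficient
moments (ESS-adjusted z-tests at the 0.01 level).

The scan order is fixed (ξ, λ, coefficients jointly, η, θ, a, b) and a
single seeded generator is threaded through everything, so runs are
bit-reproducible. Coefficients are drawn jointly from their multivariate
normal conditional via a Cholesky factor of the precision; a pivot ratio
below 10⁻⁷ (the √ε scale at which rank deficiency hides inside a
"successful" factorization) is treated as singular and rejected with a
pointer to collinear columns. Defaults are 10 000 iterations with 5 000
burn-in and no thinning; initialization is coefficients 0, all shrinkage
scales 1, λ = 1 and one truncation-respecting ξ draw at mean 0.

## Latent-functional model

Each chemical's dose-response contribution is one of L shared latent
polynomial functions f<sub>l</sub>(x) = β<sub>l1</sub>x + … +
β<sub>lc</sub>x<sup>c</sup> (cubic, c = 3, by default), selected by a
membership indicator g<sub>j</sub> with P(g<sub>j</sub> = l) = ω<sub>l</sub>;
interactions use the product variable Z<sub>k</sub> =
x<sub>j₁</sub>x<sub>j₂</sub> with their own M functions and weights Ψ. For
numerical stability the covariates are centred and scaled to unit SD
(denominator n) and every main/interaction variable is divided by its
column maximum before powers are taken (scaling Z first and then raising it
to powers; the alternative — scaling each power separately — changes only
the interpretation of the class coefficients, not the fitted curves).
Priors: N(0, 10²) per class-coefficient component and covariate effect,
symmetric Dirichlet(1) on ω and Ψ, treated independently. All are
configurable.

Because all members of a class share one coefficient vector and their
contributions add inside each subject's latent utility, the conditional for
a class coefficient pools the *sum* of its members' design blocks (a class
with two identical members is algebraically a single member with a doubled
block). Empty classes draw from the prior, keeping the chain irreducible
across assignments. Membership draws are categorical with log-domain
max-subtraction.

Label switching is left in the raw draws. The two reported summaries are
label-invariant: risk curves are built from the effective coefficients
δ<sub>j</sub> = β<sub>g<sub>j</sub></sub>, and the class-probability table
sorts within each iteration before averaging. The table reports two sorted
summaries: the mean sorted *occupancy fractions* (share of chemicals/pairs
assigned to each class), which genuinely approach zero for unused classes,
and the mean sorted Dirichlet *mixture weights*, whose posterior mean for
an unused class cannot drop below 1/(p + L) under a Dirichlet(1 + counts)
update. Parsimony statements ("extra classes get near-zero weight") refer
to the occupancy column. Sorting also biases symmetric truths — a balanced
two-class generator cannot display (0.5, 0.5) in sorted weights — which is
documented behaviour of order statistics on a simplex.

Risk curves report f(x) − f(0) per draw (zero at no exposure by
construction), rescaled to the logit scale, summarized by the posterior
mean and 95% HPD band; grids outside the observed exposure range trigger an
extrapolation warning.

## Synthetic data generator

The generator emulates the structure of a population-based case-control
study of non-Hodgkin's lymphoma with chemical concentrations measured in
carpet dust. Log-scale exposures are multivariate normal (lognormal
concentrations); detection limits are set at the empirical column quantile
of the target below-LOD fraction; outcomes are Bernoulli from the logistic
model of the chosen truth. Case-control sampling is emulated prospectively
with the intercept tuned by root-finding to the target case fraction —
under a logit link outcome-dependent sampling moves only the intercept, so
the exposure coefficients are unaffected by this shortcut.

The `nhl_like` preset freezes the study conditions: n = 1180 (expected 672
cases / 508 controls), p = 14 exposures with exchangeable correlation 0.3
and one pair at 0.95 (so the correlation filter has work to do), below-LOD
fractions {0.03, 0.10, 0.20, 0.30, 0.40, 0.50, 0.58, 0.64, 0.68, 0.72,
0.80, 0.85, 0.90, 0.93} — range 3%–93%, median exactly 61% — and four
covariates (site, sex, education, age analogues) plus intercept. The
default truth has two nonzero main effects (+0.5, −0.5 on the logit scale)
and one nonzero interaction (+0.4) between those two chemicals.

Below-LOD imputation fits each column's normal mean/SD by censored-data
maximum likelihood (observed cells plus the censored count; observed-cell
moments alone are badly biased under 60%+ censoring) and replaces each
censored cell with one draw from the fitted normal truncated above at the
limit — a single realization per call, seeded. Columns with fewer than 10
observed values are rejected as inestimable.

What the generator does **not** emulate: assay measurement error,
batch/plate effects, correlated censoring mechanisms (limits independent of
the outcome by construction), covariate-exposure dependence, and genuine
retrospective sampling. Passing tests therefore demonstrate correctness of
the samplers and the qualitative behaviour of the priors under the stated
conditions, not robustness to those real-data features.

## Posterior summaries

HPD intervals use the sorted-sample shortest-window method: the shortest
window containing ⌈level·n⌉ consecutive order statistics, leftmost window
on ties (deterministic); at least 100 draws are required. Interaction
screening is pointwise — an interaction is flagged when its 95% HPD
interval excludes zero — with no multiplicity adjustment, so ~5% of truly
null interactions flag by chance; with 91 candidates that is ~4-5 expected
false flags, a caveat any user of the report should carry. The cross-prior
comparison tabulates per-interaction interval lengths and reports the modal
ordering; on null-interaction data with several true main effects the modal
ordering is vague > independent > shared, the efficiency gain of shrinkage
plus heredity.

## Validation problem sizes

The test suite validates at desk scale: conditional-exactness checks on
grids (deterministic); Geweke at n = 20, p = 2 with 120 000 sweeps; HPD
coverage of a known truth at n = 2000, p = 5 over 50 replicates (≥ 90%
coverage observed for the 95% intervals); prior-ordering at n = 600, p = 8
(28 pooled null interactions); latent-class parsimony at n = 1000, p = 6,
L = M = 5 against a two-class truth; and the LOD-mechanism contrast at
n = 2000, p = 4 over 20 replicates, where the two-parameter model covers
the true below-LOD discontinuities while the impute-then-linear pipeline
converts a pure step (true above-LOD slope 0) into a systematically
positive slope estimate — the mechanism by which imputation-based analyses
and censoring-aware analyses can disagree about interactions.

## Known limitations

* The conversion to the logit scale exists only for ν = 7.
* No reversible-jump selection of L and M; fit a grid and inspect weights.
* No multiple-imputation pooling — one imputation realization per call.
* Ridge/lasso/horseshoe comparison priors are out of scope; external
  packages can be run on the same designs.
* No spline or kernel bases; polynomial order is the only nonlinearity.
* Pointwise screening carries the multiplicity caveat above.
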