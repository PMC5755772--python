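# Methods

## The problem and the data model

The package analyses a cross-sectional cohort of postmenopausal women
characterised by 16 variables: age, years since menopause, BMI, spine
deformity index (SDI — the sum of Genant semiquantitative vertebral
fracture grades 0–3 over the 13 levels T4–L4, range 0–39), bone-turnover
markers (ALP, BAP, CTX, 25-OH vitamin D), bone quantity (lumbar and
femoral-neck BMD, neck T- and Z-scores), bone quality (trabecular bone
score TBS, lumbar DXA bone strain BS), and two binaries (Romberg test
positivity, vertebral fracture status).  The question the maps address is
which variables sit structurally close to the fracture state.

No record-level data are available, only the cohort's marginal summary
table (mean, SD, median, min, max of each continuous variable, n = 125).
The pipeline is therefore built around a synthetic-cohort generator whose
defaults reproduce those summaries, with a planted dependence structure
that downstream stages must recover.

## Synthetic cohort generator

**Marginals.** Each continuous variable is a truncated normal on its
published [MIN, MAX] range; the parent location and scale are solved
numerically (Levenberg–Marquardt on the analytic truncated moments) so the
truncated mean and SD match the published values to within 0.1%.  SDI is
the exception: its published median of 0 with mean 2.03 / SD 4.05 demands a
zero-inflated family, implemented as a point mass at zero plus a truncated
geometric tail on 1..19.  The two parameters (zero probability, tail decay)
are jointly moment-matched; the fitted zero probability is ≈ 0.69, so the
median 0 comes out automatically.  CTX and bone strain are visibly
right-skewed in the published table (mean ≫ median); the truncated-normal
family reproduces their mean/SD/range but not their skew, a documented
simplification — their medians are not fitted targets.

**Dependence.** Continuous variables are coupled by a Gaussian copula.  The
default latent correlation is block-structured: a bone-turnover block (CTX,
ALP, BAP at ρ = 0.6), a bone-density block (lumbar/neck BMD, neck T/Z at
ρ = 0.7), quality links (TBS vs bone strain −0.5; bone strain vs the two
BMDs −0.4), and age vs years since menopause at 0.9; everything else is 0
and the matrix is projected to the nearest PSD correlation (eigenvalue
clipping with diagonal renormalisation).  These values are chosen to
reproduce the qualitative adjacency structure of the published maps, not as
quantitative claims about the cohort.

**Binary outcomes.** Each binary outcome is an independent Bernoulli draw
per record with probability logistic(intercept + coefficients ·
standardized latents).  A 15th purely latent "balance" trait is appended to
the copula: Romberg positivity loads on it (1.2) plus a mild age effect
(0.3); fracture loads on lumbar BMD (−0.8), neck BMD (−0.5), TBS (−0.6),
bone strain (+0.7) and the balance trait (+1.0), so fracture co-occurs with
low density, poor quality and impaired balance.  Intercepts are calibrated
by Gauss–Hermite quadrature so the marginal prevalences hit their targets
(defaults: fracture 0.25, Romberg 0.30 — the study reports neither, so both
are config-exposed).  A consequence of drawing fracture as a stochastic
outcome rather than deriving it from the simulated SDI is that the two are
consistent only in distribution, not per record; the subgroup analysis
therefore drops the fracture node inside each SDI subgroup by design.

**Determinism.** Every variable and outcome draws from its own named
substream (seed combined with a CRC-32 of the name), so a fixed (seed,
config) gives bitwise-identical tables and adding a column leaves the
others' draws untouched.

## Complementary encoding

Continuous variables are min–max scaled against the observed per-column
range (within-sample scaling; fixed external bounds are available as an
option) and expanded into a "high" node carrying the scaled value and a
"low" node carrying its complement.  Binary variables skip scaling and
expand into yes/no nodes directly.  The complement is computed as
`1.0 − high` in double precision, and the suite asserts `high + low == 1`
exactly for every cell.  Constant columns are a hard error naming the
variable — there is no geometry to recover from them.

## Auto-Contractive Map

One unit per node in each of three layers.  For record *s* with node values
m_s(i) ∈ [0,1], hidden h_s(i) = m_s(i)(1 − v(i)/C), net input
Net_s(j) = Σ_i (w(i,j)/C) h_s(i)/N, output o_s(j) = h_s(j)(1 − Net_s(j)/C),
with batch updates

    Δv(i)   = mean_s (m_s(i) − h_s(i)) (1 − v(i)/C)
    Δw(i,j) = mean_s (h_s(j) − o_s(j)) (1 − w(i,j)/C) h_s(i)

The input weights v rise monotonically toward the contraction constant C,
squeezing the hidden signal to zero; training therefore terminates by
itself (convergence = mean |Δw| per epoch below 1e−8, cap 5000 epochs;
default runs converge in a few dozen epochs).  The frozen w records how
strongly node pairs co-activated while signal still flowed; pairs with
higher joint activation — which is what ranks the joint probability of
variable pairs — end with strictly larger weights, verified on planted
copula correlations (0.8 > 0.4 > 0.0 gives strictly ordered weights).

Numerical choices: C defaults to 1.0 (inputs live in [0,1]); initial
weights are a uniform constant 1e−4, so training is deterministic with no
seed; updates are batch, making record order irrelevant (the
`record_order_seed` field is interface-compatibility only); the learned
matrix is symmetrized (w + wᵀ)/2 before use, as the batch dynamics is
near- but not exactly symmetric.  The exact learning constants of the
original Auto-CM software are not published; because the distance transform
below rescales min–max, any formulation difference that only changes the
overall weight scale cannot change the maps.

## Distances and map filters

d(i,j) = (C − w(i,j)), min–max rescaled over the off-diagonal to [0,1],
diagonal forced to 0 — strictly decreasing in w, so the strongest
association has distance 0 and the weakest 1.  An all-equal weight matrix
is rejected (no resolvable geometry).

**MST.** Kruskal on the sorted edge list with lexicographic tie-breaking on
the (sorted) label pair, so equal-distance inputs give a reproducible tree;
total weight is verified in the suite against exhaustive enumeration of all
labelled spanning trees via Prüfer sequences and against an independent
library implementation.

**MRG.** Candidate graphs G_k = MST + the k shortest non-tree edges (same
edge ordering), k = 0..node count; the regularity score is H(G_k) =
R/(1 + k) where R counts the cycles of a minimum cycle basis whose member
nodes all share the same degree in G_k ("regular cyclic microstructures").
The returned graph maximises H, smallest k on ties, so a graph with no
regular cycles returns the MST itself.  The MRG is by construction an edge
superset of the MST.  The original software's regularity function is
unpublished; this H is a documented reconstruction satisfying the stated
constraints (tree ⇒ H = 0; a triangle over its spanning tree scores 1/2;
added complexity is penalised linearly), and numeric agreement with the
original maps is therefore not asserted — map topology is validated on
synthetic data with known structure instead.

**Hubs.** Degree ranking, ties lexicographic.  Hubs form where joint
activation is high — typically "low" nodes of right-skewed variables (most
of the cohort shares that state), mirroring the low-turnover hub the
published map shows.

**Subgroups.** The cohort splits at SDI > 5 (fractured subgroup) versus the
rest; SDI = 5 goes to the non-fractured side, since only ">5" defines the
fractured group.  Each subgroup gets its own full encoding → Auto-CM → MRG
pass with the fracture variable removed; subgroups smaller than 2 records
or with constant continuous columns are errors naming the offenders.  Maps
are compared by edge-set Jaccard over unordered label pairs.

## Triage rule

Criteria: osteoporotic T-score (≤ −2.5, the operational osteoporosis
definition — the lowest available site T-score is compared, the default
schema carrying the neck T-score); impaired bone quality (TBS < 1.20 or
bone strain > 4.06); elevated CTX (> 484.08 pg/dl); positive Romberg.  The
quality/CTX cutoffs default to the published cohort's central statistics
because no consensus cutoffs exist for those instruments; all are
config-overridable.  Classification: **high** = positive Romberg together
with impaired quality (the impaired-balance-plus-fragile-bone state the
mapping analysis singles out); **intermediate** = any criterion triggered
otherwise; **low** = none.  The intermediate tier deliberately covers *one
or more* non-high criteria rather than exactly one: a rule that demoted a
patient with two simultaneous risk criteria to low risk would be clinically
incoherent, and every reported category carries the list of triggered
criteria as its justification.

## What the synthetic tests do and do not show

Passing tests show the pipeline recovers structure that is *planted* under
the generator's assumptions: Gaussian-copula dependence, truncated-normal
marginals, logistic outcomes.  Real cohorts have skewed marginals, nonlinear
and non-monotone dependence, measurement error and missingness, none of
which the generator emulates; the qualitative map-recovery test (the
fracture node lying within two MST steps of the balance or low-BMD nodes at
a fixed seed) is a regression guard for the pipeline's behaviour, not a
reproduction of the study's exact map, which would require the undisclosed
raw data and the original software's constants.

## Problem sizes and runtime

Default analysis runs use the study's n = 125; generator calibration checks
use n = 10,000 draws (sampling error 3·SD/√n per mean, the acceptance
band); the association-ordering check uses n = 2,000; spanning-tree
optimality is enumerated exhaustively on 200 random 5–7-node matrices, the
largest size with a comfortably enumerable tree count (7^5 = 16,807).  The
complete suite and the analysis scripts run in well under a minute on one
CPU.

## Known limitations

- Skew of CTX/BS and the per-record SDI–fracture link are not modelled
  (see above).
- The Auto-CM and MRG constants of the original software are unrecoverable;
  results are reproduced structurally, not numerically.
- Minimum cycle bases are not always unique; in the rare event of ties the
  regular-cycle count R follows the basis the graph library returns (stable
  for a fixed input on a fixed version).
- Edge stability under resampling (bootstrap) is out of scope.
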