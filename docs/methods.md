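# Methods

## Model and problem

A constraint-based model is the triple (S, [**v**ₗ, **v**ᵤ], **w**): an
m × r stoichiometric matrix, flux bounds, and a linear objective (biomass).
FBA solves max **w**·**v** s.t. S**v** = 0, **v**ₗ ≤ **v** ≤ **v**ᵤ. The
sensitivity question is: how much of the variance of the optimal objective Y
is attributable to each intake bound when all of them are uncertain?

Factors are the lower bounds of intake-capable exchange reactions. An
exchange reaction is identified *structurally* — a column of S with exactly
one nonzero entry — rather than by id prefix, which is robust across model
dialects; an id-pattern override exists for models with unconventional
boundary encodings. Intake-capable means lower bound < 0 (uptake flux is
negative by convention). Only lower bounds are perturbed; upper bounds, and
hence secretion capacity, stay as in the source model.

Each factor is uniform on a configurable interval, default [−10, 0] mM/h.
The default reflects the situation where no reference uptake rates are
known: what matters for the optimal flux distribution is largely the
*ratios* between intake capacities, and a common interval samples all
ratios. Units are carried as labels only; no conversion is attempted.

### Baseline-bounds policy

Whether non-factor exchange bounds should be kept at the model's defaults or
closed before analysis is genuinely open (published genome-scale analyses do
not always say). The pipeline exposes both (`keep-model-defaults`, the
default, and `close-all-other-intakes`) and records the choice in the run
manifest rather than asserting one as canonical.

## Sampling design

A base-2 Sobol' sequence in 2D dimensions (scipy's direction numbers,
unscrambled) is split column-wise into blocks A and B of N rows each;
A_B^(i) is A with column i replaced from B. First-order plus total-effect
estimation uses A, B, A_B^(i): N(D+2) rows. The optional second-order scheme
adds B_A^(i), giving N(2D+2). The default is the N(D+2) scheme — it is the
one whose row-count arithmetic matches the genome-scale run sizes this
workflow targets — and the manifest records which scheme ran.

The first Sobol' point is the all-zeros vector, which after scaling pins
every factor to its most negative bound; it is skipped by default
(`skip=1`), and the skip count is part of the design's identity (generation
is bit-for-bit reproducible from (N, D, scheme, skip)). N need not be a
power of two, but a warning is emitted otherwise because the sequence's
dyadic balance properties degrade.

## Estimators

With f_A, f_B, f_ABi the outputs over the blocks and
V = Var(Y over A ∪ B):

- first order (Saltelli-2010 cross-block): Sᵢ = mean(f_B·(f_ABi − f_A))/V
- total effect (Jansen): S_Tᵢ = mean((f_A − f_ABi)²)/(2V)
- second order (when B_A blocks exist):
  Sᵢⱼ = mean(f_BAi·f_ABj − f_A·f_B)/V − Sᵢ − Sⱼ

These are the default estimator forms of the standard SA libraries, chosen
for comparability. Estimates are reported unclipped — Monte-Carlo noise can
push them slightly outside [0, 1] — and the result flags factors outside by
more than their CI half-width. A constant output raises a degenerate-output
error naming the constant, since the ratio is undefined.

Confidence intervals: the N base samples are resampled with replacement
`n_boot` times (default 100); a base sample's A, B and A_B^(i) rows move
*together*, because resampling rows independently would break the pairing
the estimators depend on. The half-width is z·sd of the bootstrap
distribution at the 95 % level. Rankings sort by descending index with
lexicographic tie-break for reproducibility.

## Execution

Design rows are independent LPs, so evaluation is a static sweep: contiguous
row chunks per worker (FBA cost does not depend on bound values, so there is
nothing for dynamic scheduling to balance), results reassembled by position.
Serial and process-pool backends are bitwise identical at any worker count
because each row is solved by the same code on the same inputs. A
message-passing backend is a plug-in contract only. Workers hot-swap lower
bounds into a single model copy instead of rebuilding the LP. A JSON
checkpoint of completed chunks enables resume; `max_batch_size` computes how
many rows fit in a memory budget (floor(mem/(D·bytes·overhead))).

Non-optimal rows (infeasible/unbounded) are imputed as Y = 0 under the
default `zero` failure policy — zero growth is the natural reading of an
infeasible growth problem — with the count reported in the manifest; an
`abort` policy is available.

The LP backend is a one-function contract; the default is HiGHS via
scipy.optimize.linprog with a mass-balance residual check at 10·tol
(tol = 1e-9). Alternate optima are not resolved (no pFBA/FVA): only the
objective value, which is unique, enters Y.

## Morris screening

r random OAT trajectories on a p-level grid (default p = 4,
Δ = p/(2(p−1)) = 2/3 on the unit scale — the common convention), r(D+1) model
runs. μ*ᵢ is the mean absolute elementary effect, σᵢ their standard
deviation (ddof = 1 across trajectories). Plain random trajectories are
used, not the optimized-spread variant. σ = 0 identifies purely additive
linear responses exactly (up to float roundoff ~1e-15); σ exceeding μ*
signals that a factor's effect depends strongly on where it is measured.
Trajectory-bootstrap CIs for μ* are available.

## Single-flux perturbation

The naive local comparator: for each factor alone, the intake magnitude
|lb| is scaled down by a fraction (1.0 = depletion, 0.5 = half capacity),
the LP is re-solved, and the relative growth reduction (f₀ − f)/f₀ is
reported. The table carries both the raw 50 % reduction and the same value
normalized by the 0.5 perturbation size (the per-unit response comparable
with the 100 % point), since either normalization is defensible when
checking bisector (region-invariance) behaviour. Reductions lie in [0, 1]
whenever the baseline optimum is positive, by LP monotonicity under bound
tightening; a non-positive baseline raises an error rather than returning
undefined ratios.

## Synthetic fixtures and what they show

- *Linear chain* (yields y): optimum Σ yᵢ|lbᵢ| — additive, so
  Sᵢ = S_Tᵢ = yᵢ²/Σyⱼ² exactly.
- *Min-coupled*: optimum min(|lb_A|, |lb_B|) — S₁ = S₂ = 0.4,
  S_T = 0.6, gap 0.2 (derived from E[min|X=x] = x − x²/2; Var[E] = 1/45,
  Var(Y) = 1/18).
- *Random small models* (r ≤ 12, finite bounds, 0 always feasible): LP
  correctness is certified against brute-force vertex enumeration.
- Analytic test functions (additive, min, centered product (x₁−½)(x₂−½))
  evaluate the same estimators without the LP in the loop, isolating
  estimator defects from solver defects.

These fixtures have exactly known sensitivity structure but tiny, dense,
noise-free stoichiometry; passing on them validates the estimators,
executor and LP engine, not the biological behaviour of genome-scale
reconstructions, whose degeneracy (alternate optima plateaus) and scale are
not emulated. Genome-wide runs are supported by the same code paths but are
multi-day jobs outside the test suite.

## Numerical choices and problem sizes

Fixture analyses use N = 1024 (4096 LPs at D = 2), where Monte-Carlo error
of the indices is comfortably below the 0.05 tolerance the tests assert;
bootstrap uses 100 resamples at the 95 % level; the vertex-enumeration
cross-check runs 25 seeded 5×8 models at 1e-6 agreement. Ties in rankings
break lexicographically; designs, bootstraps, trajectories and random
models are all seeded and bit-reproducible.

## Known limitations

- Alternate FBA optima make the flux *vector* non-unique; only the objective
  is analyzed.
- The unscrambled Sobol' sequence gives no internal error estimate;
  uncertainty comes from the bootstrap only.
- Second-order indices are noisy at moderate N and are off by default.
- Gene–protein–reaction rules, compartment semantics and model curation are
  out of scope; models are taken as given.
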