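# fluxsens

Variance-based global sensitivity analysis of nutrient-uptake bounds in
constraint-based metabolic models.

## The problem

Flux balance analysis (FBA) predicts an optimal flux distribution by solving
the linear program

> maximize **w**·**v**  subject to  S·**v** = 0,  **v**ₗ ≤ **v** ≤ **v**ᵤ,

where S is the m × r stoichiometric matrix, **v** the reaction fluxes and
**w** the (biomass) objective coefficients. For genome-scale human
reconstructions the model exchanges more than a thousand nutrients with the
environment, and the lower bounds of those exchange reactions — how fast each
nutrient may be taken up — are rarely known experimentally. Which of them
actually matter for predicted growth?

`fluxsens` answers this with Sobol' variance decomposition: every
intake-capable exchange lower bound is treated as an uncertain factor on an
interval (default [−10, 0] mM/h), the model is solved for a Saltelli
cross-sampling design of bound assignments, and each factor i receives

- a first-order index Sᵢ = Var[E(Y|Xᵢ)]/Var(Y) — the share of output variance
  explained by that bound alone, and
- a total-effect index S_Tᵢ = 1 − Var[E(Y|X₋ᵢ)]/Var(Y) — its share including
  all interactions,

with 95 % bootstrap confidence intervals and a factor ranking. The gap
S_Tᵢ − Sᵢ quantifies interaction/nonlinearity per factor. Morris
elementary-effects screening (μ*, σ) and single-flux 100 %/50 % perturbation
analyses are included as cheaper/naiver comparators. Evaluation of the
design — one independent FBA per row — parallelizes embarrassingly; a
process-pool backend with deterministic result ordering and
checkpoint/resume is built in, and the design arithmetic (N(D+2) rows for
first+total indices, N(2D+2) with second-order blocks) scales to
genome-wide runs in the tens of millions of LPs.

Audience: systems-biology modellers working with COBRA-style JSON or SBML
(FBC) models who need to know which medium-composition bounds their
predictions are sensitive to.

## Worked example

Generate a toy model whose growth is `min(|lb_A|, |lb_B|)` — two nutrients
consumed 1:1, a controlled interaction instance — and analyze it:

```sh
fluxsens fixtures --kind min-coupled --out mc.json
fluxsens gsa --model mc.json --out gsa_out --n 1024 --seed 1
```

which prints `gsa: N=1024 D=2 rows=4096 imputed=0 -> gsa_out` and writes
`sobol_indices.tsv`:

| factor | S1 | S1_conf | ST | ST_conf | rank_total |
|--------|------|---------|------|---------|------------|
| EX_A | 0.397 | 0.110 | 0.604 | 0.062 | 2 |
| EX_B | 0.398 | 0.115 | 0.604 | 0.068 | 1 |

For this model the indices are known analytically: S₁ = S₂ = 0.4 and
S_T1 = S_T2 = 0.6 (on the unit scale E[min|Xᵢ=x] = x − x²/2, so
Var[E(Y|Xᵢ)] = 1/45 against Var(Y) = 1/18). The estimates at N = 1024 land
within Monte-Carlo noise of both, and the interaction-gap table reports
S_Tᵢ − Sᵢ ≈ 0.206 per factor against the analytic 0.2 — the signature of the
min-coupling that no single-factor (local) analysis can see. A
`manifest.json` records every defaulted decision (scheme, skip policy,
solver, bootstrap count) so the run is reproducible from its outputs.

Subcommands `morris` and `perturb` run the comparator analyses on the same
models; `fixtures` also emits additive linear-chain and random small models.

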