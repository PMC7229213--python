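# Methods

This note documents the models, numerical choices and limitations of the
`netgs` package: constraint-based estimation of steady-state metabolic
fluxes, per-reaction genomic prediction, and the projection of predicted
flux breeding values back onto the flux polytope to obtain a growth
prediction.

## Constraint-based flux estimation

All flux programs share the constraint family

    N v = 0                      (steady state)
    alpha_i <= v_i <= beta_i     (capacities; -1000/1000 reversible, 0/1000 irreversible)
    ratio constraints on RuBisCO carboxylation/oxygenation and
    starch/sucrose synthesis

The **reference distribution** maximizes the biomass flux with the ratios
fixed at the measured values 2.88 (carboxylation:oxygenation) and 2.58
(starch:sucrose).  All **genotype-specific** programs relax the ratios to
the intervals [0.94, 3.81] and [0.79, 3.37], reflecting genotype and
photoperiod variability around the reference values.

Genotype fluxes, environment transfer and the robustness analysis are all
reciprocal-weighted projections: minimize
`sum_{i in R!=0} ((t_i - v_i)/t_i)^2` over a target vector `t` (the
reference distribution, a sampled perturbation of it, or the flux GEBVs),
where `R!=0` is the set of reactions with non-zero target.  The reciprocal
weighting makes the objective scale free — each reaction contributes its
*relative* deviation — and restricting to `R!=0` encodes the assumption
that genetic variants modulate the magnitude of active reactions rather
than unblocking inactive ones.

Key parameters:

| parameter | default | meaning |
|---|---|---|
| zero-flux tolerance | 1e-9 | membership of `R!=0`; reciprocal weights are numerically meaningless below it |
| `eps_band` | 0.05 | relative half-width of the biomass-flux equality band in the genotype and transfer programs |
| `delta` | 1.1e-4 | offset keeping the top-ranked genotype strictly below the average model optimum |
| ratio slack `eps` (robustness) | 1e-4 | two-sided slack on the fixed-ratio equalities |
| exchange band `eps` (transfer) | 0.05 | relative half-width of the exchange-ratio bands |

**Biomass scaling.** Measured fresh weights are mapped into the model's
feasible range in two steps: per-genotype ratio targets
`v_bio_Z = (M_Z/M_ref) * v_bio_ref` are rescaled by
`(s_model - delta)/s_measurement`, where `s_model` is the mean of the
genotype-specific biomass maxima (computed with interval ratios and
non-negative carboxylation) and `s_measurement` is the largest ratio
target.  The genotype with the largest fresh weight is therefore asked to
grow just below the average model optimum, and everyone else
proportionally less.

**Band feasibility.** The equality bands exist to keep the feasible set
non-empty.  When a band is infeasible the solver widens it multiplicatively
(x2, at most three times, each widening logged) before failing hard.  The
same policy applies to the biomass band, and to the exchange-ratio bands in
the cross-environment projection, where several simultaneously-banded
exchanges can conflict on small networks whose exchanges are
stoichiometrically pinned to biomass.

**Reactions outside `R!=0`** carry no objective weight and remain free
variables of the QP (constrained only by steady state and bounds); a
`pin_zero` switch fixes them to zero instead.  For solution uniqueness the
free variables receive a tiny ridge (1e-10), acting as a minimal-norm
tie-break among otherwise equivalent optima.

**Solvers.** LPs (FBA, pFBA, FVA, biomass maxima, phase-1 feasibility) use
HiGHS through `scipy.optimize.linprog`, which is deterministic for a fixed
input.  The QPs have diagonal positive-semidefinite Hessians and are solved
by a dense primal active-set method with exact KKT solves, warm-started
from the target when feasible; `scipy`'s `trust-constr` is the fallback on
the rare singular or cycling case.  The test suite checks both solvers
against brute-force oracles (vertex enumeration for LPs, active-set
enumeration with dense KKT solves for QPs) to 1e-6 relative on randomized
small networks.

**Alternate optima.** FBA solutions need not be unique.  The package
provides flux variability analysis at the pinned optimum and a pFBA mode
(secondary minimization of total absolute flux at the optimum, via a split
variable LP) for when uniqueness matters.  On the minimal study network the
reference distribution is fully determined (FVA ranges are degenerate).

**Robustness analysis.** Per sample, each active reference flux is
perturbed uniformly within `v_i * (1 +/- e)` and projected back onto the
constraint set with the fixed ratios (two-sided slack) and the biomass flux
pinned; the element-wise mean over samples (default 50) replaces the
reference.  The sampling distribution is uniform on the stated interval —
the natural choice absent further information — and the seed is a mandatory
argument, as for every stochastic operation in the package.

## Genomic prediction (rrBLUP)

Traits (fluxes or fresh weight) are modeled as
`y = X b + Z u + e`, `u ~ N(0, sigma_u^2 I)`, with `Z` the column-centered
dosage matrix and `X` an intercept plus optional covariates (first ten
genotype PCs are the conventional choice; default is intercept-only with
PCs opt-in).  The variance ratio is estimated by profiled REML through one
eigendecomposition of `Z Z'` restricted to the complement of `X` — exact
and fast in the n << p regime of breeding panels.  Dosages are coded
{0, 1, 2}; missing calls are mean-imputed per marker (with a warning);
markers below 5% minor allele frequency and constant columns are removed.

Flux columns that are constant across the panel (fluxes fully determined by
stoichiometry, common on toy networks) cannot be modeled; they are recorded
as constants and re-enter the projection objective as fixed targets.

**Accuracy-based model selection.** Per-reaction cross-validated accuracies
can be recorded, and the projection restricted to reactions whose flux
model beats a threshold (conventionally the classical-GS fresh-weight
accuracy).  Exchange reactions in the transfer set **P** always keep their
GEBV, independent of this selection, because the transfer constraint needs
a value for them.

## Projection to growth

The growth GEBV of a genotype is the biomass entry of the closest
steady-state distribution to its flux GEBVs.  The biomass flux enters only
through the constraint `w_bio >= 0`, never the objective — growth is read
off the network fit, not predicted directly.  GEBVs below the zero-flux
tolerance are dropped from the objective (their reciprocal weight is
meaningless); negative GEBVs for irreversible reactions are left to the
bounds to clip.

## Cross-validation

Prediction accuracy is the Pearson correlation between measured fresh
weight and predicted growth on held-out accessions, aggregated over
repeated balanced k-fold cross-validation (3 folds x 50 repeats = 150
evaluations by default; fold assignment by shuffled round-robin,
reproducible by seed).  Degenerate evaluations (constant predictions) are
recorded as missing and excluded from the mean, with the count reported.

Genotype-specific flux estimation is performed once on the full panel
before cross-validation ("paper" leakage mode): the held-out accessions'
*fluxes* derive from their measured phenotypes, but the statistical models
never see held-out rows.  A strict mode — re-estimating scaling and fluxes
per training fold — can be assembled from the same primitives
(`estimate_panel_fluxes` on the training subset); the default follows the
conventional usage.

## Synthetic study design

The generator produces the conditions the pipeline assumes rather than a
replica of any real panel:

- **Networks.**  The `minimal` network (8 reactions, checked in as a
  fixture) is fully hand-checkable: photon/CO2/NO3 imports, a
  carboxylation/oxygenation pair differing in carbon yield, starch and
  sucrose synthesis, and a biomass reaction consuming starch, sucrose and
  nitrogen.  Its reference composition keeps starch:sucrose at exactly
  2.58 so the fixed-ratio reference program is feasible.  `standard`
  networks (20–40 reactions, seeded) extend the skeleton with random
  conversions and chains that conserve a positive metabolite mass
  function, so the extension cannot create matter; they guarantee all four
  ratio tags, at least four exchanges and a positive biomass optimum.
- **Panel.** 200 accessions x 500 markers by default; allele frequencies
  uniform on [0.1, 0.9] (keeping MAF filtering non-trivial), i.i.d.
  binomial dosages, 40 QTL with Gaussian effects.  Fresh weight and the
  variable biomass components (starch, sucrose, one nitrogen pool) are
  latent traits mixing the standardized genetic value with Gaussian noise
  at heritabilities 0.8 (growth) and 0.6 (composition); coefficients of
  variation 15% (fresh weight) and 8% (composition).  Two environments
  differ by a biomass scale (0.6 for E2) and a composition shift.
- **Genetic coupling.** Half of the growth genetic variance
  (`genetic_overlap = 0.5`) is routed through the negated sum of the
  composition genetic values: heavier biomass demand per gram of dry
  weight means less growth per unit of fixed carbon.  This mirrors the
  causal structure the method itself assumes — growth is produced from
  composition through the network.  With fully independent growth and
  composition genetics the flux phenotypes would be diluted by
  growth-orthogonal composition signal and network-based prediction could
  only trail the direct model; such panels can still be generated by
  setting `genetic_overlap = 0`.
- **Ground-truth fluxes** are produced by running the package's own
  genotype flux estimation on the generated compositions and fresh
  weights, so parameter-recovery tests exercise exactly the pipeline path.
  Accessions whose composition draw makes the estimation infeasible are
  resampled (bounded retries); the starch:sucrose coefficient ratio is
  clipped to [0.90, 3.30] to stay inside the interval constraint.

What the generator does **not** emulate: linkage disequilibrium, population
structure, dominance/epistasis, genotype-environment interaction beyond
scale/shift, measurement error structure of metabolite assays.  Passing
tests therefore demonstrate internal consistency of the method under its
own assumptions, not performance on real panels.

## Numerical conventions

- Steady-state tolerance 1e-6 (max-norm of `N v`); every emitted flux
  distribution is checked against it.
- Flux tables serialize at full double precision (`repr`), so write/read
  round trips are exact.
- Exchange reactions touch exactly one metabolite; imports are written
  `-> A` and carry positive flux, matching the sign convention in which
  reported import fluxes are positive.
- Biomass compositions are stored in umol gDW^-1 (consumed precursors
  negative) and scaled to mmol when substituted into the stoichiometric
  matrix, consistent with fluxes in mmol gDW^-1 d^-1.
- The coefficient of variation of a flux across accessions is sd/|mean|,
  flagged undefined when the mean is within 1e-9 of zero.
- The Mantel statistic is the Pearson correlation of upper-triangle
  entries with a joint row/column permutation test; similarity matrices
  are accepted as-is (no hollowness requirement).

## Known limitations

- The active-set QP solver targets the small dense programs of this
  pipeline; genome-scale models (hundreds of reactions) work but would
  benefit from a sparse factorization it does not implement.
- The "90% confidence interval" construction of the biomass band is
  implemented as a symmetric relative band (+/-5% by default,
  configurable); alternative readings (e.g. a per-genotype interval from
  measurement replicates) can be expressed through `eps_band`.
- `run_cv` defaults to the "paper" leakage mode described above; results
  in strict mode will generally be lower.
- Gene-protein-reaction rules, compartmented multi-tissue models,
  thermodynamic/loopless constraints and Bayesian-alphabet prediction
  models are out of scope.
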