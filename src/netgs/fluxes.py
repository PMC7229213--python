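"""Constraint-based estimation of reference and genotype-specific fluxes.

The reference flux distribution is obtained by FBA: biomass flux is maximized
subject to steady state, flux bounds and fixed flux ratios for RuBisCO
carboxylation/oxygenation (2.88) and starch/sucrose synthesis (2.58).  A
parsimonious variant (pFBA) and a flux-variability check at the optimum are
provided to diagnose alternate optima.

Genotype-specific fluxes are the solution of a quadratic program that
minimizes the reciprocal-weighted squared distance to the reference over the
reactions with non-zero reference flux, subject to steady state, bounds,
interval ratio constraints, the genotype's own biomass column, and a band
constraint tying the genotype biomass flux to the ratio of measured fresh
weights (after a model/measurement rescaling that keeps every genotype's
target inside the feasible range of the model).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._solvers import LinearSystem, solve_lp, solve_qp
from .errors import InfeasibleError, ValidationError
from .model import FluxDistribution, MetabolicModel, RatioConstraints

logger = logging.getLogger(__name__)

#: reactions with |flux| below this are treated as zero (outside R!=0);
#: reciprocal weights 1/v**2 are numerically meaningless below it
ZERO_FLUX_TOL = 1e-9

STEADY_STATE_TOL = 1e-6


@dataclass
class ScalingScheme:
    """Model/measurement scaling for genotype biomass targets.

    ``s_model`` is the mean of the genotype biomass maxima, ``s_measurement``
    the largest ratio-scaled biomass over genotypes; the target biomass flux
    of genotype Z is ``(s_model - delta) / s_measurement * (M_Z/M_ref) *
    v_bio_ref``, so the most vigorous genotype is asked to grow just below
    the average model optimum.  ``epsilon_mode`` is the relative half-width
    of the biomass equality band in the quadratic programs.
    """

    s_model: float
    s_measurement: float
    delta: float = 1.1e-4
    epsilon_mode: float = 0.05
    ratio_biomass: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.s_model > self.delta >= 0):
            raise ValidationError(f"need s_model > delta >= 0, got {self.s_model}, {self.delta}")
        if self.s_measurement <= 0:
            raise ValidationError("s_measurement must be positive")
        if not (0 < self.epsilon_mode < 1):
            raise ValidationError("epsilon_mode must be in (0, 1)")

    def scaled_target(self, genotype: str) -> float:
        """Scaled biomass-flux target for one genotype."""
        return (self.s_model - self.delta) / self.s_measurement * self.ratio_biomass[genotype]


@dataclass
class RobustnessConfig:
    """Settings for the reference-perturbation robustness analysis."""

    e: float = 0.05  # relative half-width of the per-reaction sampling interval
    n_samples: int = 50
    eps: float = 1e-4  # slack on the fixed-ratio equalities
    seed: int = 0

    def __post_init__(self):
        if self.e < 0:
            raise ValidationError("variance percentage e must be >= 0")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")


# ----------------------------------------------------------------------
# Constraint assembly
# ----------------------------------------------------------------------

def _tag_pair(model: MetabolicModel, tag_a: str, tag_b: str):
    ia, ib = model.tag_index(tag_a), model.tag_index(tag_b)
    if ia is None or ib is None:
        warnings.warn(
            f"model {model.model_id!r} lacks {tag_a}/{tag_b} tags; "
            "skipping that ratio constraint",
            stacklevel=3,
        )
        return None
    return ia, ib


def constraint_system(
    model: MetabolicModel,
    ratios: RatioConstraints | None,
    ratio_slack: float | None = None,
) -> LinearSystem:
    """Steady state + bounds + ratio constraints as a LinearSystem.

    Fixed ratios become equality rows ``v_a - r v_b = 0`` (or a two-sided
    slack band when ``ratio_slack`` is given); interval ratios become the
    pair of one-sided rows ``low v_b <= v_a <= high v_b``.
    """
    n = model.n_reactions
    system = LinearSystem(
        n, A_eq=model.S.copy(), b_eq=np.zeros(model.n_metabolites),
        lb=model.lb.copy(), ub=model.ub.copy(),
    )
    if ratios is None:
        return system
    eq_rows, eq_rhs, ub_rows, ub_rhs = [], [], [], []
    for (tag_a, tag_b), ratio in (
        (("carboxylation", "oxygenation"), ratios.carb_oxy),
        (("starch_synthesis", "sucrose_synthesis"), ratios.starch_sucrose),
    ):
        pair = _tag_pair(model, tag_a, tag_b)
        if pair is None:
            continue
        ia, ib = pair
        if isinstance(ratio, tuple):
            low, high = ratio
            row_low = np.zeros(n)
            row_low[ia], row_low[ib] = -1.0, low
            row_high = np.zeros(n)
            row_high[ia], row_high[ib] = 1.0, -high
            ub_rows += [row_low, row_high]
            ub_rhs += [0.0, 0.0]
        else:
            row = np.zeros(n)
            row[ia], row[ib] = 1.0, -float(ratio)
            if ratio_slack is None:
                eq_rows.append(row)
                eq_rhs.append(0.0)
            else:
                ub_rows += [row, -row]
                ub_rhs += [ratio_slack, ratio_slack]
    return system.with_rows(
        A_eq_extra=np.array(eq_rows) if eq_rows else None,
        b_eq_extra=np.array(eq_rhs) if eq_rhs else None,
        A_ub_extra=np.array(ub_rows) if ub_rows else None,
        b_ub_extra=np.array(ub_rhs) if ub_rhs else None,
    )


def _check_distribution(model: MetabolicModel, v: np.ndarray, context: str) -> None:
    resid = float(np.max(np.abs(model.S @ v)))
    if resid > STEADY_STATE_TOL:
        raise InfeasibleError(
            f"{context}: steady-state residual {resid:.2e} exceeds {STEADY_STATE_TOL}",
            constraint_group="steady_state",
        )


# ----------------------------------------------------------------------
# Reference estimation
# ----------------------------------------------------------------------

def solve_reference_fba(
    model: MetabolicModel, ratios: RatioConstraints | None = None
) -> FluxDistribution:
    """Maximize biomass flux under steady state, bounds and fixed flux ratios."""
    if ratios is None:
        ratios = RatioConstraints.fixed()
    if not ratios.is_fixed:
        raise ValidationError("reference FBA requires fixed-valued ratio constraints")
    system = constraint_system(model, ratios)
    c = np.zeros(model.n_reactions)
    c[model.biomass_index] = 1.0
    x, obj = solve_lp(c, system, sense="max", context=f"reference FBA on {model.model_id!r}")
    _check_distribution(model, x, "reference FBA")
    return FluxDistribution(
        x, model_ref=model.model_id, label="reference_fba",
        reaction_ids=model.reaction_ids, objective=obj,
    )


def solve_reference_pfba(
    model: MetabolicModel, ratios: RatioConstraints | None = None
) -> FluxDistribution:
    """FBA optimum first, then minimize total absolute flux at that optimum."""
    ref = solve_reference_fba(model, ratios)
    v_bio = ref.objective
    n = model.n_reactions
    base = constraint_system(model, ratios if ratios is not None else RatioConstraints.fixed())
    # extended variables [v, t] with |v_i| <= t_i
    n2 = 2 * n
    A_eq = np.hstack([base.A_eq, np.zeros((base.A_eq.shape[0], n))])
    pin = np.zeros(n2)
    pin[model.biomass_index] = 1.0
    A_eq = np.vstack([A_eq, pin])
    b_eq = np.concatenate([base.b_eq, [v_bio]])
    ub_rows = [np.hstack([base.A_ub, np.zeros((base.A_ub.shape[0], n))])] if base.A_ub is not None else []
    ub_rhs = [base.b_ub] if base.b_ub is not None else []
    eye = np.eye(n)
    ub_rows.append(np.hstack([eye, -eye]))       # v - t <= 0
    ub_rows.append(np.hstack([-eye, -eye]))      # -v - t <= 0
    ub_rhs += [np.zeros(n), np.zeros(n)]
    big = np.maximum(np.abs(base.lb), np.abs(base.ub))
    system = LinearSystem(
        n2,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=np.vstack(ub_rows),
        b_ub=np.concatenate(ub_rhs),
        lb=np.concatenate([base.lb, np.zeros(n)]),
        ub=np.concatenate([base.ub, big]),
    )
    c = np.concatenate([np.zeros(n), np.ones(n)])
    x, _ = solve_lp(c, system, sense="min", context=f"pFBA on {model.model_id!r}")
    v = x[:n]
    _check_distribution(model, v, "pFBA")
    return FluxDistribution(
        v, model_ref=model.model_id, label="reference_pfba",
        reaction_ids=model.reaction_ids, objective=float(v_bio),
    )


def flux_variability_at_optimum(
    model: MetabolicModel,
    ratios: RatioConstraints | None,
    v_ref: FluxDistribution,
    reactions: list[str] | None = None,
) -> pd.DataFrame:
    """Per-reaction [min, max] flux with biomass pinned to the reference value."""
    system = constraint_system(model, ratios if ratios is not None else RatioConstraints.fixed())
    v_bio = v_ref.biomass_flux(model)
    system.lb[model.biomass_index] = v_bio
    system.ub[model.biomass_index] = v_bio
    rids = reactions if reactions is not None else model.reaction_ids
    rows = []
    for rid in rids:
        j = model.reaction_index(rid)
        c = np.zeros(model.n_reactions)
        c[j] = 1.0
        _, lo = solve_lp(c, system, sense="min", context=f"FVA min {rid}")
        _, hi = solve_lp(c, system, sense="max", context=f"FVA max {rid}")
        rows.append({"reaction_id": rid, "min": lo, "max": hi})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Genotype estimation
# ----------------------------------------------------------------------

def max_genotype_biomass(
    model_Z: MetabolicModel, ratios: RatioConstraints | None = None
) -> float:
    """Maximum biomass flux of a genotype model under interval ratio constraints.

    Carboxylation flux is additionally required to be non-negative.
    """
    if ratios is None:
        ratios = RatioConstraints.interval()
    system = constraint_system(model_Z, ratios)
    icarb = model_Z.tag_index("carboxylation")
    if icarb is not None:
        system.lb[icarb] = max(system.lb[icarb], 0.0)
    c = np.zeros(model_Z.n_reactions)
    c[model_Z.biomass_index] = 1.0
    _, obj = solve_lp(c, system, sense="max", context=f"biomass max on {model_Z.model_id!r}")
    return obj


def build_scaling(
    maxima: dict[str, float],
    measured: dict[str, float],
    M_ref: float,
    v_bio_ref: float,
    delta: float = 1.1e-4,
    epsilon_mode: float = 0.05,
) -> ScalingScheme:
    """Build the model/measurement scaling from genotype maxima and fresh weights."""
    if not maxima or set(maxima) != set(measured):
        raise ValidationError("maxima and measured fresh weights must cover the same genotypes")
    if M_ref <= 0:
        raise ValidationError("reference fresh weight must be positive")
    bad = [g for g, m in measured.items() if m <= 0]
    if bad:
        raise ValidationError(f"non-positive fresh weight for genotypes {bad}")
    ratio_biomass = {g: (m / M_ref) * v_bio_ref for g, m in measured.items()}
    return ScalingScheme(
        s_model=float(np.mean(list(maxima.values()))),
        s_measurement=float(max(ratio_biomass.values())),
        delta=delta,
        epsilon_mode=epsilon_mode,
        ratio_biomass=ratio_biomass,
    )


def _reciprocal_objective(reference: np.ndarray, n: int, support: np.ndarray):
    H = np.zeros(n)
    c = np.zeros(n)
    H[support] = 2.0 / reference[support] ** 2
    c[support] = -2.0 / reference[support]
    return H, c


def _weighted_distance(v: np.ndarray, reference: np.ndarray, support: np.ndarray) -> float:
    return float(np.sum(((reference[support] - v[support]) / reference[support]) ** 2))


def _solve_band_qp(
    model: MetabolicModel,
    system: LinearSystem,
    reference: np.ndarray,
    support: np.ndarray,
    target: float,
    eps_band: float,
    label: str,
    pin_zero: bool,
    max_widenings: int = 3,
) -> tuple[np.ndarray, float, float]:
    """Solve a reciprocal-weighted projection with a biomass band, widening on demand."""
    n = model.n_reactions
    H, c = _reciprocal_objective(reference, n, support)
    if pin_zero:
        outside = np.setdiff1d(np.arange(n), support)
        rows = np.eye(n)[outside]
        system = system.with_rows(A_eq_extra=rows, b_eq_extra=np.zeros(len(outside)))
    eps = eps_band
    for attempt in range(max_widenings + 1):
        trial = system.with_rows()
        lo, hi = sorted((target * (1 - eps), target * (1 + eps)))
        trial.lb[model.biomass_index] = max(trial.lb[model.biomass_index], lo)
        trial.ub[model.biomass_index] = min(trial.ub[model.biomass_index], hi)
        try:
            x, _ = solve_qp(H, c, trial, x0=reference, context=label)
            return x, _weighted_distance(x, reference, support), eps
        except InfeasibleError:
            if attempt == max_widenings:
                raise InfeasibleError(
                    f"{label}: infeasible even after widening the biomass band to "
                    f"+/-{eps:.3g} (target {target:.4g})",
                    constraint_group="biomass_band",
                ) from None
            eps *= 2.0
            logger.warning("%s: biomass band infeasible, widening to +/-%.3g", label, eps)


def estimate_genotype_flux(
    model_Z: MetabolicModel,
    v_ref: FluxDistribution,
    scaled_target: float,
    ratios: RatioConstraints | None = None,
    eps_band: float = 0.05,
    pin_zero: bool = False,
) -> FluxDistribution:
    """Closest steady-state flux distribution of genotype Z to the reference.

    Minimizes ``sum_{i in R!=0} ((v_ref_i - v_i)/v_ref_i)**2`` subject to
    steady state, bounds, interval ratio constraints and a biomass flux within
    ``scaled_target * (1 +/- eps_band)``.  Reactions outside the reference
    support carry no objective weight and are left free unless ``pin_zero``.
    """
    if ratios is None:
        ratios = RatioConstraints.interval()
    support = v_ref.nonzero_support(ZERO_FLUX_TOL)
    if len(support) == 0:
        raise ValidationError("reference flux distribution has empty support")
    system = constraint_system(model_Z, ratios)
    x, dist, eps_used = _solve_band_qp(
        model_Z, system, v_ref.values, support, scaled_target, eps_band,
        label=f"genotype flux for {model_Z.model_id!r}", pin_zero=pin_zero,
    )
    _check_distribution(model_Z, x, "genotype flux estimation")
    return FluxDistribution(
        x, model_ref=model_Z.model_id, label=f"genotype(eps={eps_used:g})",
        reaction_ids=model_Z.reaction_ids, objective=dist,
    )


def estimate_panel_fluxes(
    model: MetabolicModel,
    compositions: dict[str, "BiomassComposition"],
    fresh_weights: dict[str, float],
    M_ref: float,
    v_ref: FluxDistribution,
    ratios: RatioConstraints | None = None,
    eps_band: float = 0.05,
    delta: float = 1.1e-4,
) -> tuple[pd.DataFrame, ScalingScheme]:
    """Estimate fluxes for a panel of genotypes (the per-accession pipeline).

    Returns an accessions x reactions flux table and the scaling scheme used.
    """
    from .model import set_biomass  # local import to avoid cycle in type hints

    if ratios is None:
        ratios = RatioConstraints.interval()
    models = {g: set_biomass(model, comp) for g, comp in compositions.items()}
    maxima = {g: max_genotype_biomass(m, ratios) for g, m in models.items()}
    scaling = build_scaling(
        maxima, fresh_weights, M_ref, v_ref.biomass_flux(model),
        delta=delta, epsilon_mode=eps_band,
    )
    rows = {}
    for g, m in models.items():
        flux = estimate_genotype_flux(
            m, v_ref, scaling.scaled_target(g), ratios, eps_band=eps_band
        )
        rows[g] = flux.values
    table = pd.DataFrame.from_dict(rows, orient="index", columns=model.reaction_ids)
    return table, scaling


# ----------------------------------------------------------------------
# Robustness of the reference
# ----------------------------------------------------------------------

def robust_reference(
    model: MetabolicModel,
    v_ref: FluxDistribution,
    cfg: RobustnessConfig,
    ratios: RatioConstraints | None = None,
) -> tuple[FluxDistribution, list[FluxDistribution]]:
    """Mean of steady-state projections of perturbed reference distributions.

    Each sample draws, for every reaction in the reference support, a value
    uniformly from ``v_i * (1 +/- e)`` and projects the sampled vector back
    onto the constraint set with the fixed ratios (two-sided slack ``eps``)
    and the biomass flux pinned to the reference value.
    """
    if ratios is None:
        ratios = RatioConstraints.fixed()
    rng = np.random.default_rng(cfg.seed)
    support = v_ref.nonzero_support(ZERO_FLUX_TOL)
    v_bio = v_ref.biomass_flux(model)
    base = constraint_system(model, ratios, ratio_slack=cfg.eps)
    base.lb[model.biomass_index] = v_bio
    base.ub[model.biomass_index] = v_bio
    n = model.n_reactions
    samples = []
    for r in range(cfg.n_samples):
        v_r = v_ref.values.copy()
        u = rng.uniform(-1.0, 1.0, size=len(support))
        v_r[support] = v_ref.values[support] * (1.0 + cfg.e * u)
        H, c = _reciprocal_objective(v_r, n, support)
        x, _ = solve_qp(H, c, base.with_rows(), x0=v_ref.values, context=f"robust sample {r}")
        _check_distribution(model, x, f"robust sample {r}")
        samples.append(
            FluxDistribution(
                x, model_ref=model.model_id, label=f"robust_sample_{r}",
                reaction_ids=model.reaction_ids,
                objective=_weighted_distance(x, v_r, support),
            )
        )
    mean = np.mean([s.values for s in samples], axis=0)
    mean_dist = FluxDistribution(
        mean, model_ref=model.model_id, label="robust_mean",
        reaction_ids=model.reaction_ids,
    )
    return mean_dist, samples
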