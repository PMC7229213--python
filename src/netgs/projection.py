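"""The netGS step: project predicted flux GEBVs onto the steady-state polytope.

Per-reaction GEBVs from the flux models need not satisfy mass balance.  The
growth prediction for a genotype is obtained by finding the closest
steady-state flux distribution to the GEBV vector under reciprocal weighting,
with the genotype's biomass column in place and the biomass flux constrained
only to be non-negative; the biomass entry of the projection is the growth
GEBV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._solvers import solve_qp
from .errors import InfeasibleError, ValidationError
from .fluxes import (
    ZERO_FLUX_TOL,
    _reciprocal_objective,
    _weighted_distance,
    constraint_system,
)
from .gs import FluxModelSet, GenotypeMatrix, predict_gebv
from .model import FluxDistribution, MetabolicModel, RatioConstraints

logger = logging.getLogger(__name__)


@dataclass
class ProjectionResult:
    """Outcome of one steady-state projection."""

    w: FluxDistribution
    growth_gebv: float
    objective: float
    retained_reactions: set[str] = field(default_factory=set)
    solver_status: str = "optimal"

    def __post_init__(self):
        if self.growth_gebv < -1e-9:
            raise ValidationError("growth GEBV must be non-negative")


def select_flux_models(models: FluxModelSet, threshold: float) -> set[str]:
    """Reactions whose cross-validated accuracy exceeds ``threshold``.

    The conventional threshold is the classical-GS accuracy for fresh
    weight, so only flux models that beat the direct trait model are kept.
    """
    accs = models.accuracies()
    if not accs:
        raise ValidationError("flux models carry no cross-validated accuracies")
    selected = {rid for rid, a in accs.items() if np.isfinite(a) and a > threshold}
    if not selected:
        raise ValidationError(
            f"no flux model has accuracy above {threshold}; lower the threshold"
        )
    return selected


def project_gebv_to_steady_state(
    model_Z: MetabolicModel,
    gebv: dict[str, float],
    ratios: RatioConstraints | None = None,
    extra_system=None,
) -> ProjectionResult:
    """Project a flux-GEBV vector onto the steady-state polytope of genotype Z.

    Minimizes ``sum_i ((w_i - g_i)/g_i)**2`` over the reactions with a GEBV,
    subject to steady state, bounds, interval ratio constraints and
    ``w_biomass >= 0``.  GEBVs below the zero-flux tolerance are dropped from
    the objective with a warning (their reciprocal weight is meaningless).
    ``extra_system`` substitutes a pre-built constraint system (used by the
    cross-environment variant to add exchange-ratio bands).
    """
    if ratios is None:
        ratios = RatioConstraints.interval()
    n = model_Z.n_reactions
    reference = np.zeros(n)
    retained = []
    for rid, g in gebv.items():
        if not np.isfinite(g):
            raise ValidationError(f"non-finite GEBV for reaction {rid!r}")
        j = model_Z.reaction_index(rid)
        if abs(g) <= ZERO_FLUX_TOL:
            warnings.warn(
                f"GEBV for {rid!r} is below the zero-flux tolerance; "
                "dropping it from the projection objective",
                stacklevel=2,
            )
            continue
        reference[j] = g
        retained.append(j)
    if not retained:
        raise ValidationError("no usable GEBVs to project")
    support = np.array(sorted(retained))
    system = extra_system if extra_system is not None else constraint_system(model_Z, ratios)
    system.lb[model_Z.biomass_index] = max(system.lb[model_Z.biomass_index], 0.0)
    H, c = _reciprocal_objective(reference, n, support)
    try:
        x, _ = solve_qp(H, c, system, context=f"netGS projection on {model_Z.model_id!r}")
        status = "optimal"
    except InfeasibleError as exc:
        raise InfeasibleError(
            f"projection infeasible for {model_Z.model_id!r}: {exc}",
            constraint_group=exc.constraint_group,
        ) from None
    w = FluxDistribution(
        x, model_ref=model_Z.model_id, label="netgs_projection",
        reaction_ids=model_Z.reaction_ids,
    )
    return ProjectionResult(
        w=w,
        growth_gebv=max(float(x[model_Z.biomass_index]), 0.0),
        objective=_weighted_distance(x, reference, support),
        retained_reactions={model_Z.reaction_ids[j] for j in support},
        solver_status=status,
    )


def predict_growth(
    models: FluxModelSet,
    G_test: GenotypeMatrix,
    model_by_accession: dict[str, MetabolicModel],
    retained: set[str] | None = None,
    ratios: RatioConstraints | None = None,
    covariates: np.ndarray | None = None,
) -> dict[str, float]:
    """Growth GEBVs for test accessions: evaluate flux models, then project.

    ``model_by_accession`` maps each test accession to its metabolic model
    (possibly one shared reference model, reproducing the reference-biomass
    ablation).  ``retained`` restricts the projection objective to a subset
    of modeled reactions; default is all modeled reactions.  Accessions whose
    projection fails are recorded as NaN.
    """
    use = set(models.models) if retained is None else set(retained) & set(models.models)
    if not use:
        raise ValidationError("no retained reactions with fitted models")
    gebv_table = {
        rid: predict_gebv(models.models[rid], G_test, covariates=covariates)
        for rid in sorted(use)
    }
    out: dict[str, float] = {}
    for i, acc in enumerate(G_test.accession_ids):
        gebv = {rid: float(vals[i]) for rid, vals in gebv_table.items()}
        # stoichiometry-determined fluxes re-enter as constants
        for rid, val in models.constants.items():
            if abs(val) > ZERO_FLUX_TOL:
                gebv.setdefault(rid, val)
        try:
            res = project_gebv_to_steady_state(model_by_accession[acc], gebv, ratios)
            out[acc] = res.growth_gebv
        except (InfeasibleError, ValidationError) as exc:
            logger.warning("projection failed for accession %s: %s", acc, exc)
            out[acc] = float("nan")
    return out
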