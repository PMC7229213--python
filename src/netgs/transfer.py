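"""Transfer of netGS predictions to an unseen environment.

Environmental differences are assumed to act primarily on the exchange
fluxes at the network boundary.  Given the reference genotype's flux
distribution in the training environment E1 and its biomass composition and
measured biomass in the new environment E2, the reference E2 distribution is
estimated by reciprocal-weighted projection (the E2 biomass flux tied to the
E1 value through the measured biomass ratio).  The per-exchange flux ratios
between the two reference distributions then constrain the projection of
E1-trained flux GEBVs, yielding growth predictions for E2 without any
E2-specific statistical model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleError, ValidationError
from .fluxes import ZERO_FLUX_TOL, _solve_band_qp, constraint_system
from .model import FluxDistribution, MetabolicModel, RatioConstraints
from .projection import ProjectionResult, project_gebv_to_steady_state

logger = logging.getLogger(__name__)


@dataclass
class ExchangeRatioSet:
    """Per-exchange flux ratios v_E2 / v_E1 for the transfer set P."""

    ratios: dict[str, float]
    P: list[str] = field(default_factory=list)
    eps: float = 0.05  # relative half-width of the exchange band

    def __post_init__(self):
        if not self.P:
            self.P = list(self.ratios)
        missing = [j for j in self.P if j not in self.ratios]
        if missing:
            raise ValidationError(f"no ratio for exchange reactions {missing}")
        bad = [j for j, r in self.ratios.items() if not np.isfinite(r)]
        if bad:
            raise ValidationError(f"non-finite exchange ratios for {bad}")


def reference_in_env2(
    model_E2: MetabolicModel,
    v_ref_E1: FluxDistribution,
    biomass_ratio: float,
    ratios: RatioConstraints | None = None,
    eps_band: float = 0.05,
) -> FluxDistribution:
    """Reference flux distribution in E2 from the E1 distribution.

    ``model_E2`` carries the reference genotype's E2 biomass column;
    ``biomass_ratio`` is the measured biomass ratio M_E2 / M_E1.  The E2
    biomass flux is constrained to ``biomass_ratio * v_bio_E1 * (1 +/-
    eps_band)`` and all other constraints are as in genotype estimation.
    """
    if biomass_ratio <= 0:
        raise ValidationError("biomass ratio between environments must be positive")
    if ratios is None:
        ratios = RatioConstraints.interval()
    support = v_ref_E1.nonzero_support(ZERO_FLUX_TOL)
    if len(support) == 0:
        raise ValidationError("E1 reference has empty support")
    target = biomass_ratio * v_ref_E1.biomass_flux(model_E2)
    system = constraint_system(model_E2, ratios)
    x, dist, eps_used = _solve_band_qp(
        model_E2, system, v_ref_E1.values, support, target, eps_band,
        label=f"reference transfer to {model_E2.model_id!r}", pin_zero=False,
    )
    return FluxDistribution(
        x, model_ref=model_E2.model_id, label=f"reference_E2(eps={eps_used:g})",
        reaction_ids=model_E2.reaction_ids, objective=dist,
    )


def exchange_ratios(
    v_E1: FluxDistribution,
    v_E2: FluxDistribution,
    P: list[str],
    model: MetabolicModel,
    eps: float = 0.05,
) -> ExchangeRatioSet:
    """Per-exchange ratios v_E2 / v_E1 over the transfer set P.

    Exchanges with near-zero E1 flux are dropped with a warning.
    """
    unknown = [j for j in P if j not in model.exchange_ids]
    if unknown:
        raise ValidationError(f"not exchange reactions of {model.model_id!r}: {unknown}")
    ratios: dict[str, float] = {}
    kept: list[str] = []
    for rid in P:
        a = v_E1.flux(model, rid)
        if abs(a) <= ZERO_FLUX_TOL:
            warnings.warn(
                f"exchange {rid!r} has near-zero flux in E1; dropped from P",
                stacklevel=2,
            )
            continue
        ratios[rid] = v_E2.flux(model, rid) / a
        kept.append(rid)
    return ExchangeRatioSet(ratios=ratios, P=kept, eps=eps)


def project_cross_env(
    model_Z_E1biomass: MetabolicModel,
    gebv: dict[str, float],
    xr: ExchangeRatioSet,
    ratios: RatioConstraints | None = None,
) -> ProjectionResult:
    """netGS projection with exchange fluxes re-scaled for environment E2.

    Identical to the within-environment projection, except that for every
    exchange reaction j in P the flux is constrained to
    ``ratio_j * g_j * (1 +/- eps)``.  The biomass column remains the E1
    (training-environment) column of genotype Z; the biomass entry of the
    solution is the E2 growth prediction.
    """
    if ratios is None:
        ratios = RatioConstraints.interval()
    model = model_Z_E1biomass
    missing = [j for j in xr.P if j not in gebv]
    if missing:
        raise ValidationError(f"no GEBV for exchange reactions in P: {missing}")
    eps = xr.eps
    max_widenings = 3
    for attempt in range(max_widenings + 1):
        system = constraint_system(model, ratios)
        for rid in xr.P:
            j = model.reaction_index(rid)
            center = xr.ratios[rid] * gebv[rid]
            lo, hi = sorted((center * (1 - eps), center * (1 + eps)))
            system.lb[j] = max(system.lb[j], lo)
            system.ub[j] = min(system.ub[j], hi)
            if system.lb[j] > system.ub[j]:
                raise ValidationError(
                    f"exchange band for {rid!r} ({lo:.4g}, {hi:.4g}) lies outside model bounds"
                )
        try:
            return project_gebv_to_steady_state(model, gebv, ratios, extra_system=system)
        except InfeasibleError:
            if attempt == max_widenings:
                raise
            # the band slack exists to keep the feasible set non-empty;
            # widen it as for the biomass band, logging each step
            eps *= 2.0
            logger.warning(
                "cross-env projection infeasible for %r; widening exchange bands to +/-%.3g",
                model.model_id, eps,
            )
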