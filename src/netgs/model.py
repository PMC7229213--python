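"""Core data model for stoichiometric networks and biomass reactions.

A :class:`MetabolicModel` holds the stoichiometric matrix ``S`` (metabolites x
reactions), flux bounds, the position of the biomass reaction and the tags
identifying the four reactions that enter the canonical-pathway ratio
constraints (RuBisCO carboxylation/oxygenation and starch/sucrose synthesis).

A :class:`BiomassComposition` is the measured precursor demand of one gram of
dry weight for one accession in one environment.  Substituting it for the
biomass column of a model yields the accession-specific model used throughout
the flux-estimation pipeline.

Unit conventions
----------------
Fluxes are in mmol gDW^-1 d^-1.  Biomass-composition coefficients are stored
in umol gDW^-1, signed: consumed precursors are negative.  When a composition
is written into the stoichiometric matrix, coefficients are converted to mmol
(divided by 1000) so that a biomass flux of 1 d^-1 consumes the measured
amounts per gram of dry weight per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np

from .errors import ValidationError

#: the four reactions with canonical-pathway ratio constraints
RATIO_TAGS = ("carboxylation", "oxygenation", "starch_synthesis", "sucrose_synthesis")

#: default generic bounds for reversible / irreversible reactions
REVERSIBLE_BOUNDS = (-1000.0, 1000.0)
IRREVERSIBLE_BOUNDS = (0.0, 1000.0)

UMOL_PER_MMOL = 1000.0


@dataclass(frozen=True)
class RatioConstraints:
    """Carboxylation/oxygenation and starch/sucrose flux-ratio constraints.

    Each ratio is either a fixed value (reference estimation) or a
    ``[low, high]`` interval (all genotype-specific programs).  The defaults
    are the reference genotype's measured ratios 2.88 and 2.58 and the intervals
    [0.94, 3.81] and [0.79, 3.37] derived from them.
    """

    carb_oxy: float | tuple[float, float] = 2.88
    starch_sucrose: float | tuple[float, float] = 2.58

    def __post_init__(self):
        for name, r in (("carb_oxy", self.carb_oxy), ("starch_sucrose", self.starch_sucrose)):
            vals = r if isinstance(r, tuple) else (r,)
            if any(v <= 0 or not math.isfinite(v) for v in vals):
                raise ValidationError(f"{name} ratio must be positive and finite, got {r}")
            if isinstance(r, tuple) and r[0] > r[1]:
                raise ValidationError(f"{name} interval {r} has low > high")

    @property
    def is_fixed(self) -> bool:
        return not (isinstance(self.carb_oxy, tuple) or isinstance(self.starch_sucrose, tuple))

    @classmethod
    def fixed(cls, carb_oxy: float = 2.88, starch_sucrose: float = 2.58) -> "RatioConstraints":
        return cls(carb_oxy, starch_sucrose)

    @classmethod
    def interval(
        cls,
        carb_oxy: tuple[float, float] = (0.94, 3.81),
        starch_sucrose: tuple[float, float] = (0.79, 3.37),
    ) -> "RatioConstraints":
        return cls(tuple(carb_oxy), tuple(starch_sucrose))


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounds, biomass column and tagged reactions."""

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    biomass_index: int
    tags: dict[str, str] = field(default_factory=dict)  # tag -> reaction id
    exchange_ids: list[str] = field(default_factory=list)
    model_id: str = "model"

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        m, n = self.S.shape
        if len(self.metabolite_ids) != m or len(self.reaction_ids) != n:
            raise ValidationError(
                f"S is {m}x{n} but there are {len(self.metabolite_ids)} metabolites "
                f"and {len(self.reaction_ids)} reactions"
            )
        for name, ids in (("metabolite", self.metabolite_ids), ("reaction", self.reaction_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValidationError(f"duplicate {name} ids: {dupes}")
        if self.lb.shape != (n,) or self.ub.shape != (n,):
            raise ValidationError("bound vectors must have one entry per reaction")
        if np.any(self.lb > self.ub):
            bad = [self.reaction_ids[i] for i in np.where(self.lb > self.ub)[0]]
            raise ValidationError(f"lb > ub for reactions {bad}")
        if not (0 <= self.biomass_index < n):
            raise ValidationError(f"biomass_index {self.biomass_index} out of range")
        for tag, rid in self.tags.items():
            if tag not in RATIO_TAGS:
                raise ValidationError(f"unknown tag {tag!r}")
            if rid not in self.reaction_ids:
                raise ValidationError(f"tag {tag!r} points at unknown reaction {rid!r}")
        rid_set = set(self.reaction_ids)
        for rid in self.exchange_ids:
            if rid not in rid_set:
                raise ValidationError(f"exchange id {rid!r} not a reaction")
            col = self.S[:, self.reaction_index(rid)]
            if np.count_nonzero(col) != 1:
                raise ValidationError(
                    f"exchange reaction {rid!r} must touch exactly one metabolite"
                )

    # ------------------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def biomass_id(self) -> str:
        return self.reaction_ids[self.biomass_index]

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise ValidationError(f"unknown reaction id {rid!r}") from None

    def metabolite_index(self, mid: str) -> int:
        try:
            return self.metabolite_ids.index(mid)
        except ValueError:
            raise ValidationError(f"unknown metabolite id {mid!r}") from None

    def tag_index(self, tag: str) -> int | None:
        """Column index of a tagged reaction, or None if the tag is absent."""
        rid = self.tags.get(tag)
        return None if rid is None else self.reaction_index(rid)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            biomass_index=self.biomass_index,
            tags=dict(self.tags),
            exchange_ids=list(self.exchange_ids),
            model_id=self.model_id,
        )

    def biomass_column(self) -> np.ndarray:
        return self.S[:, self.biomass_index].copy()


@dataclass(frozen=True)
class BiomassComposition:
    """Precursor demand of one gram dry weight (umol gDW^-1, consumed < 0)."""

    coefficients: Mapping[str, float]
    accession_id: str = "reference"
    environment_id: str = "E1"

    def __post_init__(self):
        coeffs = dict(self.coefficients)
        if not coeffs or all(c == 0 for c in coeffs.values()):
            raise ValidationError("biomass composition needs at least one non-zero coefficient")
        bad = [m for m, c in coeffs.items() if not math.isfinite(c)]
        if bad:
            raise ValidationError(f"non-finite coefficients for {bad}")
        object.__setattr__(self, "coefficients", coeffs)

    @classmethod
    def from_model(
        cls, model: MetabolicModel, accession_id: str = "reference", environment_id: str = "E1"
    ) -> "BiomassComposition":
        """Read the current biomass column of a model back into umol units."""
        col = model.biomass_column()
        coeffs = {
            model.metabolite_ids[i]: col[i] * UMOL_PER_MMOL
            for i in np.where(col != 0)[0]
        }
        return cls(coeffs, accession_id, environment_id)

    def scaled(self, factor: float) -> "BiomassComposition":
        return BiomassComposition(
            {m: c * factor for m, c in self.coefficients.items()},
            self.accession_id,
            self.environment_id,
        )


@dataclass
class FluxDistribution:
    """A flux value per reaction of one model (mmol gDW^-1 d^-1)."""

    values: np.ndarray
    model_ref: str
    label: str = ""
    reaction_ids: list[str] | None = None
    objective: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def flux(self, model: MetabolicModel, rid: str) -> float:
        return float(self.values[model.reaction_index(rid)])

    def biomass_flux(self, model: MetabolicModel) -> float:
        return float(self.values[model.biomass_index])

    def nonzero_support(self, tol: float = 1e-9) -> np.ndarray:
        """Indices of reactions with flux magnitude above ``tol`` (the set R!=0)."""
        return np.where(np.abs(self.values) > tol)[0]

    def steady_state_residual(self, model: MetabolicModel) -> float:
        return float(np.max(np.abs(model.S @ self.values))) if len(self.values) else 0.0


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def set_biomass(model: MetabolicModel, comp: BiomassComposition) -> MetabolicModel:
    """Return a copy of ``model`` whose biomass column encodes ``comp``.

    Coefficients are converted from umol gDW^-1 to matrix units (mmol).  The
    input model is not modified.
    """
    unknown = sorted(set(comp.coefficients) - set(model.metabolite_ids))
    if unknown:
        raise ValidationError(f"composition references unknown metabolites: {unknown}")
    out = model.copy()
    col = np.zeros(model.n_metabolites)
    for mid, coeff in comp.coefficients.items():
        col[model.metabolite_index(mid)] = coeff / UMOL_PER_MMOL
    out.S[:, out.biomass_index] = col
    out.model_id = f"{model.model_id}[{comp.accession_id}/{comp.environment_id}]"
    return out


def load_molar_masses(path=None) -> dict[str, float]:
    """Load a metabolite -> molar mass (g mol^-1) table.

    Without ``path`` the table shipped with the package is used.  The table is
    deliberately explicit: metabolites without an entry make
    :func:`assemble_biomass` fail loudly rather than silently mis-scaling.
    """
    import pandas as pd

    if path is None:
        ref = resources.files("netgs").joinpath("data/molar_masses.tsv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    return dict(zip(table["metabolite"], table["molar_mass"].astype(float)))


def assemble_biomass(
    measured: Mapping[str, float],
    protein_total: float,
    aa_fractions: Mapping[str, float],
    fixed_components: BiomassComposition | None,
    molar_masses: Mapping[str, float],
    accession_id: str = "accession",
    environment_id: str = "E1",
) -> BiomassComposition:
    """Assemble an accession-specific biomass composition.

    Parameters
    ----------
    measured
        Soluble metabolites and starch in mg gDW^-1 (non-negative amounts).
    protein_total
        Total protein in mg gDW^-1; distributed over amino acids.
    aa_fractions
        Mass fraction of each amino acid in total protein; must sum to 1.
    fixed_components
        Components assumed identical across accessions (cell wall, lipid
        precursors, nucleotides, ATP), already in umol gDW^-1 with signs.
    molar_masses
        g mol^-1 per metabolite, for the mg -> umol conversion
        (umol = 1000 * mg / molar_mass).

    All assembled coefficients are negative (consumed precursors); fixed
    components keep their stored signs.
    """
    if protein_total < 0:
        raise ValidationError("protein_total must be non-negative")
    if aa_fractions:
        total = sum(aa_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"amino-acid fractions sum to {total}, expected 1")
    coeffs: dict[str, float] = {}

    def add(mid: str, mg: float) -> None:
        if mg < 0:
            raise ValidationError(f"negative amount for {mid!r}: {mg}")
        if mid not in molar_masses:
            raise ValidationError(f"no molar mass for metabolite {mid!r}")
        umol = 1000.0 * mg / molar_masses[mid]
        coeffs[mid] = coeffs.get(mid, 0.0) - umol

    for mid in sorted(measured):
        add(mid, measured[mid])
    for aa in sorted(aa_fractions):
        add(aa, protein_total * aa_fractions[aa])
    if fixed_components is not None:
        for mid, c in fixed_components.coefficients.items():
            coeffs[mid] = coeffs.get(mid, 0.0) + c
    return BiomassComposition(coeffs, accession_id, environment_id)


def interpolate_compositions(
    base: BiomassComposition,
    perturbation: Mapping[str, float],
    accession_id: str,
) -> BiomassComposition:
    """Apply per-metabolite multiplicative perturbations to a base composition."""
    coeffs = dict(base.coefficients)
    for mid, f in perturbation.items():
        if mid in coeffs:
            coeffs[mid] = coeffs[mid] * f
    return BiomassComposition(coeffs, accession_id, base.environment_id)
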