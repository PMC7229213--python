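"""Synthetic metabolic networks and accession panels.

The generators produce inputs with the statistical structure the pipeline
assumes: a photoautotrophic toy network with tagged RuBisCO
carboxylation/oxygenation and starch/sucrose-synthesis reactions, biomass
and boundary exchanges, together with a panel of accessions whose marker
genotypes drive both biomass composition and fresh weight additively in two
environments.

The ``minimal`` network is a checked-in, fully hand-checkable fixture (8
reactions); ``standard`` networks are randomized 20-40 reaction extensions
whose added internal reactions conserve a positive metabolite mass function,
so the extension cannot create matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InfeasibleError, NetgsError, ValidationError
from .fluxes import estimate_panel_fluxes, solve_reference_fba
from .gs import GenotypeMatrix, prepare_genotypes
from .io import read_biomass_csv, read_model
from .model import BiomassComposition, FluxDistribution, MetabolicModel, RatioConstraints, set_biomass


@dataclass
class SimConfig:
    """Settings of the simulated accession panel.

    ``env_effects`` maps environment id to ``(biomass_scale,
    composition_shift)``: measured fresh weights are multiplied by the scale
    and all variable composition coefficients by ``1 + shift``.  The
    defaults emulate a two-environment design (optimal vs. limiting
    nutrition, E2 growing at 60% of E1) on a diverse inbred panel.
    """

    n_accessions: int = 200
    n_markers: int = 500
    n_qtl: int = 40
    h2_biomass: float = 0.8
    h2_composition: float = 0.6
    env_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"E1": (1.0, 0.0), "E2": (0.6, -0.08)}
    )
    seed: int = 0
    fw_cv: float = 0.15          # coefficient of variation of fresh weight
    composition_cv: float = 0.08  # coefficient of variation of biomass coefficients
    genetic_overlap: float = 0.5  # share of growth genetic variance routed through composition
    maf_threshold: float = 0.05

    def __post_init__(self):
        if self.n_qtl > self.n_markers:
            raise ValidationError("n_qtl cannot exceed n_markers")
        for name, h2 in (("h2_biomass", self.h2_biomass), ("h2_composition", self.h2_composition)):
            if not (0 < h2 <= 1):
                raise ValidationError(f"{name} must lie in (0, 1]")
        if not (0 <= self.genetic_overlap <= 1):
            raise ValidationError("genetic_overlap must lie in [0, 1]")


@dataclass
class SimulatedPanel:
    """A complete synthetic study: network, panel, phenotypes, true fluxes."""

    model: MetabolicModel                      # base network with reference E1 biomass
    ref_compositions: dict[str, BiomassComposition]   # env -> reference composition
    ref_fresh_weight: dict[str, float]                # env -> reference fresh weight
    compositions: dict[str, dict[str, BiomassComposition]]  # env -> accession -> comp
    fresh_weight: pd.DataFrame                 # accessions x environments
    genotypes: GenotypeMatrix                  # MAF-filtered panel genotypes
    raw_dosages: pd.DataFrame                  # pre-filter dosage table
    genetic_values: pd.DataFrame               # accessions x latent traits (truth)
    v_ref: dict[str, FluxDistribution]         # env -> reference flux distribution
    fluxes: dict[str, pd.DataFrame]            # env -> accessions x reactions (truth)
    config: SimConfig = None

    def accession_model(self, accession: str, environment: str = "E1") -> MetabolicModel:
        return set_biomass(self.model, self.compositions[environment][accession])


# ----------------------------------------------------------------------
# Toy networks
# ----------------------------------------------------------------------

def _load_minimal() -> tuple[MetabolicModel, dict[str, BiomassComposition]]:
    ref = resources.files("netgs").joinpath("data/minimal")
    with resources.as_file(ref) as p:
        model = read_model(Path(p), dialect="tsv")
        comps = read_biomass_csv(Path(p) / "biomass_compositions.csv")
    by_env = {env: comp for (_, env), comp in comps.items()}
    return set_biomass(model, by_env["E1"]), by_env


def _random_standard(seed: int) -> tuple[MetabolicModel, dict[str, BiomassComposition]]:
    """A randomized 20-40 reaction photoautotrophic network."""
    rng = np.random.default_rng(seed)
    mets = ["E_in", "CO2_in", "NO3_in", "H2O_in", "PGA", "STARCH", "SUCROSE", "AA"]
    mass = {"E_in": 0.2, "CO2_in": 1.0, "NO3_in": 1.0, "H2O_in": 0.4,
            "PGA": 1.2, "STARCH": 2.0, "SUCROSE": 2.2, "AA": 1.6}
    records = [
        {"id": "EX_photon", "stoich": {"E_in": 1}, "lb": 0.0, "ub": 100.0, "tag": ""},
        {"id": "EX_CO2", "stoich": {"CO2_in": 1}, "lb": 0.0, "ub": 10.0, "tag": ""},
        {"id": "EX_NO3", "stoich": {"NO3_in": 1}, "lb": 0.0, "ub": 5.0, "tag": ""},
        {"id": "EX_H2O", "stoich": {"H2O_in": 1}, "lb": 0.0, "ub": 50.0, "tag": ""},
        {"id": "CARBOXYLATION", "stoich": {"CO2_in": -1, "E_in": -1, "PGA": 1},
         "lb": 0.0, "ub": 1000.0, "tag": "carboxylation"},
        {"id": "OXYGENATION", "stoich": {"CO2_in": -1, "E_in": -1, "PGA": 0.5},
         "lb": 0.0, "ub": 1000.0, "tag": "oxygenation"},
        {"id": "STARCH_SYNTH", "stoich": {"PGA": -1, "STARCH": 1},
         "lb": 0.0, "ub": 1000.0, "tag": "starch_synthesis"},
        {"id": "SUCROSE_SYNTH", "stoich": {"PGA": -1, "SUCROSE": 1},
         "lb": 0.0, "ub": 1000.0, "tag": "sucrose_synthesis"},
        {"id": "N_ASSIM", "stoich": {"NO3_in": -1, "E_in": -0.5, "AA": 1},
         "lb": 0.0, "ub": 1000.0, "tag": ""},
    ]
    internal = ["PGA", "STARCH", "SUCROSE", "AA"]
    n_extra = int(rng.integers(10, 29))  # reactions, not iterations: total stays in 20-40
    k = 0
    while len(records) < 9 + n_extra:
        k += 1
        kind = rng.random()
        if kind < 0.5 and len(internal) >= 2:
            # mass-balanced conversion between two existing internal pools
            a, b = rng.choice(internal, size=2, replace=False)
            coeff = mass[a] / mass[b]
            rev = bool(rng.random() < 0.4)
            records.append(
                {"id": f"CONV_{k}", "stoich": {a: -1.0, b: round(coeff, 4)},
                 "lb": -1000.0 if rev else 0.0, "ub": 1000.0, "tag": ""}
            )
        else:
            # short chain through a new intermediate back into an existing pool
            a, b = rng.choice(internal, size=2, replace=False)
            new = f"X{k}"
            mets.append(new)
            mass[new] = mass[a]
            records.append(
                {"id": f"CHAIN_{k}a", "stoich": {a: -1.0, new: 1.0},
                 "lb": 0.0, "ub": 1000.0, "tag": ""}
            )
            records.append(
                {"id": f"CHAIN_{k}b", "stoich": {new: -1.0, b: round(mass[new] / mass[b], 4)},
                 "lb": 0.0, "ub": 1000.0, "tag": ""}
            )
    # reference E1 composition keeps starch/sucrose at exactly the fixed ratio
    suc = 500.0
    sta = 2.58 * suc
    comps = {
        "E1": BiomassComposition(
            {"STARCH": -sta, "SUCROSE": -suc, "AA": -350.0, "H2O_in": -600.0},
            accession_id="reference", environment_id="E1",
        ),
        "E2": BiomassComposition(
            {"STARCH": -sta * 0.92, "SUCROSE": -suc * 0.96, "AA": -250.0, "H2O_in": -550.0},
            accession_id="reference", environment_id="E2",
        ),
    }
    records.append(
        {"id": "BIOMASS",
         "stoich": {m: c / 1000.0 for m, c in comps["E1"].coefficients.items()},
         "lb": 0.0, "ub": 1000.0, "tag": "biomass"}
    )
    from .io import _build_model

    model = _build_model(mets, records, model_id=f"standard_{seed}")
    return model, comps


def make_toy_model(
    size: str = "minimal", seed: int = 0, max_attempts: int = 20
) -> tuple[MetabolicModel, dict[str, BiomassComposition]]:
    """Generate a toy network and its reference biomass compositions per environment.

    ``minimal`` is the deterministic 8-reaction fixture; ``standard`` is a
    randomized 20-40 reaction network with a guaranteed positive biomass
    optimum, all four ratio tags and at least four exchange reactions.
    """
    if size == "minimal":
        return _load_minimal()
    if size != "standard":
        raise ValidationError(f"unknown toy-model size {size!r}")
    for attempt in range(max_attempts):
        model, comps = _random_standard(seed + 1_000_003 * attempt)
        try:
            ref = solve_reference_fba(model, RatioConstraints.fixed())
        except (InfeasibleError, NetgsError):
            continue
        if ref.objective > 1e-6:
            return model, comps
    raise NetgsError(f"could not generate a feasible standard network after {max_attempts} tries")


# ----------------------------------------------------------------------
# Panel simulation
# ----------------------------------------------------------------------

_VARIABLE_COMPONENTS = ("STARCH", "SUCROSE")  # plus any nitrogen-bearing pool


def _clip_ratio(coeffs: dict[str, float], low: float = 0.90, high: float = 3.30) -> dict[str, float]:
    """Keep the starch/sucrose coefficient ratio inside the feasible band."""
    sta, suc = coeffs.get("STARCH"), coeffs.get("SUCROSE")
    if sta is None or suc is None or suc == 0:
        return coeffs
    ratio = sta / suc
    if ratio < low:
        coeffs["STARCH"] = suc * low
    elif ratio > high:
        coeffs["STARCH"] = suc * high
    return coeffs


def simulate_panel(
    model: MetabolicModel,
    ref_compositions: dict[str, BiomassComposition],
    cfg: SimConfig,
    flux_environments: tuple[str, ...] = ("E1",),
    ratios: RatioConstraints | None = None,
) -> SimulatedPanel:
    """Simulate an accession panel on a toy network.

    Marker dosages are i.i.d. binomial with allele frequencies uniform on
    [0.1, 0.9].  A fixed QTL subset carries Gaussian effects on four latent
    traits (growth and the variable biomass components); phenotypes mix the
    standardized genetic value with Gaussian noise at the configured
    heritabilities.  Ground-truth fluxes are produced by running the
    genotype flux estimation against the generated compositions and fresh
    weights, exactly as the pipeline would.
    """
    if ratios is None:
        ratios = RatioConstraints.interval()
    rng = np.random.default_rng(cfg.seed)
    accessions = [f"acc{i:04d}" for i in range(cfg.n_accessions)]
    markers = [f"m{j:05d}" for j in range(cfg.n_markers)]
    freqs = rng.uniform(0.1, 0.9, cfg.n_markers)
    dosages = rng.binomial(2, freqs, size=(cfg.n_accessions, cfg.n_markers)).astype(float)
    raw = pd.DataFrame(dosages, index=accessions, columns=markers)

    variable = [m for m in _VARIABLE_COMPONENTS if m in ref_compositions["E1"].coefficients]
    n_pool = [m for m in ref_compositions["E1"].coefficients
              if m not in variable and m not in ("H2O_in",)]
    variable = variable + n_pool[:1]  # one nitrogen-bearing / residual pool varies too
    traits = ["growth"] + [f"comp_{m}" for m in variable]
    qtl_idx = rng.choice(cfg.n_markers, size=cfg.n_qtl, replace=False)
    beta = rng.normal(size=(cfg.n_qtl, len(traits)))
    Zq = dosages[:, qtl_idx]
    genetic = (Zq - Zq.mean(axis=0)) @ beta
    sd = genetic.std(axis=0)
    sd[sd == 0] = 1.0
    genetic = genetic / sd
    # growth is genetically coupled to composition: heavier biomass demand per
    # gram lowers growth per unit carbon, so part of the growth genetic value
    # is the (negated, standardized) sum of the composition genetic values
    if cfg.genetic_overlap > 0 and genetic.shape[1] > 1:
        comp_mix = -genetic[:, 1:].sum(axis=1)
        comp_mix = comp_mix / max(comp_mix.std(), 1e-12)
        g_growth = (
            np.sqrt(cfg.genetic_overlap) * comp_mix
            + np.sqrt(1.0 - cfg.genetic_overlap) * genetic[:, 0]
        )
        genetic[:, 0] = g_growth / max(g_growth.std(), 1e-12)
    genetic_df = pd.DataFrame(genetic, index=accessions, columns=traits)

    h2 = {"growth": cfg.h2_biomass}
    h2.update({t: cfg.h2_composition for t in traits[1:]})

    def draw_scores(noise_rng):
        scores = {}
        for t in traits:
            noise = noise_rng.normal(size=cfg.n_accessions)
            scores[t] = np.sqrt(h2[t]) * genetic_df[t].to_numpy() + np.sqrt(1 - h2[t]) * noise
        return pd.DataFrame(scores, index=accessions)

    scores = draw_scores(rng)
    envs = list(cfg.env_effects)

    def build_phenotypes(scores):
        fw = {}
        comps = {}
        for env in envs:
            scale, shift = cfg.env_effects[env]
            fw[env] = np.maximum(
                scale * (1.0 + cfg.fw_cv * scores["growth"].to_numpy()), 0.1 * scale
            )
            comps[env] = {}
            base = ref_compositions[env].coefficients
            for i, acc in enumerate(accessions):
                coeffs = dict(base)
                for t, m in zip(traits[1:], variable):
                    coeffs[m] = base[m] * (1.0 + shift) * (
                        1.0 + cfg.composition_cv * scores.loc[acc, t]
                    )
                coeffs = _clip_ratio(coeffs)
                comps[env][acc] = BiomassComposition(coeffs, accession_id=acc, environment_id=env)
        return pd.DataFrame(fw, index=accessions), comps

    fresh_weight, compositions = build_phenotypes(scores)
    ref_fw = {env: cfg.env_effects[env][0] for env in envs}

    # reference flux distribution per environment that needs ground-truth fluxes
    v_ref: dict[str, FluxDistribution] = {}
    fluxes: dict[str, pd.DataFrame] = {}
    for env in flux_environments:
        env_model = set_biomass(model, ref_compositions[env])
        v_ref[env] = solve_reference_fba(env_model, RatioConstraints.fixed())

    for attempt in range(5):
        try:
            for env in flux_environments:
                env_model = set_biomass(model, ref_compositions[env])
                table, _ = estimate_panel_fluxes(
                    env_model,
                    compositions[env],
                    dict(zip(accessions, fresh_weight[env])),
                    M_ref=ref_fw[env],
                    v_ref=v_ref[env],
                    ratios=ratios,
                )
                fluxes[env] = table
            break
        except InfeasibleError:
            if attempt == 4:
                raise
            scores = draw_scores(rng)  # resample environmental noise and retry
            fresh_weight, compositions = build_phenotypes(scores)

    genotypes = prepare_genotypes(raw, maf_threshold=cfg.maf_threshold)
    return SimulatedPanel(
        model=model,
        ref_compositions=ref_compositions,
        ref_fresh_weight=ref_fw,
        compositions=compositions,
        fresh_weight=fresh_weight,
        genotypes=genotypes,
        raw_dosages=raw,
        genetic_values=genetic_df,
        v_ref=v_ref,
        fluxes=fluxes,
        config=cfg,
    )
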