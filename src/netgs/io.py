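"""Readers and writers for metabolic models, compositions, fluxes and genotypes.

Three model dialects are supported:

``tsv``
    The canonical dialect: a directory (or the ``reactions.tsv`` file inside
    it) with ``reactions.tsv`` (columns ``id, equation, lb, ub, tag``) and
    ``metabolites.tsv`` (column ``id``).  Equations use ``->`` for
    irreversible and ``<->`` for reversible reactions; an empty side denotes
    an exchange with the boundary (``-> A`` imports A with positive flux).
``json``
    The same content as a single JSON document.
``sbml``
    SBML Level 3 with the ``fbc`` package for flux bounds and the biomass
    objective; implemented as a thin layer over the tabular representation.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .model import (
    IRREVERSIBLE_BOUNDS,
    RATIO_TAGS,
    REVERSIBLE_BOUNDS,
    BiomassComposition,
    FluxDistribution,
    MetabolicModel,
)

_ARROW_RE = re.compile(r"\s*(<->|<=>|->)\s*")


def _parse_side(side: str, line_ctx: str) -> dict[str, float]:
    """Parse one side of an equation like ``A + 2 B`` into {metabolite: coeff}."""
    out: dict[str, float] = {}
    side = side.strip()
    if not side:
        return out
    for term in side.split("+"):
        parts = term.strip().split()
        if len(parts) == 1:
            coeff, mid = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coeff = float(parts[0])
            except ValueError:
                raise FormatError(f"bad coefficient {parts[0]!r} in {line_ctx}") from None
            mid = parts[1]
        else:
            raise FormatError(f"cannot parse term {term.strip()!r} in {line_ctx}")
        out[mid] = out.get(mid, 0.0) + coeff
    return out


def parse_equation(eq: str, rid: str = "?") -> tuple[dict[str, float], bool]:
    """Parse an equation string into a stoichiometry map and reversibility flag.

    Reactants get negative, products positive coefficients.
    """
    m = _ARROW_RE.search(eq)
    if m is None:
        raise FormatError(f"reaction {rid!r}: equation {eq!r} lacks an arrow")
    arrow = m.group(1)
    left, right = eq[: m.start()], eq[m.end():]
    stoich: dict[str, float] = {}
    for mid, c in _parse_side(left, f"reaction {rid!r}").items():
        stoich[mid] = stoich.get(mid, 0.0) - c
    for mid, c in _parse_side(right, f"reaction {rid!r}").items():
        stoich[mid] = stoich.get(mid, 0.0) + c
    stoich = {m_: c for m_, c in stoich.items() if c != 0}
    if not stoich:
        raise FormatError(f"reaction {rid!r}: equation {eq!r} has no net stoichiometry")
    return stoich, arrow in ("<->", "<=>")


def format_equation(stoich: dict[str, float], reversible: bool) -> str:
    def side(items):
        terms = []
        for mid, c in items:
            terms.append(mid if c == 1 else f"{c:g} {mid}")
        return " + ".join(terms)

    left = side([(m, -c) for m, c in stoich.items() if c < 0])
    right = side([(m, c) for m, c in stoich.items() if c > 0])
    arrow = "<->" if reversible else "->"
    return f"{left} {arrow} {right}".strip()


def _build_model(
    metabolite_ids: list[str],
    records: list[dict],
    model_id: str,
) -> MetabolicModel:
    """Assemble a MetabolicModel from per-reaction records (id/stoich/lb/ub/tag)."""
    reaction_ids = [r["id"] for r in records]
    if len(set(reaction_ids)) != len(reaction_ids):
        dupes = sorted({i for i in reaction_ids if reaction_ids.count(i) > 1})
        raise ValidationError(f"duplicate reaction ids: {dupes}")
    met_set = set(metabolite_ids)
    biomass_ids = [r["id"] for r in records if r.get("tag") == "biomass"]
    if len(biomass_ids) != 1:
        raise ValidationError(
            f"exactly one reaction must be tagged 'biomass', found {len(biomass_ids)}"
        )
    m, n = len(metabolite_ids), len(records)
    S = np.zeros((m, n))
    lb = np.zeros(n)
    ub = np.zeros(n)
    tags: dict[str, str] = {}
    exchange_ids: list[str] = []
    met_pos = {mid: i for i, mid in enumerate(metabolite_ids)}
    for j, rec in enumerate(records):
        for mid, c in rec["stoich"].items():
            if mid not in met_set:
                raise ValidationError(
                    f"reaction {rec['id']!r} references unknown metabolite {mid!r}"
                )
            S[met_pos[mid], j] = c
        lb[j], ub[j] = rec["lb"], rec["ub"]
        tag = rec.get("tag") or ""
        if tag in RATIO_TAGS:
            if tag in tags:
                raise ValidationError(f"tag {tag!r} assigned to more than one reaction")
            tags[tag] = rec["id"]
        if len(rec["stoich"]) == 1:
            exchange_ids.append(rec["id"])
    return MetabolicModel(
        metabolite_ids=list(metabolite_ids),
        reaction_ids=reaction_ids,
        S=S,
        lb=lb,
        ub=ub,
        biomass_index=reaction_ids.index(biomass_ids[0]),
        tags=tags,
        exchange_ids=exchange_ids,
        model_id=model_id,
    )


def _default_bounds(reversible: bool) -> tuple[float, float]:
    return REVERSIBLE_BOUNDS if reversible else IRREVERSIBLE_BOUNDS


# ----------------------------------------------------------------------
# TSV dialect
# ----------------------------------------------------------------------

def _read_tsv(path: Path) -> MetabolicModel:
    if path.is_dir():
        rxn_path, met_path = path / "reactions.tsv", path / "metabolites.tsv"
    else:
        rxn_path, met_path = path, path.parent / "metabolites.tsv"
    if not rxn_path.exists():
        raise FormatError(f"missing {rxn_path}")
    rxns = pd.read_csv(rxn_path, sep="\t", dtype={"tag": str}, keep_default_na=False)
    for col in ("id", "equation"):
        if col not in rxns.columns:
            raise FormatError(f"{rxn_path}: missing required column {col!r}")
    if met_path.exists():
        metabolite_ids = pd.read_csv(met_path, sep="\t")["id"].astype(str).tolist()
    else:
        metabolite_ids = None
    records = []
    for _, row in rxns.iterrows():
        stoich, reversible = parse_equation(str(row["equation"]), str(row["id"]))
        dlb, dub = _default_bounds(reversible)
        lb = float(row["lb"]) if "lb" in rxns.columns and str(row["lb"]) != "" else dlb
        ub = float(row["ub"]) if "ub" in rxns.columns and str(row["ub"]) != "" else dub
        records.append(
            {"id": str(row["id"]), "stoich": stoich, "lb": lb, "ub": ub,
             "tag": str(row.get("tag", "") or "")}
        )
    if metabolite_ids is None:
        seen: list[str] = []
        for rec in records:
            for mid in rec["stoich"]:
                if mid not in seen:
                    seen.append(mid)
        metabolite_ids = seen
    return _build_model(metabolite_ids, records, model_id=rxn_path.stem)


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    tag_of = {rid: tag for tag, rid in model.tags.items()}
    tag_of[model.biomass_id] = "biomass"
    for j, rid in enumerate(model.reaction_ids):
        stoich = {
            model.metabolite_ids[i]: model.S[i, j] for i in np.where(model.S[:, j] != 0)[0]
        }
        reversible = model.lb[j] < 0
        rows.append(
            {
                "id": rid,
                "equation": format_equation(stoich, reversible),
                "lb": repr(float(model.lb[j])),
                "ub": repr(float(model.ub[j])),
                "tag": tag_of.get(rid, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame({"id": model.metabolite_ids}).to_csv(
        path / "metabolites.tsv", sep="\t", index=False
    )


# ----------------------------------------------------------------------
# JSON dialect
# ----------------------------------------------------------------------

def _read_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from None
    try:
        metabolite_ids = [str(m) for m in doc["metabolites"]]
        records = [
            {
                "id": str(r["id"]),
                "stoich": {str(k): float(v) for k, v in r["metabolites"].items()},
                "lb": float(r["lb"]),
                "ub": float(r["ub"]),
                "tag": str(r.get("tag", "")),
            }
            for r in doc["reactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: missing or malformed element: {exc}") from None
    return _build_model(metabolite_ids, records, model_id=doc.get("id", Path(path).stem))


def _write_json(model: MetabolicModel, path: Path) -> None:
    tag_of = {rid: tag for tag, rid in model.tags.items()}
    tag_of[model.biomass_id] = "biomass"
    doc = {
        "id": model.model_id,
        "metabolites": model.metabolite_ids,
        "reactions": [
            {
                "id": rid,
                "metabolites": {
                    model.metabolite_ids[i]: model.S[i, j]
                    for i in np.where(model.S[:, j] != 0)[0]
                },
                "lb": model.lb[j],
                "ub": model.ub[j],
                "tag": tag_of.get(rid, ""),
            }
            for j, rid in enumerate(model.reaction_ids)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# ----------------------------------------------------------------------
# SBML dialect (libsbml + fbc)
# ----------------------------------------------------------------------

def _sanitize(sid: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", sid)


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path}: no model element")
    fbc = sbml_model.getPlugin("fbc")
    metabolite_ids = [s.getId() for s in sbml_model.getListOfSpecies()]
    params = {
        p.getId(): p.getValue() for p in sbml_model.getListOfParameters()
    }
    biomass_rid = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            biomass_rid = obj.getFluxObjective(0).getReaction()
    records = []
    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for sr in rxn.getListOfReactants():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for sr in rxn.getListOfProducts():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        rfbc = rxn.getPlugin("fbc")
        if rfbc is not None and rfbc.getLowerFluxBound():
            lb = params[rfbc.getLowerFluxBound()]
            ub = params[rfbc.getUpperFluxBound()]
        else:
            lb, ub = _default_bounds(rxn.getReversible())
        tag = ""
        notes = rxn.getNotesString() if rxn.isSetNotes() else ""
        m = re.search(r"netgs_tag:\s*(\w+)", notes)
        if m:
            tag = m.group(1)
        if biomass_rid is not None and rxn.getId() == biomass_rid:
            tag = "biomass"
        records.append({"id": rxn.getId(), "stoich": stoich, "lb": lb, "ub": ub, "tag": tag})
    return _build_model(metabolite_ids, records, model_id=sbml_model.getId() or Path(path).stem)


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sanitize(model.model_id))
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(True)
    comp = sm.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    comp.setSize(1.0)
    for mid in model.metabolite_ids:
        sp = sm.createSpecies()
        sp.setId(_sanitize(mid))
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    tag_of = {rid: tag for tag, rid in model.tags.items()}
    for j, rid in enumerate(model.reaction_ids):
        rxn = sm.createReaction()
        rxn.setId(_sanitize(rid))
        rxn.setReversible(bool(model.lb[j] < 0))
        rxn.setFast(False)
        for i in np.where(model.S[:, j] != 0)[0]:
            c = model.S[i, j]
            sr = rxn.createReactant() if c < 0 else rxn.createProduct()
            sr.setSpecies(_sanitize(model.metabolite_ids[i]))
            sr.setStoichiometry(abs(float(c)))
            sr.setConstant(True)
        rfbc = rxn.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(float(model.lb[j])))
        rfbc.setUpperFluxBound(bound_param(float(model.ub[j])))
        if rid in tag_of:
            rxn.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>netgs_tag: {tag_of[rid]}</p></body>"
            )
    obj = fbc.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(_sanitize(model.biomass_id))
    fo.setCoefficient(1.0)
    fbc.setActiveObjectiveId("obj")
    libsbml.writeSBMLToFile(doc, str(path))


# ----------------------------------------------------------------------
# Public entry points
# ----------------------------------------------------------------------

_READERS = {"tsv": _read_tsv, "json": _read_json, "sbml": _read_sbml}
_WRITERS = {"tsv": _write_tsv, "json": _write_json, "sbml": _write_sbml}


def read_model(path, dialect: str = "tsv") -> MetabolicModel:
    """Read a metabolic model from ``path`` in the named dialect."""
    if dialect not in _READERS:
        raise FormatError(f"unknown dialect {dialect!r}; choose from {sorted(_READERS)}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return _READERS[dialect](path)


def write_model(model: MetabolicModel, path, dialect: str = "tsv") -> None:
    if dialect not in _WRITERS:
        raise FormatError(f"unknown dialect {dialect!r}; choose from {sorted(_WRITERS)}")
    _WRITERS[dialect](model, Path(path))


# ----------------------------------------------------------------------
# Compositions, fluxes, genotypes, traits
# ----------------------------------------------------------------------

def read_biomass_csv(path) -> dict[tuple[str, str], BiomassComposition]:
    """Read ``biomass.csv`` (metabolite, coefficient, accession, environment)."""
    table = pd.read_csv(path)
    required = {"metabolite", "coefficient", "accession", "environment"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: dict[tuple[str, str], BiomassComposition] = {}
    for (acc, env), group in table.groupby(["accession", "environment"], sort=False):
        out[(str(acc), str(env))] = BiomassComposition(
            dict(zip(group["metabolite"].astype(str), group["coefficient"].astype(float))),
            accession_id=str(acc),
            environment_id=str(env),
        )
    return out


def write_biomass_csv(comps, path) -> None:
    rows = [
        {"metabolite": m, "coefficient": c, "accession": comp.accession_id,
         "environment": comp.environment_id}
        for comp in comps
        for m, c in comp.coefficients.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_flux_tsv(flux: FluxDistribution, model: MetabolicModel, path) -> None:
    tol = 1e-9
    pd.DataFrame(
        {
            "reaction_id": model.reaction_ids,
            "flux": [repr(float(v)) for v in flux.values],
            "lb_active": np.abs(flux.values - model.lb) < tol,
            "ub_active": np.abs(flux.values - model.ub) < tol,
        }
    ).to_csv(path, sep="\t", index=False)


def read_flux_tsv(path, model: MetabolicModel, label: str = "") -> FluxDistribution:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    order = {rid: i for i, rid in enumerate(model.reaction_ids)}
    table = table.sort_values("reaction_id", key=lambda s: s.map(order))
    if list(table["reaction_id"]) != model.reaction_ids:
        raise FormatError(f"{path}: reaction ids do not match model {model.model_id!r}")
    return FluxDistribution(
        table["flux"].astype(float).to_numpy(), model_ref=model.model_id, label=label,
        reaction_ids=model.reaction_ids,
    )


def read_genotype_csv(path) -> pd.DataFrame:
    """Accessions x markers dosage table; first column = accession id."""
    table = pd.read_csv(path)
    table = table.set_index(table.columns[0])
    table.index = table.index.astype(str)
    return table.astype(float)


def read_genotype_vcf(path) -> pd.DataFrame:
    """Extract a dosage matrix from the GT fields of a VCF (biallelic sites only)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers, columns, skipped = [], [], 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        name = variant.ID or f"{variant.CHROM}_{variant.POS}"
        dosages = np.array(
            [gt[0] + gt[1] if gt[0] >= 0 and gt[1] >= 0 else np.nan
             for gt in variant.genotypes],
            dtype=float,
        )
        markers.append(name)
        columns.append(dosages)
    if skipped:
        import warnings

        warnings.warn(f"skipped {skipped} non-biallelic records", stacklevel=2)
    return pd.DataFrame(np.column_stack(columns) if columns else np.empty((len(samples), 0)),
                        index=samples, columns=markers)


def read_trait_csv(path) -> pd.DataFrame:
    """Trait table with columns accession, trait, value, environment."""
    table = pd.read_csv(path)
    missing = {"accession", "trait", "value", "environment"} - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    table["accession"] = table["accession"].astype(str)
    return table
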