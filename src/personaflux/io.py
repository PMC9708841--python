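"""Model serialisation: SBML (Level 3 + FBC) and a mirror JSON dialect.

The JSON dialect carries exactly the content the package uses from SBML —
ids, compartments, boundary flags, bounds, stoichiometry, flattened gene
sets, subsystems — so test fixtures need no SBML toolchain.  SBML reading and
writing is delegated to cobrapy, with a small libsbml pass to preserve the
``boundaryCondition`` species attribute that cobrapy does not model.
"""

from __future__ import annotations

import json
from pathlib import Path

from .exceptions import ModelFormatError, ValidationError
from .network import DEFAULT_BOUND, Metabolite, MetabolicNetwork, Reaction

_SBML_SUFFIXES = {".xml", ".sbml"}


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    if path.suffix in _SBML_SUFFIXES:
        return "sbml"
    if path.suffix == ".json":
        return "json"
    raise ModelFormatError(f"cannot infer model format from {path.name!r}; pass format=")


def read_model(path, format: str | None = None) -> MetabolicNetwork:
    """Read a metabolic network from SBML or the package JSON dialect."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "json":
        return _read_json(path)
    if fmt == "sbml":
        return _read_sbml(path)
    raise ModelFormatError(f"unknown model format {fmt!r}")


def write_model(net: MetabolicNetwork, path, format: str | None = None) -> None:
    """Write a metabolic network to SBML or the package JSON dialect."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        _write_json(net, path)
    elif fmt == "sbml":
        _write_sbml(net, path)
    else:
        raise ModelFormatError(f"unknown model format {fmt!r}")


# -- JSON dialect ----------------------------------------------------------


def network_to_dict(net: MetabolicNetwork) -> dict:
    return {
        "id": net.id,
        "metabolites": [
            {"id": m.id, "compartment": m.compartment, "boundary": m.boundary}
            for m in net.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "subsystem": r.subsystem,
                "lower_bound": r.lb,
                "upper_bound": r.ub,
                "metabolites": r.stoich,
                "genes": sorted(r.genes),
            }
            for r in net.reactions
        ],
        "inequalities": [
            {"coefficients": coeffs, "upper": upper} for coeffs, upper in net.inequalities
        ],
    }


def network_from_dict(doc: dict) -> MetabolicNetwork:
    try:
        metabolites = [
            Metabolite(m["id"], m.get("compartment", ""), bool(m.get("boundary", False)))
            for m in doc["metabolites"]
        ]
        reactions = [
            Reaction(
                r["id"],
                {k: float(v) for k, v in r.get("metabolites", {}).items()},
                lb=float(r.get("lower_bound", 0.0)),
                ub=float(r.get("upper_bound", DEFAULT_BOUND)),
                name=r.get("name", ""),
                subsystem=r.get("subsystem", ""),
                genes=frozenset(r.get("genes", ())),
            )
            for r in doc["reactions"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed model document: {exc!r}") from exc
    inequalities = [
        (dict(row["coefficients"]), float(row["upper"])) for row in doc.get("inequalities", [])
    ]
    return MetabolicNetwork(metabolites, reactions, inequalities, id=doc.get("id", ""))


def _read_json(path: Path) -> MetabolicNetwork:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path.name}: invalid JSON ({exc})") from exc
    return network_from_dict(doc)


def _write_json(net: MetabolicNetwork, path: Path) -> None:
    path.write_text(json.dumps(network_to_dict(net), indent=1))


# -- SBML ------------------------------------------------------------------


def _read_sbml(path: Path) -> MetabolicNetwork:
    import cobra.io
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise ModelFormatError(f"{path.name}: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"{path.name}: no model element")
    boundary_flags = {
        sp.getId(): sp.getBoundaryCondition() for sp in sbml_model.getListOfSpecies()
    }
    try:
        cb = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises several parse exception types
        raise ModelFormatError(f"{path.name}: {exc}") from exc

    # cobra strips the SBML "M_" prefix; the libsbml flag map may keep it
    metabolites = [
        Metabolite(
            m.id,
            m.compartment or "",
            boundary=boundary_flags.get("M_" + m.id, boundary_flags.get(m.id, False)),
        )
        for m in cb.metabolites
    ]
    reactions = [
        Reaction(
            r.id,
            {m.id: coef for m, coef in r.metabolites.items()},
            lb=r.lower_bound,
            ub=r.upper_bound,
            name=r.name or r.id,
            subsystem=r.subsystem or r.notes.get("SUBSYSTEM", ""),
            genes=frozenset(g.id for g in r.genes),
        )
        for r in cb.reactions
    ]
    return MetabolicNetwork(metabolites, reactions, id=cb.id or path.stem)


def _write_sbml(net: MetabolicNetwork, path: Path) -> None:
    import cobra
    import libsbml

    cb = cobra.Model(net.id or "model")
    compartments = {m.compartment or "c" for m in net.metabolites}
    cb.compartments = {c: c for c in compartments}
    mets = {}
    for m in net.metabolites:
        cm = cobra.Metabolite(m.id, compartment=m.compartment or "c")
        mets[m.id] = cm
    cb.add_metabolites(list(mets.values()))
    rxns = []
    for r in net.reactions:
        cr = cobra.Reaction(r.id, name=r.name, lower_bound=r.lb, upper_bound=r.ub)
        cr.subsystem = r.subsystem
        if r.subsystem:  # cobra only round-trips the subsystem through notes
            cr.notes["SUBSYSTEM"] = r.subsystem
        rxns.append(cr)
    cb.add_reactions(rxns)
    for r in net.reactions:
        cr = cb.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[mid]: coef for mid, coef in r.stoich.items()})
        if r.genes:
            cr.gene_reaction_rule = " or ".join(sorted(r.genes))
    cobra.io.write_sbml_model(cb, str(path))

    boundary = {m.id for m in net.metabolites if m.boundary}
    if boundary:
        doc = libsbml.readSBMLFromFile(str(path))
        model = doc.getModel()
        for sp in model.getListOfSpecies():
            sid = sp.getId()
            bare = sid[2:] if sid.startswith("M_") else sid
            if bare in boundary or sid in boundary:
                sp.setBoundaryCondition(True)
        libsbml.writeSBMLToFile(doc, str(path))


def validate_model_file(path, format: str | None = None) -> MetabolicNetwork:
    """Read a model and raise ValidationError/ModelFormatError on any defect."""
    net = read_model(path, format=format)
    net.validate()
    return net


__all__ = [
    "read_model",
    "write_model",
    "network_to_dict",
    "network_from_dict",
    "validate_model_file",
    "ModelFormatError",
    "ValidationError",
]
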