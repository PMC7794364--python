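"""Model readers and writers.

Primary interchange dialect is COBRA-style JSON (the format cobrapy
writes): top-level ``metabolites``, ``reactions``, each reaction carrying
``metabolites`` (stoichiometry), ``lower_bound``, ``upper_bound``,
``gene_reaction_rule`` and ``objective_coefficient``.  A TSV triple
(metabolites.tsv + reactions.tsv, stoichiometry and GPR inline) is
supported for hand-written toy models, and SBML Level 3 + FBC can be
imported when python-libsbml is available.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .model import MetabolicModel, Metabolite, Reaction, ValidationError, validate_model

__all__ = ["load_model", "save_model", "model_to_dict", "model_from_dict"]


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load and validate a model from ``json``, ``tsv`` or ``sbml``.

    ``format=None`` infers from the suffix (``.json``, ``.tsv``,
    ``.xml``/``.sbml``).  For ``tsv``, ``path`` is the reactions table;
    a ``<stem>.metabolites.tsv`` sibling, if present, supplies
    metabolite names/compartments.  Raises :class:`ValidationError` if
    the parsed model violates any structural invariant.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".json": "json", ".tsv": "tsv", ".xml": "sbml", ".sbml": "sbml"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer model format from suffix {suffix!r}")
    if format == "json":
        model = _load_json(path)
    elif format == "tsv":
        model = _load_tsv(path)
    elif format == "sbml":
        model = _load_sbml(path)
    else:
        raise ValueError(f"unknown model format {format!r}")
    violations = validate_model(model)
    if violations:
        raise ValidationError(
            f"model {path.name!r} failed validation:\n  " + "\n  ".join(violations)
        )
    return model


def save_model(model: MetabolicModel, path: str | Path, format: str = "json") -> None:
    """Write a model; JSON round-trips losslessly through
    :func:`load_model` (stoichiometry, bounds, GPR, objective)."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))
    elif format == "tsv":
        _save_tsv(model, path)
    else:
        raise ValueError(f"unsupported save format {format!r}")


# ---------------------------------------------------------------------------
# COBRA-dialect JSON
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.name,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr,
                "objective_coefficient": model.objective.get(r.id, 0.0),
            }
            for r in model.reactions
        ],
        "genes": [],
        "version": "1",
    }


def model_from_dict(payload: dict) -> MetabolicModel:
    try:
        metabolites = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c") or "c",
            )
            for m in payload["metabolites"]
        ]
        reactions = []
        objective: dict[str, float] = {}
        for r in payload["reactions"]:
            reactions.append(
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                    lower_bound=float(r.get("lower_bound", -1000.0)),
                    upper_bound=float(r.get("upper_bound", 1000.0)),
                    gpr=r.get("gene_reaction_rule", "") or "",
                )
            )
            coeff = float(r.get("objective_coefficient", 0.0))
            if coeff != 0.0:
                objective[r["id"]] = coeff
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"malformed model document: {exc}") from exc
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective=objective,
        name=payload.get("id", "") or "",
    )


def _load_json(path: Path) -> MetabolicModel:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path.name}: JSON parse error at line {exc.lineno}: {exc.msg}")
    return model_from_dict(payload)


# ---------------------------------------------------------------------------
# TSV triple (hand-written toys)
# ---------------------------------------------------------------------------
#
# reactions.tsv columns: id, stoichiometry, lower_bound, upper_bound,
# gpr, objective.  Stoichiometry syntax: "glc_c:-1; pyr_c:2".

def _parse_stoich(text: str) -> dict[str, float]:
    stoich: dict[str, float] = {}
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        met, _, coeff = part.rpartition(":")
        if not met:
            raise ValidationError(f"bad stoichiometry term {part!r}")
        stoich[met.strip()] = float(coeff)
    return stoich


def _load_tsv(path: Path) -> MetabolicModel:
    rxn_df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    met_path = path.with_suffix("").with_suffix(".metabolites.tsv")
    met_info: dict[str, tuple[str, str]] = {}
    if met_path.exists():
        met_df = pd.read_csv(met_path, sep="\t", dtype=str).fillna("")
        for _, row in met_df.iterrows():
            met_info[row["id"]] = (row.get("name", ""), row.get("compartment", "") or "c")

    reactions, objective = [], {}
    met_ids: list[str] = []
    for _, row in rxn_df.iterrows():
        stoich = _parse_stoich(row["stoichiometry"])
        for mid in stoich:
            if mid not in met_ids:
                met_ids.append(mid)
        reactions.append(
            Reaction(
                id=row["id"],
                stoichiometry=stoich,
                lower_bound=float(row.get("lower_bound", -1000) or -1000),
                upper_bound=float(row.get("upper_bound", 1000) or 1000),
                gpr=row.get("gpr", ""),
            )
        )
        if row.get("objective", ""):
            objective[row["id"]] = float(row["objective"])
    metabolites = []
    for mid in met_ids:
        name, comp = met_info.get(mid, ("", _infer_compartment(mid)))
        metabolites.append(Metabolite(id=mid, name=name, compartment=comp))
    # any metabolites declared but unused still belong to the model
    for mid, (name, comp) in met_info.items():
        if mid not in met_ids:
            metabolites.append(Metabolite(id=mid, name=name, compartment=comp))
    return MetabolicModel(metabolites=metabolites, reactions=reactions,
                          objective=objective, name=path.stem)


def _infer_compartment(met_id: str) -> str:
    # trailing "_x" tag is the usual compartment suffix convention
    if len(met_id) > 2 and met_id[-2] == "_":
        return met_id[-1]
    return "c"


def _save_tsv(model: MetabolicModel, path: Path) -> None:
    rows = []
    for r in model.reactions:
        rows.append(
            {
                "id": r.id,
                "stoichiometry": "; ".join(f"{m}:{c:g}" for m, c in r.stoichiometry.items()),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr,
                "objective": model.objective.get(r.id, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    met_rows = [
        {"id": m.id, "name": m.name, "compartment": m.compartment} for m in model.metabolites
    ]
    pd.DataFrame(met_rows).to_csv(
        path.with_suffix("").with_suffix(".metabolites.tsv"), sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC import (optional)
# ---------------------------------------------------------------------------

def _load_sbml(path: Path) -> MetabolicModel:
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "SBML import requires python-libsbml (install the 'sbml' extra)"
        ) from exc
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ValidationError(f"{path.name}: SBML parse error: {err.getMessage()}")
    sbml_model = doc.getModel()
    fbc = sbml_model.getPlugin("fbc")

    metabolites = [
        Metabolite(
            id=sp.getId(),
            name=sp.getName() or "",
            compartment=sp.getCompartment() or "c",
        )
        for sp in sbml_model.getListOfSpecies()
    ]

    def _param(pid: str, default: float) -> float:
        p = sbml_model.getParameter(pid) if pid else None
        return p.getValue() if p is not None else default

    objective: dict[str, float] = {}
    if fbc is not None and fbc.getActiveObjective() is not None:
        for fo in fbc.getActiveObjective().getListOfFluxObjectives():
            objective[fo.getReaction()] = fo.getCoefficient()

    reactions = []
    for rx in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for sr in rx.getListOfReactants():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for sr in rx.getListOfProducts():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None:
            lb = _param(rfbc.getLowerFluxBound(), -1000.0)
            ub = _param(rfbc.getUpperFluxBound(), 1000.0)
            gpa = rfbc.getGeneProductAssociation()
            gpr = _gpa_to_infix(gpa.getAssociation(), fbc) if gpa is not None else ""
        else:
            lb, ub, gpr = (-1000.0 if rx.getReversible() else 0.0), 1000.0, ""
        reactions.append(
            Reaction(id=rx.getId(), name=rx.getName() or "", stoichiometry=stoich,
                     lower_bound=lb, upper_bound=ub, gpr=gpr)
        )
    return MetabolicModel(metabolites=metabolites, reactions=reactions,
                          objective=objective, name=sbml_model.getId() or path.stem)


def _gpa_to_infix(assoc, fbc) -> str:
    import libsbml

    if assoc is None:
        return ""
    if assoc.isGeneProductRef():
        gp = fbc.getGeneProduct(assoc.getGeneProduct())
        return gp.getLabel() or gp.getId() if gp is not None else assoc.getGeneProduct()
    op = " and " if assoc.isFbcAnd() else " or "
    parts = [
        _gpa_to_infix(assoc.getAssociation(i), fbc)
        for i in range(assoc.getNumAssociations())
    ]
    return "(" + op.join(parts) + ")"
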