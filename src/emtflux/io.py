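"""Readers and writers for the model formats the pipeline touches.

Three formats are supported:

``json``
    Canonical, versioned round-trip format; the reference serialisation.
``table``
    The tabular dialect used for pathway spreadsheets: either a directory
    of TSV files or an ``.xlsx`` workbook with sheets named ``Reactions``,
    ``Species``, ``GPRs`` and optionally ``Modifiers``, ``Activators``,
    ``Inhibitors`` and ``Proteins`` (the protein→gene map).
``sbml``
    SBML Level 2/3 import (species, reactions, listOfModifiers) via
    libSBML.  Import only: regulatory sign information and bounds are not
    part of plain SBML, so modifiers are returned as annotation and bounds
    default to [0, 1000] AU pending :func:`~emtflux.reconstruction.convert_pathway`.

Every reader returns ``(model, annotation)`` where ``annotation`` is a
:class:`~emtflux.model.RegulatoryAnnotation` or ``None`` when the source
carries no regulatory layer.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from .model import (
    DEFAULT_UPPER_BOUND,
    ModelValidationError,
    Reaction,
    RegulatoryAnnotation,
    Species,
    StoichiometricModel,
)

__all__ = ["read_model", "write_model", "parse_formula", "ModelParseError"]

_JSON_FORMAT = "emtflux-model"
_JSON_VERSION = 1

_TABLE_SHEETS = ("Reactions", "Species", "GPRs", "Modifiers", "Activators", "Inhibitors", "Proteins")


class ModelParseError(ValueError):
    """A model file is malformed; the message names the file and element."""


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "table"
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xlsx", ".xls", ".tsv"):
        return "table"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ValueError(f"cannot infer model format from {path.name!r}; pass format=")


def read_model(
    path: str | Path, format: str | None = None
) -> tuple[StoichiometricModel, RegulatoryAnnotation | None]:
    """Read a model (and its regulatory annotation, if present) from disk."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "json":
        return _read_json(path)
    if fmt == "table":
        return _read_table(path)
    if fmt == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(
    model: StoichiometricModel,
    path: str | Path,
    format: str | None = None,
    annotation: RegulatoryAnnotation | None = None,
) -> Path:
    """Write a model so that reading the file back yields an equal model."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "json":
        return _write_json(model, path, annotation)
    if fmt == "table":
        return _write_table(model, path, annotation)
    raise ValueError(
        f"unsupported write format {fmt!r}: models are exported as 'json' or 'table'"
    )


# ---------------------------------------------------------------------------
# formula strings


_ARROWS = ("->", "→", "=>")


def parse_formula(text: str) -> dict[str, float]:
    """Parse ``A + 2 B -> C`` into signed stoichiometry.

    An empty side denotes a boundary: ``-> A`` is uptake, ``A ->`` secretion.
    """
    for arrow in _ARROWS:
        if arrow in text:
            left, right = text.split(arrow, 1)
            break
    else:
        raise ModelParseError(f"no reaction arrow in formula {text!r}")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in re.split(r"\s*\+\s*", side):
            parts = term.split()
            if len(parts) == 1:
                coef, sid = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError:
                    raise ModelParseError(
                        f"bad coefficient {parts[0]!r} in formula {text!r}"
                    ) from None
                sid = parts[1]
            else:
                raise ModelParseError(f"cannot parse term {term!r} in formula {text!r}")
            stoich[sid] = stoich.get(sid, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    zeros = [s for s, c in stoich.items() if c == 0]
    if zeros:
        raise ModelParseError(
            f"species {zeros} cancel to zero stoichiometry in formula {text!r}"
        )
    if not stoich:
        raise ModelParseError(f"formula {text!r} has no species")
    return stoich


def format_formula(rxn: Reaction) -> str:
    return rxn.formula()


# ---------------------------------------------------------------------------
# JSON


def _annotation_to_dict(ann: RegulatoryAnnotation) -> dict:
    return {
        "modifiers": ann.modifiers,
        "activators": ann.activators,
        "inhibitors": ann.inhibitors,
        "protein_genes": ann.protein_genes,
        "protein_relation": ann.protein_relation,
    }


def _annotation_from_dict(d: dict) -> RegulatoryAnnotation:
    return RegulatoryAnnotation(
        modifiers={k: list(v) for k, v in d.get("modifiers", {}).items()},
        activators={k: list(v) for k, v in d.get("activators", {}).items()},
        inhibitors={k: list(v) for k, v in d.get("inhibitors", {}).items()},
        protein_genes={k: list(v) for k, v in d.get("protein_genes", {}).items()},
        protein_relation=dict(d.get("protein_relation", {})),
    )


def model_to_dict(
    model: StoichiometricModel, annotation: RegulatoryAnnotation | None = None
) -> dict:
    doc = {
        "format": _JSON_FORMAT,
        "version": _JSON_VERSION,
        "metadata": dict(model.metadata),
        "species": [{"id": s.id, "name": s.name, "role": s.role} for s in model.species],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr_string,
            }
            for r in model.reactions
        ],
    }
    if annotation is not None:
        doc["annotation"] = _annotation_to_dict(annotation)
    return doc


def model_from_dict(doc: dict) -> tuple[StoichiometricModel, RegulatoryAnnotation | None]:
    if doc.get("format") != _JSON_FORMAT:
        raise ModelParseError(
            f"not an {_JSON_FORMAT} document (format={doc.get('format')!r})"
        )
    try:
        species = [
            Species(id=s["id"], name=s.get("name", ""), role=s.get("role", "signaling-component"))
            for s in doc["species"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry=r["stoichiometry"],
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", DEFAULT_UPPER_BOUND)),
                gpr=r.get("gpr") or None,
            )
            for r in doc["reactions"]
        ]
    except (KeyError, TypeError, ModelValidationError) as exc:
        raise ModelParseError(f"malformed model document: {exc}") from exc
    model = StoichiometricModel(species, reactions, doc.get("metadata"))
    ann = _annotation_from_dict(doc["annotation"]) if "annotation" in doc else None
    return model, ann


def _read_json(path: Path) -> tuple[StoichiometricModel, RegulatoryAnnotation | None]:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path.name}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    try:
        return model_from_dict(doc)
    except ModelParseError as exc:
        raise ModelParseError(f"{path.name}: {exc}") from exc


def _write_json(
    model: StoichiometricModel, path: Path, annotation: RegulatoryAnnotation | None
) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(model_to_dict(model, annotation), indent=1, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# table dialect (TSV directory or workbook)


def _rows_to_model(
    sheets: dict[str, list[dict[str, str]]], origin: str
) -> tuple[StoichiometricModel, RegulatoryAnnotation | None]:
    def need(sheet: str) -> list[dict[str, str]]:
        if sheet not in sheets:
            raise ModelParseError(f"{origin}: missing required sheet/table {sheet!r}")
        return sheets[sheet]

    species = []
    for i, row in enumerate(need("Species"), start=2):
        try:
            species.append(
                Species(
                    id=row["species_id"],
                    name=row.get("name", "") or "",
                    role=row.get("role") or "signaling-component",
                )
            )
        except (KeyError, ModelValidationError) as exc:
            raise ModelParseError(f"{origin}: Species row {i}: {exc}") from exc

    reactions = []
    for i, row in enumerate(need("Reactions"), start=2):
        try:
            reactions.append(
                Reaction(
                    id=row["reaction_id"],
                    name=row.get("name", "") or "",
                    stoichiometry=parse_formula(row["formula"]),
                    lower_bound=float(row.get("lower_bound") or 0.0),
                    upper_bound=float(row.get("upper_bound") or DEFAULT_UPPER_BOUND),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ModelParseError(f"{origin}: Reactions row {i}: {exc}") from exc

    model = StoichiometricModel(species, reactions)
    by_id = {r.id: r for r in model.reactions}
    for i, row in enumerate(sheets.get("GPRs", []), start=2):
        rid, text = row.get("reaction_id", ""), (row.get("gpr") or "").strip()
        if rid not in by_id:
            raise ModelParseError(f"{origin}: GPRs row {i}: unknown reaction {rid!r}")
        if text:
            from .gpr import parse_gpr

            try:
                by_id[rid].gpr = parse_gpr(text)
            except ValueError as exc:
                raise ModelParseError(f"{origin}: GPRs row {i}: {exc}") from exc

    ann = None
    reg_sheets = [s for s in ("Modifiers", "Activators", "Inhibitors", "Proteins") if s in sheets]
    if reg_sheets:
        ann = RegulatoryAnnotation()
        for sheet, table in (
            ("Modifiers", ann.modifiers),
            ("Activators", ann.activators),
            ("Inhibitors", ann.inhibitors),
        ):
            for i, row in enumerate(sheets.get(sheet, []), start=2):
                rid, pid = row.get("reaction_id", ""), row.get("protein_id", "")
                if rid not in by_id:
                    raise ModelParseError(f"{origin}: {sheet} row {i}: unknown reaction {rid!r}")
                table.setdefault(rid, []).append(pid)
        for i, row in enumerate(sheets.get("Proteins", []), start=2):
            pid = row.get("protein_id", "")
            genes = [g for g in (row.get("genes") or "").split(";") if g]
            if not pid or not genes:
                raise ModelParseError(f"{origin}: Proteins row {i}: needs protein_id and genes")
            ann.protein_genes[pid] = genes
            ann.protein_relation[pid] = row.get("relation") or "complex"
    return model, ann


def _model_to_rows(
    model: StoichiometricModel, annotation: RegulatoryAnnotation | None
) -> dict[str, list[dict[str, str]]]:
    sheets: dict[str, list[dict[str, str]]] = {
        "Species": [
            {"species_id": s.id, "name": s.name, "role": s.role} for s in model.species
        ],
        "Reactions": [
            {
                "reaction_id": r.id,
                "name": r.name,
                "formula": r.formula(),
                "lower_bound": repr(r.lower_bound),
                "upper_bound": repr(r.upper_bound),
            }
            for r in model.reactions
        ],
        "GPRs": [
            {"reaction_id": r.id, "gpr": r.gpr_string} for r in model.reactions
        ],
    }
    if annotation is not None:
        for sheet, table in (
            ("Modifiers", annotation.modifiers),
            ("Activators", annotation.activators),
            ("Inhibitors", annotation.inhibitors),
        ):
            sheets[sheet] = [
                {"reaction_id": rid, "protein_id": pid}
                for rid in table
                for pid in table[rid]
            ]
        sheets["Proteins"] = [
            {
                "protein_id": pid,
                "genes": ";".join(genes),
                "relation": annotation.protein_relation.get(pid, "complex"),
            }
            for pid, genes in annotation.protein_genes.items()
        ]
    return sheets


def _read_table(path: Path) -> tuple[StoichiometricModel, RegulatoryAnnotation | None]:
    if path.is_dir():
        sheets: dict[str, list[dict[str, str]]] = {}
        for sheet in _TABLE_SHEETS:
            f = path / f"{sheet}.tsv"
            if f.exists():
                sheets[sheet] = _read_tsv(f)
        return _rows_to_model(sheets, str(path))
    if path.suffix.lower() in (".xlsx", ".xls"):
        return _rows_to_model(_read_workbook(path), path.name)
    raise ModelParseError(
        f"{path}: table format expects a directory of TSVs or an .xlsx workbook"
    )


def _read_tsv(path: Path) -> list[dict[str, str]]:
    lines = path.read_text().splitlines()
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        values = line.split("\t")
        rows.append({h: (values[k] if k < len(values) else "") for k, h in enumerate(header)})
    return rows


def _read_workbook(path: Path) -> dict[str, list[dict[str, str]]]:
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    sheets: dict[str, list[dict[str, str]]] = {}
    for name in wb.sheetnames:
        ws = wb[name]
        rows = list(ws.iter_rows(values_only=True))
        if not rows:
            continue
        header = [str(h) if h is not None else "" for h in rows[0]]
        sheets[name] = [
            {
                h: ("" if v is None else str(v))
                for h, v in zip(header, row)
            }
            for row in rows[1:]
            if any(v is not None and str(v).strip() for v in row)
        ]
    wb.close()
    return sheets


def _write_table(
    model: StoichiometricModel, path: Path, annotation: RegulatoryAnnotation | None
) -> Path:
    sheets = _model_to_rows(model, annotation)
    if path.suffix.lower() in (".xlsx", ".xls"):
        import openpyxl

        wb = openpyxl.Workbook()
        wb.remove(wb.active)
        for name, rows in sheets.items():
            ws = wb.create_sheet(name)
            header = list(rows[0].keys()) if rows else []
            if header:
                ws.append(header)
            for row in rows:
                ws.append([row.get(h, "") for h in header])
        path.parent.mkdir(parents=True, exist_ok=True)
        wb.save(path)
        return path
    path.mkdir(parents=True, exist_ok=True)
    for name, rows in sheets.items():
        header = list(rows[0].keys()) if rows else []
        lines = ["\t".join(header)]
        lines += ["\t".join(str(row.get(h, "")) for h in header) for row in rows]
        (path / f"{name}.tsv").write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# SBML import


def _read_sbml(path: Path) -> tuple[StoichiometricModel, RegulatoryAnnotation | None]:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(
            f"{path.name}: SBML error at line {err.getLine()}: {err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path.name}: no <model> element")

    species = [
        Species(id=s.getId(), name=s.getName() or "")
        for s in sbml_model.getListOfSpecies()
    ]
    reactions = []
    ann = RegulatoryAnnotation()
    has_modifiers = False
    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rxn.getListOfReactants():
            c = ref.getStoichiometry()
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - (
                c if c == c and c != 0 else 1.0
            )
        for ref in rxn.getListOfProducts():
            c = ref.getStoichiometry()
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + (
                c if c == c and c != 0 else 1.0
            )
        stoich = {s: c for s, c in stoich.items() if c != 0}
        if not stoich:
            raise ModelParseError(
                f"{path.name}: reaction {rxn.getId()!r} has empty stoichiometry"
            )
        try:
            reactions.append(
                Reaction(
                    id=rxn.getId(),
                    name=rxn.getName() or "",
                    stoichiometry=stoich,
                    lower_bound=0.0,
                    upper_bound=DEFAULT_UPPER_BOUND,
                )
            )
        except ModelValidationError as exc:
            raise ModelParseError(f"{path.name}: reaction {rxn.getId()!r}: {exc}") from exc
        mods = [m.getSpecies() for m in rxn.getListOfModifiers()]
        if mods:
            has_modifiers = True
            ann.modifiers[rxn.getId()] = mods

    model = StoichiometricModel(
        species, reactions, {"id": sbml_model.getId() or path.stem, "source": path.name}
    )
    return model, (ann if has_modifiers else None)
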