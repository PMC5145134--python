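"""Readers and writers for the standard formats the simulator touches.

* StochKit2-style XML for reaction-network models (lossless round trip for
  every model field; unknown elements are dropped with a warning).
* An SBML Level 2/3 subset: species, compartments, global and local
  parameters, reactions with MathML kinetic laws.  Kinetic laws matching the
  mass-action pattern ``k * prod(reactants)`` import as mass-action
  channels; anything else becomes a custom propensity.  Unsupported features
  (function definitions, events, rules, extra compartments) each produce one
  warning naming the feature and the element id.
* The DOLFIN XML mesh dialect (vertices + tetrahedron cells), extended with
  an optional vertex subdomain block so generated geometries round trip.
* Result export: StochKit2-style whitespace-delimited flat files for
  well-mixed ensembles, and CSV or legacy ASCII VTK (unstructured grid,
  version 3.0) for spatial results.  VTK point data carries per-species
  counts and concentrations (count / (N_A * v_i)).

Numeric serialization uses ``repr`` (shortest round-trip decimal), so
re-imported doubles are bit-identical.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import sympy
from lxml import etree

from .expressions import ExpressionError, parse_expression
from .mesh import Mesh
from .model import (
    AVOGADRO,
    CUSTOM,
    MASS_ACTION,
    Parameter,
    Reaction,
    ReactionNetworkModel,
    Species,
)
from .results import Ensemble, SpatialResult

__all__ = [
    "read_stochkit_xml",
    "write_stochkit_xml",
    "import_sbml",
    "read_dolfin_xml_mesh",
    "write_dolfin_xml_mesh",
    "export_wellmixed",
    "export_spatial",
    "ModelIOError",
]


class ModelIOError(ValueError):
    pass


def _num(text: str) -> float:
    return float(text.strip())


# ---------------------------------------------------------------------------
# StochKit2 XML

_KNOWN_MODEL_CHILDREN = {
    "Name", "Description", "Units", "Volume", "NumberOfSpecies",
    "NumberOfReactions", "SpeciesList", "ParametersList", "ReactionsList",
}


def read_stochkit_xml(document) -> ReactionNetworkModel:
    """Parse a StochKit2-style model document (path, bytes, or XML text)."""
    root = _parse_xml(document)
    if root.tag != "Model":
        raise ModelIOError(f"expected root element 'Model', found {root.tag!r}")
    for required in ("SpeciesList", "ParametersList", "ReactionsList"):
        if root.find(required) is None:
            raise ModelIOError(f"missing required element {required!r}")

    for child in root:
        if isinstance(child.tag, str) and child.tag not in _KNOWN_MODEL_CHILDREN:
            warnings.warn(f"dropped unknown element {child.tag!r}", stacklevel=2)

    name = root.findtext("Name", default="model").strip()
    units = root.findtext("Units", default="population").strip()
    volume_text = root.findtext("Volume")
    volume = _num(volume_text) if volume_text is not None else None

    species = []
    for el in root.find("SpeciesList").findall("Species"):
        allowed = el.findtext("AllowedSubdomains", default="").split()
        species.append(
            Species(
                name=el.findtext("Id").strip(),
                initial_value=_num(el.findtext("InitialPopulation", default="0")),
                diffusion_coefficient=_num(el.findtext("DiffusionCoefficient", default="0")),
                allowed_subdomains=frozenset(allowed),
            )
        )
    parameters = [
        Parameter(
            name=el.findtext("Id").strip(),
            value=_num(el.findtext("Expression", default="0")),
            unit=el.findtext("Unit", default="dimensionless").strip(),
        )
        for el in root.find("ParametersList").findall("Parameter")
    ]

    reactions = []
    for el in root.find("ReactionsList").findall("Reaction"):
        rname = el.findtext("Id").strip()
        rtype = el.findtext("Type", default="mass-action").strip()
        reactants = _read_stoich(el.find("Reactants"))
        products = _read_stoich(el.find("Products"))
        restrict = frozenset(el.findtext("RestrictTo", default="").split())
        if rtype == "mass-action":
            reactions.append(
                Reaction(rname, reactants, products, kinetics=MASS_ACTION,
                         rate_parameter=el.findtext("Rate").strip(),
                         restrict_to=restrict)
            )
        elif rtype == "customized":
            reactions.append(
                Reaction(rname, reactants, products, kinetics=CUSTOM,
                         propensity=el.findtext("PropensityFunction").strip(),
                         restrict_to=restrict)
            )
        else:
            raise ModelIOError(f"unknown reaction Type {rtype!r} in reaction {rname!r}")

    return ReactionNetworkModel(
        name=name, units_mode=units, volume=volume,
        species=species, parameters=parameters, reactions=reactions,
    )


def _read_stoich(el) -> dict:
    stoich = {}
    if el is None:
        return stoich
    for ref in el.findall("SpeciesReference"):
        stoich[ref.get("id")] = stoich.get(ref.get("id"), 0) + int(ref.get("stoichiometry", "1"))
    return stoich


def write_stochkit_xml(model: ReactionNetworkModel, path=None) -> str:
    """Serialize a model; returns the document text (and writes it if a path
    is given).  ``read_stochkit_xml(write_stochkit_xml(m))`` is
    field-identical to ``m``."""
    root = etree.Element("Model")
    etree.SubElement(root, "Name").text = model.name
    etree.SubElement(root, "Units").text = model.units_mode
    if model.volume is not None:
        etree.SubElement(root, "Volume").text = repr(float(model.volume))
    etree.SubElement(root, "NumberOfSpecies").text = str(len(model.species))
    etree.SubElement(root, "NumberOfReactions").text = str(len(model.reactions))

    slist = etree.SubElement(root, "SpeciesList")
    for s in model.species:
        el = etree.SubElement(slist, "Species")
        etree.SubElement(el, "Id").text = s.name
        etree.SubElement(el, "InitialPopulation").text = repr(float(s.initial_value))
        if s.diffusion_coefficient:
            etree.SubElement(el, "DiffusionCoefficient").text = repr(float(s.diffusion_coefficient))
        if s.allowed_subdomains:
            etree.SubElement(el, "AllowedSubdomains").text = " ".join(sorted(s.allowed_subdomains))

    plist = etree.SubElement(root, "ParametersList")
    for p in model.parameters:
        el = etree.SubElement(plist, "Parameter")
        etree.SubElement(el, "Id").text = p.name
        etree.SubElement(el, "Expression").text = repr(float(p.value))
        etree.SubElement(el, "Unit").text = p.unit

    rlist = etree.SubElement(root, "ReactionsList")
    for r in model.reactions:
        el = etree.SubElement(rlist, "Reaction")
        etree.SubElement(el, "Id").text = r.name
        if r.kinetics == MASS_ACTION:
            etree.SubElement(el, "Type").text = "mass-action"
            etree.SubElement(el, "Rate").text = r.rate_parameter
        else:
            etree.SubElement(el, "Type").text = "customized"
            etree.SubElement(el, "PropensityFunction").text = r.propensity.text
        for tag, stoich in (("Reactants", r.reactants), ("Products", r.products)):
            sub = etree.SubElement(el, tag)
            for name, n in stoich.items():
                etree.SubElement(sub, "SpeciesReference", id=name, stoichiometry=str(n))
        if r.restrict_to:
            etree.SubElement(el, "RestrictTo").text = " ".join(sorted(r.restrict_to))

    text = etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8").decode()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _parse_xml(document):
    if isinstance(document, bytes):
        return etree.fromstring(document)
    if isinstance(document, str):
        stripped = document.lstrip()
        if stripped.startswith("<"):
            return etree.fromstring(document.encode())
        return etree.parse(document).getroot()
    if hasattr(document, "read"):
        return etree.parse(document).getroot()
    return etree.parse(os.fspath(document)).getroot()


# ---------------------------------------------------------------------------
# SBML subset import


def _local(el) -> str:
    return etree.QName(el).localname if isinstance(el.tag, str) else ""


def _findall_local(parent, name):
    return [el for el in parent.iter() if _local(el) == name]


def _children_local(parent, name):
    return [el for el in parent if isinstance(el.tag, str) and _local(el) == name]


def _mathml_to_expression(el) -> str:
    """Convert content MathML to the expression grammar (text)."""
    tag = _local(el)
    if tag == "math":
        children = [c for c in el if isinstance(c.tag, str)]
        if len(children) != 1:
            raise ModelIOError("expected a single MathML root expression")
        return _mathml_to_expression(children[0])
    if tag == "ci":
        return el.text.strip()
    if tag == "cn":
        if el.get("type") == "e-notation":
            parts = [t for t in [el.text] + [c.tail for c in el] if t and t.strip()]
            return f"{parts[0].strip()}e{parts[1].strip()}"
        return el.text.strip()
    if tag == "apply":
        children = [c for c in el if isinstance(c.tag, str)]
        op, args = _local(children[0]), children[1:]
        sub = [_mathml_to_expression(a) for a in args]
        if op == "times":
            return "(" + "*".join(sub) + ")"
        if op == "plus":
            return "(" + "+".join(sub) + ")"
        if op == "minus":
            return f"(-{sub[0]})" if len(sub) == 1 else "(" + "-".join(sub) + ")"
        if op == "divide":
            return f"({sub[0]}/{sub[1]})"
        if op == "power":
            return f"({sub[0]}^{sub[1]})"
        if op == "exp":
            return f"exp({sub[0]})"
        if op == "ln":
            return f"log({sub[0]})"
        raise ModelIOError(f"unsupported MathML operator {op!r}")
    raise ModelIOError(f"unsupported MathML element {tag!r}")


def _match_mass_action(expr_text, reactants, parameter_names, compartment_id):
    """If the kinetic law is k * prod(reactant^stoich), optionally times the
    compartment size symbol, return the rate-parameter name; else None."""
    try:
        expr = parse_expression(expr_text).to_sympy()
    except ExpressionError:
        return None
    denom = sympy.Integer(1)
    for name, stoich in reactants.items():
        denom *= sympy.Symbol(name) ** stoich
    for candidate in (expr / denom,
                      expr / (denom * sympy.Symbol(compartment_id)) if compartment_id else None):
        if candidate is None:
            continue
        ratio = sympy.simplify(candidate)
        if ratio.is_Symbol and str(ratio) in parameter_names:
            return str(ratio)
    return None


def import_sbml(document):
    """Import an SBML Level 2/3 document (subset).

    Returns ``(model, warnings_list)``; never fails on a supported document.
    Each ignored feature produces one warning naming the feature and the
    element id.
    """
    root = _parse_xml(document)
    if _local(root) != "sbml":
        raise ModelIOError("not an SBML document")
    model_el = _children_local(root, "model")
    if not model_el:
        raise ModelIOError("SBML document has no model element")
    model_el = model_el[0]
    warns = []

    for feature, tag in (
        ("functions", "functionDefinition"),
        ("events", "event"),
        ("rules", "assignmentRule"),
        ("rules", "rateRule"),
        ("rules", "algebraicRule"),
        ("constraints", "constraint"),
        ("initial assignments", "initialAssignment"),
    ):
        for el in _findall_local(model_el, tag):
            ident = el.get("id") or el.get("variable") or tag
            warns.append(f"ignored SBML {feature}: {ident!r}")

    compartments = _findall_local(model_el, "compartment")
    compartment_id = compartments[0].get("id") if compartments else None
    volume = None
    if compartments:
        size = compartments[0].get("size") or compartments[0].get("volume")
        volume = float(size) if size is not None else None
        for extra in compartments[1:]:
            warns.append(f"ignored SBML compartments: {extra.get('id')!r} "
                         f"(model imported against {compartment_id!r})")

    species = []
    modes = set()
    for el in _findall_local(model_el, "species"):
        if el.get("initialConcentration") is not None:
            value, mode = float(el.get("initialConcentration")), "concentration"
        else:
            value, mode = float(el.get("initialAmount") or 0.0), "population"
        modes.add(mode)
        if el.get("compartment") not in (None, compartment_id):
            warns.append(f"ignored SBML compartments: species {el.get('id')!r} "
                         f"reassigned to {compartment_id!r}")
        species.append(Species(el.get("id"), value))
    units_mode = "concentration" if modes == {"concentration"} else "population"
    if len(modes) > 1:
        warns.append("ignored SBML mixed initial amount/concentration; using population mode")

    parameters = [
        Parameter(el.get("id"), float(el.get("value") or 0.0))
        for el in _children_local(_first_or_empty(model_el, "listOfParameters"), "parameter")
    ]

    reactions = []
    for el in _findall_local(model_el, "reaction"):
        rid = el.get("id")
        reactants, products = {}, {}
        for tag, target in (("listOfReactants", reactants), ("listOfProducts", products)):
            for lst in _children_local(el, tag):
                for ref in _children_local(lst, "speciesReference"):
                    st = int(float(ref.get("stoichiometry", "1")))
                    target[ref.get("species")] = target.get(ref.get("species"), 0) + st
        for lst in _children_local(el, "listOfModifiers"):
            for ref in _children_local(lst, "modifierSpeciesReference"):
                pass  # modifiers only matter through the kinetic law expression

        klaws = _findall_local(el, "kineticLaw")
        if not klaws:
            warns.append(f"ignored SBML reaction without kinetic law: {rid!r}")
            continue
        klaw = klaws[0]
        # local parameters are namespaced reactionid_paramname
        local_map = {}
        for lp in _findall_local(klaw, "parameter") + _findall_local(klaw, "localParameter"):
            local_name = f"{rid}_{lp.get('id')}"
            local_map[lp.get("id")] = local_name
            parameters.append(Parameter(local_name, float(lp.get("value") or 0.0)))
        maths = _children_local(klaw, "math")
        if not maths:
            raise ModelIOError(f"kinetic law of reaction {rid!r} has no math element")
        expr_text = _mathml_to_expression(maths[0])
        for old, new in local_map.items():
            expr_text = _rename_identifier(expr_text, old, new)

        param_names = {p.name for p in parameters}
        rate = _match_mass_action(expr_text, reactants, param_names, compartment_id)
        if rate is not None and sum(reactants.values()) <= 2:
            reactions.append(Reaction(rid, reactants, products, kinetics=MASS_ACTION,
                                      rate_parameter=rate))
        else:
            reactions.append(Reaction(rid, reactants, products, kinetics=CUSTOM,
                                      propensity=expr_text))

    model = ReactionNetworkModel(
        name=model_el.get("id") or model_el.get("name") or "sbml_model",
        units_mode=units_mode,
        volume=volume,
        species=species,
        parameters=parameters,
        reactions=reactions,
    )
    return model, warns


def _first_or_empty(parent, name):
    found = _children_local(parent, name)
    return found[0] if found else etree.Element("empty")


def _rename_identifier(expr_text, old, new):
    import re

    return re.sub(rf"\b{re.escape(old)}\b", new, expr_text)


# ---------------------------------------------------------------------------
# DOLFIN XML meshes


def read_dolfin_xml_mesh(document) -> Mesh:
    """Read a DOLFIN-dialect XML mesh (3D tetrahedral only)."""
    root = _parse_xml(document)
    mesh_el = root if _local(root) == "mesh" else next(
        (el for el in root.iter() if _local(el) == "mesh"), None
    )
    if mesh_el is None:
        raise ModelIOError("no mesh element found")
    celltype = mesh_el.get("celltype", "tetrahedron")
    if celltype != "tetrahedron":
        raise ModelIOError(f"unsupported cell type {celltype!r} (3D tetrahedral only)")

    vert_el = next(el for el in mesh_el.iter() if _local(el) == "vertices")
    n = int(vert_el.get("size"))
    vertices = np.zeros((n, 3))
    for v in vert_el:
        if not isinstance(v.tag, str):
            continue
        i = int(v.get("index"))
        vertices[i] = [float(v.get("x", 0)), float(v.get("y", 0)), float(v.get("z", 0))]

    cells_el = next(el for el in mesh_el.iter() if _local(el) == "cells")
    tets = []
    for c in cells_el:
        if not isinstance(c.tag, str):
            continue
        if _local(c) != "tetrahedron":
            raise ModelIOError(f"unsupported cell type {_local(c)!r} (3D tetrahedral only)")
        idx = [int(c.get(f"v{k}")) for k in range(4)]
        if any(i < 0 or i >= n for i in idx):
            raise ModelIOError(
                f"vertex index out of range in cell {c.get('index')}"
            )
        tets.append(idx)

    labels = None
    gene_site = None
    for el in root.iter():
        if _local(el) == "subdomains":
            labels = ["domain"] * n
            for v in el:
                if isinstance(v.tag, str):
                    labels[int(v.get("index"))] = v.get("value")
            gene_attr = el.get("gene_site_vertex")
            gene_site = int(gene_attr) if gene_attr is not None else None
    return Mesh(
        vertices=vertices,
        tetrahedra=np.array(tets, dtype=np.int64),
        subdomain_labels=labels,
        gene_site_vertex=gene_site,
    )


def write_dolfin_xml_mesh(mesh: Mesh, path=None) -> str:
    """Serialize a mesh in the DOLFIN XML dialect (with a subdomain extension
    block when labels are informative)."""
    root = etree.Element("dolfin")
    mesh_el = etree.SubElement(root, "mesh", celltype="tetrahedron", dim="3")
    vert_el = etree.SubElement(mesh_el, "vertices", size=str(mesh.n_vertices))
    for i, (x, y, z) in enumerate(mesh.vertices):
        etree.SubElement(vert_el, "vertex", index=str(i),
                         x=repr(float(x)), y=repr(float(y)), z=repr(float(z)))
    cells_el = etree.SubElement(mesh_el, "cells", size=str(len(mesh.tetrahedra)))
    for i, tet in enumerate(mesh.tetrahedra):
        etree.SubElement(
            cells_el, "tetrahedron", index=str(i),
            **{f"v{k}": str(int(tet[k])) for k in range(4)},
        )
    if set(mesh.subdomain_labels) != {"domain"} or mesh.gene_site_vertex is not None:
        attrs = {}
        if mesh.gene_site_vertex is not None:
            attrs["gene_site_vertex"] = str(mesh.gene_site_vertex)
        sub_el = etree.SubElement(root, "subdomains", **attrs)
        for i, label in enumerate(mesh.subdomain_labels):
            etree.SubElement(sub_el, "vertex", index=str(i), value=label)

    text = etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8").decode()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Result export


def _write_table(path, times, values, species_names):
    with open(path, "w") as fh:
        fh.write("time " + " ".join(species_names) + "\n")
        for t, row in zip(times, values):
            fh.write(repr(float(t)) + " " + " ".join(repr(float(v)) for v in row) + "\n")


def export_wellmixed(ensemble: Ensemble, directory) -> list:
    """StochKit2-style flat files: one whitespace-delimited file per
    trajectory (first column time, one column per species) plus means and
    variances files.  Returns the written paths."""
    if ensemble.n_reps == 0:
        raise ValueError("empty ensemble")
    os.makedirs(directory, exist_ok=True)
    paths = []
    names = ensemble.species_names
    for r, traj in enumerate(ensemble.trajectories):
        path = os.path.join(directory, f"trajectory_{r}.txt")
        _write_table(path, traj.times, traj.values, names)
        paths.append(path)
    for fname, arr in (("means.txt", ensemble.mean()), ("variances.txt", ensemble.variance())):
        path = os.path.join(directory, fname)
        _write_table(path, ensemble.times, arr, names)
        paths.append(path)
    return paths


def export_spatial(result: SpatialResult, directory, format: str = "csv") -> list:
    """Spatial export: ``csv`` writes mesh.csv (vertex id, x, y, z, volume,
    subdomain) plus trajectory.csv (one row per time and vertex); ``vtk``
    writes one legacy ASCII VTK unstructured-grid file per frame with a point
    data array per species (counts and concentrations)."""
    if len(result.times) == 0:
        raise ValueError("empty spatial result")
    os.makedirs(directory, exist_ok=True)
    mesh = result.mesh
    if format == "csv":
        mesh_path = os.path.join(directory, "mesh.csv")
        with open(mesh_path, "w", newline="\n") as fh:
            fh.write("vertex,x,y,z,volume,subdomain\n")
            for i in range(mesh.n_vertices):
                x, y, z = mesh.vertices[i]
                fh.write(
                    f"{i},{float(x)!r},{float(y)!r},{float(z)!r},"
                    f"{float(mesh.voxel_volumes[i])!r},{mesh.subdomain_labels[i]}\n"
                )
        traj_path = os.path.join(directory, "trajectory.csv")
        with open(traj_path, "w", newline="\n") as fh:
            fh.write("time,vertex," + ",".join(result.species_names) + "\n")
            for ti, t in enumerate(result.times):
                for i in range(mesh.n_vertices):
                    counts = ",".join(str(int(c)) for c in result.counts[ti, i])
                    fh.write(f"{float(t)!r},{i},{counts}\n")
        return [mesh_path, traj_path]

    if format != "vtk":
        raise ValueError(f"unknown spatial export format {format!r}")
    paths = []
    v_litres = mesh.voxel_volumes
    for ti, t in enumerate(result.times):
        path = os.path.join(directory, f"frame_{ti:04d}.vtk")
        with open(path, "w", newline="\n") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write(f"spatial counts at t={float(t)!r}\n")
            fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {mesh.n_vertices} double\n")
            for x, y, z in mesh.vertices:
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
            m = len(mesh.tetrahedra)
            fh.write(f"CELLS {m} {5 * m}\n")
            for tet in mesh.tetrahedra:
                fh.write("4 " + " ".join(str(int(v)) for v in tet) + "\n")
            fh.write(f"CELL_TYPES {m}\n")
            fh.write("\n".join(["10"] * m) + "\n")
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for j, name in enumerate(result.species_names):
                fh.write(f"SCALARS {name}_count double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(repr(float(c)) for c in result.counts[ti, :, j]) + "\n")
                conc = result.counts[ti, :, j] / (AVOGADRO * v_litres)
                fh.write(f"SCALARS {name}_concentration double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(repr(float(c)) for c in conc) + "\n")
        paths.append(path)
    return paths
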