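"""Metabolic reconstructions, connectivity graphs and shortest-path mapping.

A genome-scale reconstruction (SBML) is reduced to an undirected
metabolite connectivity graph: after removing ubiquitous currency
metabolites (ATP, NAD, water, ...) that would create biologically
meaningless shortcuts, the stoichiometric matrix is split into
non-negative consumed and produced incidence matrices and their product
``consumed @ produced.T`` is sign-thresholded and symmetrised — an edge
connects two metabolites whenever some reaction converts one into the
other, in either direction (all reactions are treated as reversible).

Differentially correlated metabolite pairs are then mapped onto this
graph via breadth-first shortest paths, the per-pair paths are unioned
into condition sub-networks, and sub-networks from two cohorts are
compared node-by-node (A-only / B-only / shared).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from itertools import product

import libsbml
import networkx as nx
import numpy as np
import pandas as pd

from .corrstats import DifferentialCorrelation
from .profiles import MetaboliteAnnotation

__all__ = [
    "Species",
    "Reaction",
    "MetabolicNetwork",
    "StoichiometricDecomposition",
    "PathResult",
    "ComparisonNetwork",
    "load_sbml",
    "write_sbml",
    "default_currency",
    "remove_currency",
    "decompose",
    "connectivity_graph",
    "metabolite_graph",
    "shortest_path",
    "map_pairs",
    "assemble_subnetwork",
    "compare_networks",
    "export_network",
    "import_network",
    "paths_table",
]

_KEGG_CPD = re.compile(r"(C\d{5})")


@dataclass(frozen=True)
class Species:
    id: str
    name: str = ""
    kegg: str | None = None


@dataclass(frozen=True)
class Reaction:
    """One reaction with positive stoichiometric coefficients per side.

    ``consumed`` lists the reactant side, ``produced`` the product side;
    reversibility is handled downstream by symmetrising the connectivity
    graph, so the stored orientation carries no directional meaning.
    """

    id: str
    name: str = ""
    consumed: tuple[tuple[str, float], ...] = ()
    produced: tuple[tuple[str, float], ...] = ()


@dataclass
class MetabolicNetwork:
    species: list[Species]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate species ids")
        known = set(ids)
        for rxn in self.reactions:
            for sid, coeff in rxn.consumed + rxn.produced:
                if sid not in known:
                    raise ValueError(
                        f"reaction {rxn.id!r} references unknown species {sid!r}"
                    )
                if coeff <= 0:
                    raise ValueError(
                        f"reaction {rxn.id!r}: non-positive coefficient for {sid!r}"
                    )

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_by_id(self) -> dict[str, Species]:
        return {s.id: s for s in self.species}


def _species_kegg(sp: libsbml.Species) -> str | None:
    """Best-effort KEGG compound id from CV terms, notes or the species id."""
    for i in range(sp.getNumCVTerms()):
        term = sp.getCVTerm(i)
        for j in range(term.getNumResources()):
            uri = term.getResourceURI(j)
            if "kegg" in uri.lower():
                m = _KEGG_CPD.search(uri)
                if m:
                    return m.group(1)
    if sp.isSetNotes():
        m = _KEGG_CPD.search(libsbml.XMLNode.convertXMLNodeToString(sp.getNotes()))
        if m:
            return m.group(1)
    m = _KEGG_CPD.fullmatch(sp.getId().lstrip("M_").split("_")[0]) or _KEGG_CPD.search(
        sp.getId()
    )
    return m.group(1) if m else None


def load_sbml(path, *, strip_compartment: bool | None = None) -> MetabolicNetwork:
    """Load an SBML (Level 2/3) model as a :class:`MetabolicNetwork`.

    Reactant sides become ``consumed``, product sides ``produced``, with
    stoichiometric coefficients preserved. When the model declares a
    single compartment, a trailing ``_<compartment>`` suffix on species
    ids is stripped (``strip_compartment=None`` selects this automatic
    behaviour); multi-compartment models are loaded as-is.
    """
    reader = libsbml.SBMLReader()
    doc = reader.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ValueError(
            f"SBML parse error at line {err.getLine()}, column {err.getColumn()}: "
            f"{err.getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise ValueError(f"no model element found in {path}")

    if strip_compartment is None:
        strip_compartment = model.getNumCompartments() == 1
    suffixes = (
        tuple(
            f"_{model.getCompartment(i).getId()}"
            for i in range(model.getNumCompartments())
        )
        if strip_compartment and model.getNumCompartments() == 1
        else ()
    )

    def canon(sid: str) -> str:
        for suf in suffixes:
            if sid.endswith(suf) and len(sid) > len(suf):
                return sid[: -len(suf)]
        return sid

    species = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        species.append(
            Species(id=canon(sp.getId()), name=sp.getName() or "", kegg=_species_kegg(sp))
        )

    reactions = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        consumed = tuple(
            (canon(rxn.getReactant(j).getSpecies()), rxn.getReactant(j).getStoichiometry())
            for j in range(rxn.getNumReactants())
        )
        produced = tuple(
            (canon(rxn.getProduct(j).getSpecies()), rxn.getProduct(j).getStoichiometry())
            for j in range(rxn.getNumProducts())
        )
        reactions.append(
            Reaction(id=rxn.getId(), name=rxn.getName() or "", consumed=consumed, produced=produced)
        )
    return MetabolicNetwork(species=species, reactions=reactions)


def write_sbml(net: MetabolicNetwork, path) -> None:
    """Write the network as an SBML Level 3 Version 1 document."""
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId("model")
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    for sp in net.species:
        s = model.createSpecies()
        s.setId(sp.id)
        if sp.name:
            s.setName(sp.name)
        s.setCompartment("c")
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        if sp.kegg:
            s.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml"><p>KEGG: {sp.kegg}</p></body>'
            )
    for rxn in net.reactions:
        r = model.createReaction()
        r.setId(rxn.id)
        if rxn.name:
            r.setName(rxn.name)
        r.setReversible(True)
        r.setFast(False)
        for sid, coeff in rxn.consumed:
            ref = r.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for sid, coeff in rxn.produced:
            ref = r.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
    libsbml.writeSBMLToFile(doc, str(path))


# -- currency metabolites ------------------------------------------------


def _norm_name(name: str) -> str:
    return re.sub(r"[\s\-_',]+", "", name).lower()


def default_currency() -> list[dict[str, str]]:
    """The shipped currency-metabolite table (name, synonyms, KEGG id)."""
    text = (
        resources.files("metcorrnet.data")
        .joinpath("currency_metabolites.tsv")
        .read_text()
    )
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    for row in rows:
        row["synonyms"] = row.get("synonyms", "")
    return rows


def load_currency(path) -> list[dict[str, str]]:
    """Read a user-supplied currency table with the same columns as the default."""
    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def remove_currency(
    net: MetabolicNetwork,
    currency: list[dict[str, str]] | list[str] | None = None,
) -> MetabolicNetwork:
    """Drop currency metabolites from every reaction and from the species list.

    ``currency`` entries are matched against species by id, by
    (punctuation-insensitive) name or synonym, and by KEGG annotation.
    Reactions left with empty consumed AND produced sides are dropped.
    Unmatched currency entries are ignored (the list is model-agnostic).
    """
    if currency is None:
        currency = default_currency()
    tokens: set[str] = set()
    kegg_tokens: set[str] = set()
    for entry in currency:
        if isinstance(entry, str):
            tokens.add(_norm_name(entry))
            if _KEGG_CPD.fullmatch(entry):
                kegg_tokens.add(entry)
            continue
        tokens.add(_norm_name(entry["name"]))
        for syn in entry.get("synonyms", "").split(";"):
            if syn.strip():
                tokens.add(_norm_name(syn))
        if entry.get("kegg_id"):
            kegg_tokens.add(entry["kegg_id"].strip())

    doomed = {
        sp.id
        for sp in net.species
        if _norm_name(sp.id) in tokens
        or _norm_name(sp.name) in tokens
        or (sp.kegg and sp.kegg in kegg_tokens)
        or sp.id in kegg_tokens
    }
    species = [sp for sp in net.species if sp.id not in doomed]
    reactions = []
    for rxn in net.reactions:
        consumed = tuple((s, c) for s, c in rxn.consumed if s not in doomed)
        produced = tuple((s, c) for s, c in rxn.produced if s not in doomed)
        if not consumed and not produced:
            continue
        reactions.append(
            Reaction(id=rxn.id, name=rxn.name, consumed=consumed, produced=produced)
        )
    return MetabolicNetwork(species=species, reactions=reactions)


# -- stoichiometric decomposition and connectivity -----------------------


@dataclass
class StoichiometricDecomposition:
    """Non-negative consumed / produced incidence matrices (species x reactions)."""

    species_ids: list[str]
    reaction_ids: list[str]
    consumed: np.ndarray
    produced: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.species_ids), len(self.reaction_ids))
        if self.consumed.shape != shape or self.produced.shape != shape:
            raise ValueError("incidence matrices do not match id lists")
        if (self.consumed < 0).any() or (self.produced < 0).any():
            raise ValueError("incidence matrices must be non-negative")


def decompose(net: MetabolicNetwork) -> StoichiometricDecomposition:
    """Split the stoichiometric matrix into consumed and produced incidences."""
    sids = net.species_ids
    rids = [r.id for r in net.reactions]
    srow = {s: i for i, s in enumerate(sids)}
    consumed = np.zeros((len(sids), len(rids)))
    produced = np.zeros((len(sids), len(rids)))
    for j, rxn in enumerate(net.reactions):
        for sid, coeff in rxn.consumed:
            consumed[srow[sid], j] += coeff
        for sid, coeff in rxn.produced:
            produced[srow[sid], j] += coeff
    return StoichiometricDecomposition(
        species_ids=sids, reaction_ids=rids, consumed=consumed, produced=produced
    )


def connectivity_graph(d: StoichiometricDecomposition) -> nx.Graph:
    """Undirected metabolite connectivity graph from the decomposition.

    Adjacency is the sign of ``consumed @ produced.T``, symmetrised by
    logical OR with its transpose (reversibility) and with the diagonal
    cleared (no self-loops). Each edge carries the set of reaction ids
    that support the conversion.
    """
    adj = (d.consumed @ d.produced.T) > 0
    adj = adj | adj.T
    np.fill_diagonal(adj, False)

    g = nx.Graph()
    g.add_nodes_from(d.species_ids)
    ii, jj = np.nonzero(adj)
    for i, j in zip(ii, jj):
        if i < j:
            g.add_edge(d.species_ids[i], d.species_ids[j], reactions=set())
    for j, rid in enumerate(d.reaction_ids):
        cons = [d.species_ids[i] for i in np.nonzero(d.consumed[:, j])[0]]
        prod = [d.species_ids[i] for i in np.nonzero(d.produced[:, j])[0]]
        for a, b in product(cons, prod):
            if a != b:
                g.edges[a, b]["reactions"].add(rid)
    return g


def metabolite_graph(
    net: MetabolicNetwork, currency: list | None | bool = True
) -> nx.Graph:
    """Currency-purged connectivity graph with name/KEGG node attributes.

    ``currency=True`` uses the shipped default list, ``False``/``None``
    skips the purge, and an explicit list overrides the default.
    """
    if currency is True:
        net = remove_currency(net)
    elif currency:
        net = remove_currency(net, currency)
    g = connectivity_graph(decompose(net))
    for sp in net.species:
        g.nodes[sp.id]["name"] = sp.name
        g.nodes[sp.id]["kegg"] = sp.kegg or ""
    return g


# -- shortest paths ------------------------------------------------------


@dataclass
class PathResult:
    """Outcome of one shortest-path query between two metabolites."""

    pair: tuple[str, str]
    status: str  # found | source_absent | target_absent | disconnected
    nodes: tuple[str, ...] = ()
    step_reactions: tuple[frozenset[str], ...] = ()
    source_id: str | None = None
    target_id: str | None = None

    @property
    def length(self) -> int | None:
        return len(self.nodes) - 1 if self.status == "found" else None


def _bfs_path(g: nx.Graph, source: str, target: str) -> tuple[str, ...] | None:
    """Deterministic BFS shortest path with lexicographic neighbour expansion."""
    if source == target:
        return (source,)
    parent: dict[str, str] = {source: source}
    frontier = [source]
    while frontier:
        nxt: list[str] = []
        for node in frontier:
            for nb in sorted(g.neighbors(node)):
                if nb in parent:
                    continue
                parent[nb] = node
                if nb == target:
                    path = [nb]
                    while path[-1] != source:
                        path.append(parent[path[-1]])
                    return tuple(reversed(path))
                nxt.append(nb)
        frontier = nxt
    return None


def shortest_path(g: nx.Graph, source: str, target: str) -> PathResult:
    """Breadth-first shortest path by edge count, with explicit statuses.

    Ties are broken deterministically by expanding neighbours in
    lexicographic order. Absent endpoints or disconnected pairs are
    reported in ``status`` rather than raised.
    """
    pair = (source, target)
    if source not in g:
        return PathResult(pair=pair, status="source_absent")
    if target not in g:
        return PathResult(pair=pair, status="target_absent")
    nodes = _bfs_path(g, source, target)
    if nodes is None:
        return PathResult(pair=pair, status="disconnected")
    steps = tuple(
        frozenset(g.edges[a, b]["reactions"]) for a, b in zip(nodes, nodes[1:])
    )
    return PathResult(
        pair=pair,
        status="found",
        nodes=nodes,
        step_reactions=steps,
        source_id=source,
        target_id=target,
    )


def _candidates(
    peak: str,
    annotations: dict[str, MetaboliteAnnotation],
    index: dict[str, str],
    g: nx.Graph,
) -> list[str]:
    ann = annotations.get(peak)
    if ann is None:  # unannotated peak: usable only if it is itself a node id
        return [peak] if peak in g else []
    out = []
    for kegg in ann.kegg_ids:
        if kegg in index:
            out.append(index[kegg])
        elif kegg in g:
            out.append(kegg)
    return out


def map_pairs(
    g: nx.Graph,
    diffs: list[DifferentialCorrelation],
    annotations: dict[str, MetaboliteAnnotation],
    policy: str = "shortest",
) -> list[PathResult]:
    """Map differential pairs onto the network via annotation candidates.

    Each peak's candidate KEGG compound ids are resolved to graph nodes;
    multi-identity peaks ("Galactose/Glucose") contribute several
    candidates. Policies: ``shortest`` (default) evaluates all candidate
    combinations and keeps the shortest found path, recording the chosen
    ids; ``first`` uses only the first-listed candidate per peak. Pairs
    whose endpoints do not resolve, or that are disconnected under every
    combination, are reported with the corresponding status — never
    dropped silently.
    """
    if policy not in {"shortest", "first"}:
        raise ValueError(f"unknown policy {policy!r}")
    index = {
        data["kegg"]: node
        for node, data in g.nodes(data=True)
        if data.get("kegg")
    }
    results = []
    for d in diffs:
        peak_a, peak_b = d.pair
        cand_a = _candidates(peak_a, annotations, index, g)
        cand_b = _candidates(peak_b, annotations, index, g)
        if policy == "first":
            cand_a, cand_b = cand_a[:1], cand_b[:1]
        if not cand_a:
            results.append(PathResult(pair=d.pair, status="source_absent"))
            continue
        if not cand_b:
            results.append(PathResult(pair=d.pair, status="target_absent"))
            continue
        best: PathResult | None = None
        for sa, sb in product(cand_a, cand_b):
            if sa == sb:
                continue
            res = shortest_path(g, sa, sb)
            if res.status != "found":
                continue
            if best is None or res.length < best.length:
                best = res
        if best is None:
            results.append(PathResult(pair=d.pair, status="disconnected"))
        else:
            results.append(
                PathResult(
                    pair=d.pair,
                    status="found",
                    nodes=best.nodes,
                    step_reactions=best.step_reactions,
                    source_id=best.pair[0],
                    target_id=best.pair[1],
                )
            )
    return results


def paths_table(paths: list[PathResult]) -> pd.DataFrame:
    """Path results as a table (pair, status, length, node sequence, reactions)."""
    rows = []
    for p in paths:
        rows.append(
            {
                "metabolite_a": p.pair[0],
                "metabolite_b": p.pair[1],
                "status": p.status,
                "length": p.length if p.length is not None else "",
                "nodes": ";".join(p.nodes),
                "reactions": "|".join(
                    ";".join(sorted(step)) for step in p.step_reactions
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["metabolite_a", "metabolite_b", "status", "length", "nodes", "reactions"],
    )


# -- sub-network assembly and comparison ---------------------------------


def assemble_subnetwork(paths: list[PathResult]) -> nx.Graph:
    """Union of all found shortest paths, with merged reaction annotations.

    Node set = union of path nodes; edge set = union of path edges. The
    result is independent of path order and idempotent under repetition.
    """
    g = nx.Graph()
    for p in paths:
        if p.status != "found":
            continue
        for node in p.nodes:
            g.add_node(node)
        for (a, b), rxns in zip(zip(p.nodes, p.nodes[1:]), p.step_reactions):
            if g.has_edge(a, b):
                g.edges[a, b]["reactions"] = set(g.edges[a, b]["reactions"]) | set(rxns)
            else:
                g.add_edge(a, b, reactions=set(rxns))
    return g


@dataclass
class ComparisonNetwork:
    """Union of two sub-networks with node/edge origin classes.

    Origins partition nodes and edges into ``A_only`` / ``B_only`` /
    ``shared`` — the white / black / grey scheme used when overlaying the
    responses of two cohorts.
    """

    graph: nx.Graph
    label_a: str = "A"
    label_b: str = "B"

    def node_counts(self) -> dict[str, int]:
        counts = {"A_only": 0, "B_only": 0, "shared": 0}
        for _, data in self.graph.nodes(data=True):
            counts[data["origin"]] += 1
        return counts

    def nodes_with_origin(self, origin: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["origin"] == origin}


def compare_networks(
    sub_a: nx.Graph, sub_b: nx.Graph, label_a: str = "A", label_b: str = "B"
) -> ComparisonNetwork:
    """Overlay two condition sub-networks and classify node/edge origins."""
    g = nx.Graph()
    for node in set(sub_a) | set(sub_b):
        if node in sub_a and node in sub_b:
            origin = "shared"
        elif node in sub_a:
            origin = "A_only"
        else:
            origin = "B_only"
        attrs = {}
        for src in (sub_a, sub_b):
            if node in src:
                attrs.update(src.nodes[node])
        g.add_node(node, origin=origin, **attrs)
    edges_a = {frozenset(e) for e in sub_a.edges}
    edges_b = {frozenset(e) for e in sub_b.edges}
    for e in edges_a | edges_b:
        a, b = tuple(e)
        origin = (
            "shared" if e in edges_a and e in edges_b else "A_only" if e in edges_a else "B_only"
        )
        rxns: set[str] = set()
        for src in (sub_a, sub_b):
            if src.has_edge(a, b):
                rxns |= set(src.edges[a, b].get("reactions", ()))
        g.add_edge(a, b, origin=origin, reactions=rxns)
    return ComparisonNetwork(graph=g, label_a=label_a, label_b=label_b)


# -- export --------------------------------------------------------------


def export_network(net: nx.Graph | ComparisonNetwork, path, format: str = "graphml") -> None:
    """Write a (comparison) network as GraphML or SIF.

    GraphML carries node origin and edge reaction-id attributes (sets
    serialised as semicolon-joined sorted strings). SIF uses the relation
    ``cc`` (connected conversion) per edge, one line per edge.
    """
    g = net.graph if isinstance(net, ComparisonNetwork) else net
    if format == "graphml":
        out = nx.Graph()
        for node, data in g.nodes(data=True):
            out.add_node(node, **{k: _attr_str(v) for k, v in data.items()})
        for a, b, data in g.edges(data=True):
            out.add_edge(a, b, **{k: _attr_str(v) for k, v in data.items()})
        nx.write_graphml(out, str(path))
    elif format == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(map(sorted, g.edges())):
                fh.write(f"{a}\tcc\t{b}\n")
            for node in sorted(n for n in g if g.degree(n) == 0):
                fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'graphml' or 'sif'")


def _attr_str(v):
    if isinstance(v, (set, frozenset)):
        return ";".join(sorted(v))
    return v


def import_network(path, format: str = "graphml") -> nx.Graph:
    """Re-import a network written by :func:`export_network`."""
    if format == "graphml":
        g = nx.read_graphml(str(path))
        out = nx.Graph()
        for node, data in g.nodes(data=True):
            out.add_node(node, **data)
        for a, b, data in g.edges(data=True):
            attrs = dict(data)
            if "reactions" in attrs and isinstance(attrs["reactions"], str):
                attrs["reactions"] = {
                    r for r in attrs["reactions"].split(";") if r
                }
            out.add_edge(a, b, **attrs)
        return out
    if format == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    g.add_edge(parts[0], parts[2])
                elif parts[0]:
                    g.add_node(parts[0])
        return g
    raise ValueError(f"unknown format {format!r}")
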