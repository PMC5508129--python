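"""Domain types and assembly of the bipartite metabolite-enzyme inhibition network.

The network joins small-molecule inhibitors (metabolites of a genome-scale
metabolic model) to the enzymatic reactions (EC numbers) they inhibit.  It is
built in two steps: :func:`load_model` instantiates the metabolic model from
TSV tables or SBML, and :func:`map_inhibitors` maps an inhibitor-annotation
snapshot (EC number, inhibitor name, mechanism, species) onto the model's
metabolites, yielding one edge per distinct resolved (metabolite, EC) pair.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "."

#: closed mechanism vocabulary for inhibition edges
MECHANISMS = frozenset({"competitive", "noncompetitive", "uncompetitive", "unknown"})

#: first EC digit -> enzyme class name
ENZYME_CLASS_NAMES = {
    1: "Oxidoreductases",
    2: "Transferases",
    3: "Hydrolases",
    4: "Lyases",
    5: "Isomerases",
    6: "Ligases",
}

_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")

# ---------------------------------------------------------------------------
# HMDB superclass merging
# ---------------------------------------------------------------------------

AROMATIC_GROUP = "Aromatic Cyclic Compounds"
OTHERS_GROUP = "Others"

_AROMATIC_RAW = {
    "Aromatic Heteropolycyclic Compounds",
    "Aromatic Heteromonocyclic Compounds",
    "Aromatic Homomonocyclic Compounds",
}

_OTHERS_RAW = {
    "Alkaloids and Derivatives",
    "Aliphatic Homomonocyclic Compounds",
    "Aliphatic Heteropolycyclic Compounds",
    "Benzenoids",
    "Homogeneous Non-metal Compounds",
    "Organophosphorus Compounds",
    "Organooxygen Compounds",
    "Aliphatic Heteromonocyclic Compounds",
}

_RETAINED = {
    "Nucleosides, Nucleotides, and Analogues",
    "Organic Acids and Derivatives",
    "Amino Acids, Peptides and Analogues",
    "Aliphatic Acyclic Compounds",
    "Carbohydrates and Carbohydrate Conjugates",
    "Lipids",
}

#: the closed 8-group vocabulary (6 retained + merged aromatic + Others)
SUPERCLASS_GROUPS = tuple(sorted(_RETAINED)) + (AROMATIC_GROUP, OTHERS_GROUP)

UNCLASSIFIED = "unclassified"


def merge_superclasses(raw_superclass: str) -> str:
    """Map a raw HMDB superclass string onto the merged 8-group vocabulary.

    The three aromatic superclasses collapse into "Aromatic Cyclic Compounds";
    eight enumerated small superclasses collapse into "Others".  Six large
    superclasses are retained verbatim.  Any other string also maps to
    "Others" (with a log message) so the function is total.
    """
    raw = raw_superclass.strip()
    # normalize the comma variant "Nucleosides, Nucleotides and Analogues"
    if raw == "Nucleosides, Nucleotides and Analogues":
        raw = "Nucleosides, Nucleotides, and Analogues"
    if raw in _RETAINED:
        return raw
    if raw in _AROMATIC_RAW:
        return AROMATIC_GROUP
    if raw not in _OTHERS_RAW:
        logger.info("unlisted superclass %r mapped to %r", raw_superclass, OTHERS_GROUP)
    return OTHERS_GROUP


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    kegg_id: str | None = None
    hmdb_id: str | None = None
    superclass: str = UNCLASSIFIED
    smiles: str | None = None
    compartments: set[str] = field(default_factory=set)
    phosphorylated: bool = False
    essential: bool | None = None


@dataclass
class EnzymeReaction:
    ec_number: str
    substrates: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    pathways: list[str] = field(default_factory=list)
    compartments: set[str] = field(default_factory=set)
    essential: bool | None = None
    unlocalized: bool = False

    @property
    def enzyme_class(self) -> int:
        """First EC field, 1-6."""
        return int(self.ec_number.split(".")[0])


@dataclass
class InhibitionEdge:
    metabolite_id: str
    ec_number: str
    mechanism: str = "unknown"
    species_evidence: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism {self.mechanism!r} not in {sorted(MECHANISMS)}")


class InhibitionNetwork:
    """Bipartite network of Metabolite and EnzymeReaction nodes.

    Edges are annotated inhibitory interactions; (metabolite, EC) pairs are
    unique, so the edge count equals the number of distinct pairs.
    """

    def __init__(self, metabolites: dict[str, Metabolite] | None = None,
                 reactions: dict[str, EnzymeReaction] | None = None):
        self.metabolites: dict[str, Metabolite] = metabolites or {}
        self.reactions: dict[str, EnzymeReaction] = reactions or {}
        self._edges: dict[tuple[str, str], InhibitionEdge] = {}

    @property
    def edges(self) -> list[InhibitionEdge]:
        return list(self._edges.values())

    def get_edge(self, metabolite_id: str, ec: str) -> InhibitionEdge | None:
        return self._edges.get((metabolite_id, ec))

    def add_edge(self, edge: InhibitionEdge) -> None:
        if edge.metabolite_id not in self.metabolites:
            raise KeyError(f"edge references unknown metabolite {edge.metabolite_id!r}")
        if edge.ec_number not in self.reactions:
            raise KeyError(f"edge references unknown reaction EC {edge.ec_number!r}")
        self._edges[(edge.metabolite_id, edge.ec_number)] = edge

    # -- degree helpers ----------------------------------------------------

    def metabolite_degree(self, metabolite_id: str) -> int:
        return sum(1 for (m, _e) in self._edges if m == metabolite_id)

    def reaction_degree(self, ec: str) -> int:
        return sum(1 for (_m, e) in self._edges if e == ec)

    def reactions_of_metabolite(self, metabolite_id: str) -> list[str]:
        """ECs of reactions in which the metabolite is a substrate or product."""
        return [ec for ec, r in self.reactions.items()
                if metabolite_id in r.substrates or metabolite_id in r.products]

    # -- graph views -------------------------------------------------------

    def bipartite_graph(self):
        """Inhibition network as a networkx Graph.

        Metabolite nodes carry ``bipartite=0``, reaction nodes ``bipartite=1``;
        reaction node names are prefixed with ``"EC:"`` to keep the namespaces
        disjoint.
        """
        import networkx as nx

        g = nx.Graph()
        for mid in sorted(self.metabolites):
            g.add_node(mid, bipartite=0, kind="metabolite")
        for ec in sorted(self.reactions):
            g.add_node("EC:" + ec, bipartite=1, kind="enzyme")
        for (mid, ec), edge in sorted(self._edges.items()):
            g.add_edge(mid, "EC:" + ec, mechanism=edge.mechanism)
        return g

    # -- serialization -----------------------------------------------------

    def to_edges_tsv(self, path: str | Path) -> None:
        rows = [
            {"metabolite_id": m, "ec": e,
             "mechanism": edge.mechanism,
             "species": ";".join(sorted(edge.species_evidence)) or MISSING}
            for (m, e), edge in sorted(self._edges.items())
        ]
        pd.DataFrame(rows, columns=["metabolite_id", "ec", "mechanism", "species"]).to_csv(
            path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.bipartite_graph(), str(path))

    def validate(self) -> None:
        """Assert bipartite structural invariants; raise on violation."""
        for (mid, ec), edge in self._edges.items():
            if mid not in self.metabolites or ec not in self.reactions:
                raise AssertionError(f"dangling edge ({mid}, {ec})")
        for r in self.reactions.values():
            for m in list(r.substrates) + list(r.products):
                if m not in self.metabolites:
                    raise AssertionError(f"reaction {r.ec_number} references unknown metabolite {m}")


@dataclass
class Provenance:
    """Source-file digests plus row bookkeeping (dropped + mapped = total)."""

    digests: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    dropped_records: list[dict] = field(default_factory=list)
    mechanism_conflicts: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def add_file(self, label: str, path: str | Path) -> None:
        data = Path(path).read_bytes()
        self.digests[label] = hashlib.sha256(data).hexdigest()


@dataclass
class ModelBundle:
    network: InhibitionNetwork
    id_map: dict[str, str] = field(default_factory=dict)
    provenance: Provenance = field(default_factory=Provenance)


# ---------------------------------------------------------------------------
# Structure-derived flags
# ---------------------------------------------------------------------------


def flag_phosphorylated(metabolite: Metabolite) -> bool:
    """True iff the structure contains a phosphate/phosphonate motif.

    The motif is a phosphorus atom bonded to at least three oxygens.  A
    metabolite without a structure, or with an unparseable one, is False.
    """
    if not metabolite.smiles:
        return False
    from rdkit import Chem

    mol = Chem.MolFromSmiles(metabolite.smiles)
    if mol is None:
        logger.warning("unparseable structure for %s; phosphorylated=False", metabolite.id)
        return False
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "P":
            n_oxy = sum(1 for nb in atom.GetNeighbors() if nb.GetSymbol() == "O")
            if n_oxy >= 3:
                return True
    return False


# ---------------------------------------------------------------------------
# Model loading
# ---------------------------------------------------------------------------


def _split_list(cell: str) -> list[str]:
    if not cell or cell == MISSING:
        return []
    return [t for t in re.split(r"[;,]", cell) if t]


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_model(model_source: str | Path, superclass_map: str | Path | None = None) -> ModelBundle:
    """Instantiate a ModelBundle from model TSV tables or an SBML file.

    ``model_source`` is either a directory containing ``metabolites.tsv`` and
    ``reactions.tsv`` (plus optional ``pathways.tsv`` mapping pathway ->
    compartment), or a path to an SBML Level 3 file.  ``superclass_map`` is an
    optional TSV (metabolite_id, superclass) of raw HMDB superclasses;
    metabolites absent from the map get superclass "unclassified".

    Rows with malformed EC strings are rejected (counted in provenance);
    duplicate reactions (same EC and substrate set) are merged.
    """
    source = Path(model_source)
    prov = Provenance()
    if source.is_dir():
        mets, rxns = _load_model_tsv(source, prov)
    else:
        mets, rxns = _load_model_sbml(source, prov)

    net = InhibitionNetwork(metabolites=mets, reactions=rxns)

    if superclass_map is not None:
        prov.add_file("superclass_map", superclass_map)
        scmap = _read_tsv(Path(superclass_map))
        for _, row in scmap.iterrows():
            m = net.metabolites.get(row["metabolite_id"])
            if m is not None and row["superclass"] != MISSING:
                m.superclass = merge_superclasses(row["superclass"])

    for m in net.metabolites.values():
        m.phosphorylated = flag_phosphorylated(m)

    net.validate()
    prov.counts["metabolites"] = len(net.metabolites)
    prov.counts["reactions"] = len(net.reactions)
    return ModelBundle(network=net, provenance=prov)


def _load_model_tsv(source: Path, prov: Provenance) -> tuple[dict, dict]:
    met_path = source / "metabolites.tsv"
    rxn_path = source / "reactions.tsv"
    prov.add_file("metabolites", met_path)
    prov.add_file("reactions", rxn_path)

    mets: dict[str, Metabolite] = {}
    for _, row in _read_tsv(met_path).iterrows():
        m = Metabolite(
            id=row["id"],
            name=row.get("name", row["id"]),
            kegg_id=None if row.get("kegg_id", MISSING) == MISSING else row["kegg_id"],
            hmdb_id=None if row.get("hmdb_id", MISSING) == MISSING else row["hmdb_id"],
            smiles=None if row.get("smiles", MISSING) == MISSING else row["smiles"],
        )
        mets[m.id] = m

    rxns: dict[str, EnzymeReaction] = {}
    dropped = 0
    merged = 0
    for _, row in _read_tsv(rxn_path).iterrows():
        ec = row["ec"].strip()
        if not _EC_RE.match(ec):
            logger.warning("malformed EC %r: row rejected", ec)
            prov.dropped_records.append({"table": "reactions", "ec": ec, "reason": "malformed_ec"})
            dropped += 1
            continue
        r = EnzymeReaction(
            ec_number=ec,
            substrates=_split_list(row.get("substrates", "")),
            products=_split_list(row.get("products", "")),
            genes=_split_list(row.get("genes", "")),
            pathways=_split_list(row.get("pathways", "")),
        )
        if ec in rxns:
            prev = rxns[ec]
            if set(prev.substrates) == set(r.substrates):
                logger.info("duplicate reaction %s merged", ec)
                merged += 1
                prev.products = sorted(set(prev.products) | set(r.products))
                prev.genes = sorted(set(prev.genes) | set(r.genes))
                prev.pathways = sorted(set(prev.pathways) | set(r.pathways))
                continue
            # same EC, different substrate set: union everything under one EC node
            prev.substrates = sorted(set(prev.substrates) | set(r.substrates))
            prev.products = sorted(set(prev.products) | set(r.products))
            prev.genes = sorted(set(prev.genes) | set(r.genes))
            prev.pathways = sorted(set(prev.pathways) | set(r.pathways))
            continue
        rxns[ec] = r

    prov.counts["reactions_dropped"] = dropped
    prov.counts["reactions_merged"] = merged
    return mets, rxns


# SBML round-tripping uses the COBRA notes convention (GENE_ASSOCIATION,
# SUBSYSTEM, EC Number) so that genome-scale reconstructions exported by the
# usual toolchains parse without extra configuration.

def _load_model_sbml(source: Path, prov: Provenance) -> tuple[dict, dict]:
    import libsbml

    prov.add_file("sbml", source)
    doc = libsbml.readSBMLFromString(source.read_text())
    model = doc.getModel()
    if model is None:
        raise ValueError(f"not a parseable SBML file: {source}")

    mets: dict[str, Metabolite] = {}
    for sp in model.getListOfSpecies():
        notes = _parse_notes(sp.getNotesString() if sp.isSetNotes() else "")
        m = Metabolite(
            id=sp.getId(),
            name=sp.getName() or sp.getId(),
            kegg_id=notes.get("KEGG") or None,
            hmdb_id=notes.get("HMDB") or None,
            smiles=notes.get("SMILES") or None,
        )
        mets[m.id] = m

    rxns: dict[str, EnzymeReaction] = {}
    dropped = 0
    for rx in model.getListOfReactions():
        notes = _parse_notes(rx.getNotesString() if rx.isSetNotes() else "")
        ec = notes.get("EC Number", "").strip()
        if not _EC_RE.match(ec):
            logger.warning("reaction %s without well-formed EC: rejected", rx.getId())
            prov.dropped_records.append({"table": "sbml_reactions", "ec": ec, "reason": "malformed_ec"})
            dropped += 1
            continue
        r = EnzymeReaction(
            ec_number=ec,
            substrates=[s.getSpecies() for s in rx.getListOfReactants()],
            products=[s.getSpecies() for s in rx.getListOfProducts()],
            genes=_split_list(notes.get("GENE_ASSOCIATION", "")),
            pathways=_split_list(notes.get("SUBSYSTEM", "")),
        )
        if r.ec_number in rxns:
            prev = rxns[r.ec_number]
            prev.substrates = sorted(set(prev.substrates) | set(r.substrates))
            prev.products = sorted(set(prev.products) | set(r.products))
            prev.genes = sorted(set(prev.genes) | set(r.genes))
            prev.pathways = sorted(set(prev.pathways) | set(r.pathways))
            continue
        rxns[r.ec_number] = r

    prov.counts["reactions_dropped"] = dropped
    prov.counts["reactions_merged"] = 0
    return mets, rxns


def _parse_notes(notes_xml: str) -> dict[str, str]:
    out = {}
    for m in re.finditer(r"<p>\s*([^:<]+):\s*([^<]*)</p>", notes_xml):
        out[m.group(1).strip()] = m.group(2).strip()
    return out


def write_sbml(bundle: ModelBundle, path: str | Path) -> None:
    """Write the bundle's model (no inhibition edges) as SBML Level 3."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel("inhibnet_model")
    comp = model.createCompartment()
    comp.setId("default")
    comp.setConstant(True)

    def set_notes(obj, pairs):
        body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs if v)
        obj.setNotes(f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>')

    net = bundle.network
    for mid in sorted(net.metabolites):
        m = net.metabolites[mid]
        sp = model.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment("default")
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        set_notes(sp, [("KEGG", m.kegg_id), ("HMDB", m.hmdb_id), ("SMILES", m.smiles)])
    for i, ec in enumerate(sorted(net.reactions)):
        r = net.reactions[ec]
        rx = model.createReaction()
        rx.setId(f"R{i}")
        rx.setReversible(False)
        rx.setFast(False)
        for s in r.substrates:
            ref = rx.createReactant()
            ref.setSpecies(s)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        for p in r.products:
            ref = rx.createProduct()
            ref.setSpecies(p)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        set_notes(rx, [("EC Number", ec),
                       ("GENE_ASSOCIATION", ";".join(r.genes)),
                       ("SUBSYSTEM", ";".join(r.pathways))])
    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# Inhibitor mapping
# ---------------------------------------------------------------------------


def _normalize_mechanism(label: str) -> str:
    label = label.strip().lower()
    if label in ("", MISSING):
        return "unknown"
    aliases = {
        "non-competitive": "noncompetitive",
        "un-competitive": "uncompetitive",
    }
    label = aliases.get(label, label)
    return label if label in MECHANISMS else "unknown"


def map_inhibitors(bundle: ModelBundle, annotations: str | Path,
                   id_map: str | Path | None = None) -> InhibitionNetwork:
    """Map an inhibitor-annotation snapshot onto the bundle's model.

    ``annotations`` is a TSV with columns (ec, inhibitor, mechanism, species);
    ``inhibitor`` may be a raw name resolved through ``id_map`` (TSV with
    columns name, kegg_id, hmdb_id) or directly a model metabolite ID.

    Resolution preference is KEGG ID > HMDB ID > exact name/ID match.  One
    edge is created per distinct resolved (metabolite, EC) pair; rows whose
    inhibitor cannot be resolved, or whose EC is absent from the model, are
    dropped and counted.  Conflicting mechanism labels for one pair collapse
    to "unknown" with all labels retained in provenance.
    """
    net = bundle.network
    prov = bundle.provenance
    prov.add_file("annotations", annotations)

    by_kegg = {m.kegg_id: m.id for m in net.metabolites.values() if m.kegg_id}
    by_hmdb = {m.hmdb_id: m.id for m in net.metabolites.values() if m.hmdb_id}
    by_name = {m.name: m.id for m in net.metabolites.values()}

    name_map: dict[str, tuple[str | None, str | None]] = {}
    if id_map is not None:
        prov.add_file("id_map", id_map)
        for _, row in _read_tsv(Path(id_map)).iterrows():
            kegg = None if row.get("kegg_id", MISSING) == MISSING else row["kegg_id"]
            hmdb = None if row.get("hmdb_id", MISSING) == MISSING else row["hmdb_id"]
            name_map[row["name"]] = (kegg, hmdb)

    def resolve(raw: str) -> str | None:
        kegg, hmdb = name_map.get(raw, (None, None))
        if kegg and kegg in by_kegg:
            return by_kegg[kegg]
        if hmdb and hmdb in by_hmdb:
            return by_hmdb[hmdb]
        if raw in net.metabolites:
            return raw
        if raw in by_kegg:
            return by_kegg[raw]
        if raw in by_hmdb:
            return by_hmdb[raw]
        return by_name.get(raw)

    ann = _read_tsv(Path(annotations))
    total = len(ann)
    dropped = 0
    mapped_rows = 0
    mech_seen: dict[tuple[str, str], set[str]] = {}
    species_seen: dict[tuple[str, str], set[str]] = {}

    for _, row in ann.iterrows():
        ec = row["ec"].strip()
        mid = resolve(row["inhibitor"].strip())
        if mid is None:
            prov.dropped_records.append({"table": "annotations", "inhibitor": row["inhibitor"],
                                         "reason": "unresolved_inhibitor"})
            dropped += 1
            continue
        if ec not in net.reactions:
            prov.dropped_records.append({"table": "annotations", "ec": ec,
                                         "reason": "ec_not_in_model"})
            dropped += 1
            continue
        mapped_rows += 1
        key = (mid, ec)
        mech = _normalize_mechanism(str(row.get("mechanism", "")))
        mech_seen.setdefault(key, set()).add(mech)
        sp = str(row.get("species", "")).strip()
        if sp and sp != MISSING:
            species_seen.setdefault(key, set()).add(sp)
        else:
            species_seen.setdefault(key, set())

    for key, mechs in sorted(mech_seen.items()):
        informative = mechs - {"unknown"}
        if len(informative) == 1:
            mech = next(iter(informative))
        elif len(informative) > 1:
            mech = "unknown"
            prov.mechanism_conflicts[key] = sorted(mechs)
        else:
            mech = "unknown"
        net.add_edge(InhibitionEdge(metabolite_id=key[0], ec_number=key[1],
                                    mechanism=mech, species_evidence=species_seen[key]))

    prov.counts["annotation_rows"] = total
    prov.counts["annotation_rows_mapped"] = mapped_rows
    prov.counts["annotation_rows_dropped"] = dropped
    prov.counts["edges"] = len(net.edges)
    assert mapped_rows + dropped == total
    return net


# ---------------------------------------------------------------------------
# Cross-network merge report
# ---------------------------------------------------------------------------


@dataclass
class CrossInhibitionReport:
    """Counts from merging a foreign metabolic network into a base network."""

    foreign_metabolites_inhibiting_base: int
    base_metabolites_inhibiting_foreign: int
    n_foreign_only_metabolites: int
    n_foreign_only_reactions: int


def merge_networks(base: InhibitionNetwork, foreign: InhibitionNetwork,
                   combined_annotations: pd.DataFrame) -> CrossInhibitionReport:
    """Cross-inhibition accounting for a hypothetical network merge.

    Given a combined annotation table (columns metabolite_id, ec), counts
    (i) foreign-only metabolites annotated as inhibitors of base reactions and
    (ii) base metabolites annotated as inhibitors of foreign-only reactions.
    Both networks must share an ID namespace; disjoint namespaces simply give
    zero counts (with a warning).
    """
    foreign_only_mets = set(foreign.metabolites) - set(base.metabolites)
    foreign_only_rxns = set(foreign.reactions) - set(base.reactions)
    if not (set(foreign.metabolites) & set(base.metabolites)) and base.metabolites:
        logger.warning("base and foreign networks share no metabolite IDs")

    inhibiting_base = set()
    inhibiting_foreign = set()
    for _, row in combined_annotations.iterrows():
        mid, ec = row["metabolite_id"], row["ec"]
        if mid in foreign_only_mets and ec in base.reactions:
            inhibiting_base.add(mid)
        if mid in base.metabolites and ec in foreign_only_rxns:
            inhibiting_foreign.add(mid)

    return CrossInhibitionReport(
        foreign_metabolites_inhibiting_base=len(inhibiting_base),
        base_metabolites_inhibiting_foreign=len(inhibiting_foreign),
        n_foreign_only_metabolites=len(foreign_only_mets),
        n_foreign_only_reactions=len(foreign_only_rxns),
    )
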