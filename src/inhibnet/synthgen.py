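"""Synthetic model bundles with the statistical structure the analyses assume.

The generator emulates the features of a curated inhibition network that the
downstream statistics rely on, without any download:

* pathways are chains of molecules built by successive small substituent
  additions to a family scaffold, so neighbouring metabolites share large
  common substructures while cross-family pairs do not;
* a few "currency" hub metabolites (phosphate/nucleotide-like scaffolds)
  participate in reactions across all pathways, span multiple compartments,
  and are the most frequent inhibitors;
* inhibition edges are planted preferentially where an inhibitor is
  structurally similar to a reaction substrate (within-family), at a low
  background rate otherwise, and at a high rate for hubs;
* within-organelle similarity-driven self-inhibition is suppressed relative
  to the cytoplasm, emulating selection against organellar self-inhibition;
* essential genes concentrate on hub metabolism;
* initial-rate kinetics data are drawn from a chosen inhibition mechanism
  with multiplicative noise.

All randomness derives from one root seed through deterministic child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinetics as kin
from .chemsim import SimilarityEngine
from .compartments import DEFAULT_COMPARTMENTS, assign_compartments
from .enrich import annotate_essentiality
from .netcore import (InhibitionEdge, InhibitionNetwork, Metabolite, MISSING,
                      ModelBundle, EnzymeReaction, flag_phosphorylated,
                      merge_superclasses)

# scaffold families: (name, head SMILES, substituent units, raw HMDB-like superclass)
# unit alphabets are disjoint across families so cross-family common
# substructures stay small relative to molecule size
SCAFFOLD_FAMILIES = (
    ("diacid", "OC(=O)CC(=O)O", ("C", "CC"), "Organic Acids and Derivatives"),
    ("polyamine", "NCCNCCN", ("CN",), "Amino Acids, Peptides and Analogues"),
    ("polyol", "OCC(O)C(O)CO", ("C(O)",), "Carbohydrates and Carbohydrate Conjugates"),
    ("aromatic", "Oc1ccccc1", ("C",), "Aromatic Homomonocyclic Compounds"),
    ("ether", "COC(C)OC", ("OC",), "Organooxygen Compounds"),
    ("thioether", "CSCCSCC", ("CS",), "Homogeneous Non-metal Compounds"),
)

# currency hubs: phosphate/nucleotide-like scaffolds kept structurally far
# from the chain families
HUB_SCAFFOLDS = (
    ("hub_triphosphate", "OP(=O)(O)OP(=O)(O)OP(=O)(O)OCC1OC(O)C(O)C1O",
     "Nucleosides, Nucleotides, and Analogues"),
    ("hub_diphosphate", "OP(=O)(O)OP(=O)(O)OCC1OC(O)C(O)C1O",
     "Nucleosides, Nucleotides, and Analogues"),
    ("hub_monophosphate", "OP(=O)(O)OCC1OC(O)C(O)C1O",
     "Nucleosides, Nucleotides, and Analogues"),
    ("hub_dihydronicotinamide", "NC(=O)C1=CN(C2OC(COP(=O)(O)O)C(O)C2O)C=CC1",
     "Nucleosides, Nucleotides, and Analogues"),
    ("hub_nicotinamide", "NC(=O)c1ccc[n+](C2OC(COP(=O)(O)O)C(O)C2O)c1",
     "Nucleosides, Nucleotides, and Analogues"),
    ("hub_tripeptide", "OC(=O)C(N)CCC(=O)NC(CS)C(=O)NCC(=O)O",
     "Amino Acids, Peptides and Analogues"),
)

_MECH_SIMILAR = (("competitive", 0.85), ("noncompetitive", 0.10), ("uncompetitive", 0.05))
_MECH_OTHER = (("competitive", 0.35), ("noncompetitive", 0.45), ("uncompetitive", 0.20))
_SPECIES = ("human", "E. coli", "S. cerevisiae", "R. norvegicus")


@dataclass
class SynthConfig:
    n_pathways: int = 6
    pathway_length: int = 8
    n_currency_hubs: int = 6
    p_inhib_similar: float = 0.6
    p_inhib_background: float = 0.03
    p_inhib_hub: float = 0.9
    similarity_threshold: float = 0.8
    organelle_suppression: float = 0.05  # multiplier on similar-edge probability inside organelles
    hub_coupling: float = 0.3            # probability a chain reaction consumes/regenerates a hub
    mechanism_known: float = 0.7         # fraction of edges with a recorded mechanism
    n_compartments: int = 4
    essential_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_inhib_similar, self.p_inhib_background, self.p_inhib_hub,
                  self.essential_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_inhib_similar < self.p_inhib_background:
            raise ValueError("p_inhib_similar must be >= p_inhib_background")
        for c in (self.n_pathways, self.pathway_length, self.n_currency_hubs,
                  self.n_compartments):
            if c < 1:
                raise ValueError("all counts must be >= 1")


@dataclass
class Metabolome:
    metabolites: list[Metabolite]
    pathway_of: dict[str, int]          # metabolite id -> pathway index (hubs absent)
    hub_ids: list[str]
    raw_superclass: dict[str, str]


@dataclass
class GroundTruth:
    planted_edges: dict[tuple[str, str], str]  # (metabolite, ec) -> cause
    compartment_map: dict[str, str]            # pathway label -> compartment
    essential_genes: set[str]
    kinetic_params: list[dict] = field(default_factory=list)


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2 ** 31))


def generate_metabolome(config: SynthConfig) -> Metabolome:
    """Pathway-chained molecules plus currency hubs.

    Pathway ``p`` draws on scaffold family ``p mod 6``; molecule ``j`` of the
    chain is the family head extended by ``j`` substituent units, so adjacent
    chain members differ by one small edit and the smaller always embeds in
    the larger.
    """
    rng = np.random.default_rng(config.seed)
    mets: list[Metabolite] = []
    pathway_of: dict[str, int] = {}
    raw_sc: dict[str, str] = {}
    counter = 0

    for p in range(config.n_pathways):
        fam_name, head, units, raw = SCAFFOLD_FAMILIES[p % len(SCAFFOLD_FAMILIES)]
        tail: list[str] = []
        for j in range(config.pathway_length):
            smiles = head + "".join(tail)
            counter += 1
            mid = f"M_p{p}_{j}"
            m = Metabolite(id=mid, name=f"{fam_name} {p}-{j}",
                           kegg_id=f"C{counter:05d}", hmdb_id=f"HMDB{counter:07d}",
                           smiles=smiles, superclass=merge_superclasses(raw))
            mets.append(m)
            pathway_of[mid] = p
            raw_sc[mid] = raw
            tail.append(units[int(rng.integers(len(units)))])

    hub_ids = []
    for h in range(config.n_currency_hubs):
        name, smiles, raw = HUB_SCAFFOLDS[h % len(HUB_SCAFFOLDS)]
        # beyond the scaffold list, extend the phosphate chain for distinctness
        extra = h // len(HUB_SCAFFOLDS)
        if extra:
            smiles = "OP(=O)(O)" * extra + smiles[1:] if smiles.startswith("O") else smiles
        counter += 1
        mid = f"M_hub{h}"
        m = Metabolite(id=mid, name=f"{name}_{h}",
                       kegg_id=f"C{counter:05d}", hmdb_id=f"HMDB{counter:07d}",
                       smiles=smiles, superclass=merge_superclasses(raw))
        mets.append(m)
        hub_ids.append(mid)
        raw_sc[mid] = raw

    for m in mets:
        m.phosphorylated = flag_phosphorylated(m)
    return Metabolome(metabolites=mets, pathway_of=pathway_of, hub_ids=hub_ids,
                      raw_superclass=raw_sc)


def _pathway_compartment(p: int, labels: tuple[str, ...]) -> str:
    # even pathways cytosolic, odd pathways cycle through the organelles
    if p % 2 == 0 or len(labels) == 1:
        return labels[0]
    return labels[1 + (p // 2) % (len(labels) - 1)]


def generate_network(config: SynthConfig,
                     metabolome: Metabolome | None = None) -> tuple[ModelBundle, GroundTruth]:
    """Assemble the synthetic model, plant inhibition edges, annotate.

    Chain reactions convert pathway neighbours (with hub co-substrates at
    rate ``hub_coupling``); each hub also has a dedicated synthesis reaction
    with an essential gene.  An inhibition edge (m, r) is planted with
    probability ``p_inhib_similar`` when the best substrate similarity
    (MCS overlap) reaches ``similarity_threshold`` (damped by
    ``organelle_suppression`` when the interaction would be organellar
    self-inhibition), ``p_inhib_hub`` for hubs, and ``p_inhib_background``
    otherwise.  The returned bundle is fully annotated (compartments,
    essentiality); GroundTruth records every planted edge and its cause.
    """
    if metabolome is None:
        metabolome = generate_metabolome(config)
    rng = np.random.default_rng(config.seed + 1)

    net = InhibitionNetwork(metabolites={m.id: m for m in metabolome.metabolites})
    labels = DEFAULT_COMPARTMENTS[:config.n_compartments]
    compartment_map = {f"PWY{p}": _pathway_compartment(p, labels)
                       for p in range(config.n_pathways)}

    # chain reactions
    ec_counter: dict[int, int] = {}
    hub_cycle = 0
    for p in range(config.n_pathways):
        cls = (p % 6) + 1
        chain = [m for m, pw in metabolome.pathway_of.items() if pw == p]
        chain.sort(key=lambda mid: int(mid.rsplit("_", 1)[1]))
        for j in range(len(chain) - 1):
            ec_counter[cls] = ec_counter.get(cls, 0) + 1
            ec = f"{cls}.{p + 1}.{j + 1}.{ec_counter[cls]}"
            subs, prods = [chain[j]], [chain[j + 1]]
            if metabolome.hub_ids and j == 0:
                # the most currency-like hubs drive the first step of every
                # pathway, so they span every compartment (ATP/ADP-style)
                subs.append(metabolome.hub_ids[0])
                if len(metabolome.hub_ids) > 1:
                    prods.append(metabolome.hub_ids[1])
            elif metabolome.hub_ids and rng.random() < config.hub_coupling:
                hub = metabolome.hub_ids[hub_cycle % len(metabolome.hub_ids)]
                hub_cycle += 1
                subs.append(hub)
                # regenerate a partner hub so hubs appear on both sides
                partner = metabolome.hub_ids[hub_cycle % len(metabolome.hub_ids)]
                prods.append(partner)
            net.reactions[ec] = EnzymeReaction(
                ec_number=ec, substrates=subs, products=prods,
                genes=[f"G_p{p}_{j}"], pathways=[f"PWY{p}"])

    # hub synthesis reactions (one per hub, essential gene)
    synthesis_genes = []
    for h, hub in enumerate(metabolome.hub_ids):
        p = h % config.n_pathways
        cls = (p % 6) + 1
        ec_counter[cls] = ec_counter.get(cls, 0) + 1
        ec = f"{cls}.{p + 1}.99.{ec_counter[cls]}"
        first = f"M_p{p}_0"
        gene = f"G_hubsyn{h}"
        synthesis_genes.append(gene)
        net.reactions[ec] = EnzymeReaction(
            ec_number=ec, substrates=[first], products=[hub],
            genes=[gene], pathways=[f"PWY{p}"])

    bundle = ModelBundle(network=net)
    locations = pd.DataFrame([{"pathway": pw, "compartment": c}
                              for pw, c in compartment_map.items()])
    assign_compartments(bundle, locations)

    # essential genes: hub synthesis always, chain genes at essential_fraction
    all_genes = sorted({g for r in net.reactions.values() for g in r.genes})
    essential = set(synthesis_genes)
    for g in all_genes:
        if g not in essential and rng.random() < config.essential_fraction:
            essential.add(g)
    annotate_essentiality(bundle, essential)

    # plant inhibition edges
    engine = SimilarityEngine({m.id: m.smiles for m in metabolome.metabolites},
                              metric="mcs_overlap")
    hub_set = set(metabolome.hub_ids)
    planted: dict[tuple[str, str], str] = {}
    organelles = set(labels[1:])
    for ec in sorted(net.reactions):
        rxn = net.reactions[ec]
        for mid in sorted(net.metabolites):
            met = net.metabolites[mid]
            best = 0.0
            for sub in rxn.substrates:
                if sub == mid:
                    continue
                s = engine.pair_score(mid, sub)
                if s is not None:
                    best = max(best, s)
            if mid in hub_set:
                cause, p_edge = "hub", config.p_inhib_hub
            elif best >= config.similarity_threshold:
                cause, p_edge = "similar", config.p_inhib_similar
            else:
                cause, p_edge = "background", config.p_inhib_background
            if cause != "hub":
                # organellar co-localized inhibition is depleted (selection
                # against self-inhibition inside organelles); cytoplasmic
                # co-localization is untouched
                shared = met.compartments & rxn.compartments
                if shared and shared <= organelles:
                    p_edge *= config.organelle_suppression
            if rng.random() >= p_edge:
                continue
            mechs, probs = zip(*(_MECH_SIMILAR if cause == "similar" else _MECH_OTHER))
            mech = str(rng.choice(mechs, p=probs))
            if rng.random() >= config.mechanism_known:
                mech = "unknown"
            species = set(rng.choice(_SPECIES,
                                     size=int(rng.integers(1, len(_SPECIES) + 1)),
                                     replace=False))
            net.add_edge(InhibitionEdge(metabolite_id=mid, ec_number=ec,
                                        mechanism=mech, species_evidence=species))
            planted[(mid, ec)] = cause

    net.validate()
    bundle.provenance.counts.update({
        "metabolites": len(net.metabolites), "reactions": len(net.reactions),
        "edges": len(net.edges)})
    truth = GroundTruth(planted_edges=planted, compartment_map=compartment_map,
                        essential_genes=essential)
    return bundle, truth


def gold_standard_table(network, seed: int | None = None) -> pd.DataFrame:
    """Gold-standard mechanism table: edges with a recorded mechanism."""
    rows = [{"metabolite_id": e.metabolite_id, "ec": e.ec_number,
             "mechanism": e.mechanism, "reference": "synthetic"}
            for e in network.edges if e.mechanism != "unknown"]
    return pd.DataFrame(rows, columns=["metabolite_id", "ec", "mechanism", "reference"])


def generate_kinetics(mechanism: str, vmax: float, km: float, ki: float,
                      design: list[tuple[float, float]], noise_cv: float = 0.0,
                      seed: int | None = None) -> kin.RateDataset:
    """Initial rates from a mechanism's law with multiplicative Gaussian noise.

    ``design`` is a list of (substrate, inhibitor) concentration pairs in mM;
    ``noise_cv`` is the coefficient of variation of the multiplicative error
    (0 gives exact law values).
    """
    if not design:
        raise ValueError("design must be non-empty")
    S = np.array([s for s, _ in design], dtype=float)
    I = np.array([i for _, i in design], dtype=float)
    v = kin.rate(mechanism, S, I, vmax, km, ki)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + noise_cv * rng.standard_normal(len(v)))
    return kin.RateDataset(data=pd.DataFrame({"S_mM": S, "I_mM": I, "rate": v}))


DEFAULT_KINETIC_DESIGN = [(s, i)
                          for i in (0.0, 2.5, 5.0, 7.5)
                          for s in (0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0)]


# ---------------------------------------------------------------------------
# File emission (the exact TSV/SMILES set netcore reads)
# ---------------------------------------------------------------------------


def write_bundle(bundle: ModelBundle, metabolome: Metabolome, truth: GroundTruth,
                 outdir: str | Path) -> None:
    """Write the generated model as the netcore TSV file set.

    Emits metabolites.tsv, reactions.tsv, pathways.tsv, superclass.tsv,
    annotations.tsv (inhibitors by raw name), idmap.tsv, structures.smi and
    essential_genes.txt, all parseable by netcore with zero dropped rows.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = bundle.network

    pd.DataFrame([{"id": m.id, "name": m.name, "kegg_id": m.kegg_id or MISSING,
                   "hmdb_id": m.hmdb_id or MISSING, "smiles": m.smiles or MISSING}
                  for m in net.metabolites.values()]).to_csv(
        outdir / "metabolites.tsv", sep="\t", index=False)

    pd.DataFrame([{"ec": r.ec_number,
                   "substrates": ";".join(r.substrates) or MISSING,
                   "products": ";".join(r.products) or MISSING,
                   "genes": ";".join(r.genes) or MISSING,
                   "pathways": ";".join(r.pathways) or MISSING}
                  for r in net.reactions.values()]).to_csv(
        outdir / "reactions.tsv", sep="\t", index=False)

    pd.DataFrame([{"pathway": pw, "compartment": c}
                  for pw, c in truth.compartment_map.items()]).to_csv(
        outdir / "pathways.tsv", sep="\t", index=False)

    pd.DataFrame([{"metabolite_id": mid, "superclass": raw}
                  for mid, raw in metabolome.raw_superclass.items()]).to_csv(
        outdir / "superclass.tsv", sep="\t", index=False)

    ann_rows = []
    for e in net.edges:
        met = net.metabolites[e.metabolite_id]
        ann_rows.append({"ec": e.ec_number, "inhibitor": met.name,
                         "mechanism": e.mechanism if e.mechanism != "unknown" else MISSING,
                         "species": ";".join(sorted(e.species_evidence)) or MISSING})
    pd.DataFrame(ann_rows, columns=["ec", "inhibitor", "mechanism", "species"]).to_csv(
        outdir / "annotations.tsv", sep="\t", index=False)

    pd.DataFrame([{"name": m.name, "kegg_id": m.kegg_id or MISSING,
                   "hmdb_id": m.hmdb_id or MISSING}
                  for m in net.metabolites.values()]).to_csv(
        outdir / "idmap.tsv", sep="\t", index=False)

    with open(outdir / "structures.smi", "w") as fh:
        for m in net.metabolites.values():
            if m.smiles:
                fh.write(f"{m.smiles}\t{m.id}\n")

    (outdir / "essential_genes.txt").write_text(
        "\n".join(sorted(truth.essential_genes)) + "\n")
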