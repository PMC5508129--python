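"""Shared fixtures: small hand-built models and one seeded synthetic bundle."""

from __future__ import annotations

import itertools

import pandas as pd
import pytest

from inhibnet import chemsim, netcore, synthgen

# small molecules (all <= 10 heavy atoms) used throughout the chemistry tests
FIXTURE_SMILES = {
    "pyruvate": "CC(=O)C(=O)O",
    "oxaloacetate": "OC(=O)CC(=O)C(=O)O",
    "malonate": "OC(=O)CC(=O)O",
    "lactate": "CC(O)C(=O)O",
    "acetate": "CC(=O)O",
    "succinate": "OC(=O)CCC(=O)O",
    "glycerol": "OCC(O)CO",
    "alanine": "CC(N)C(=O)O",
    "phenol": "Oc1ccccc1",
    "ethanol": "CCO",
    "water": "O",
}


@pytest.fixture(scope="session")
def molecules():
    return {name: chemsim.parse_structure(smi) for name, smi in FIXTURE_SMILES.items()}


@pytest.fixture(scope="session")
def synth_default():
    """Default-condition synthetic bundle (generated once per session)."""
    cfg = synthgen.SynthConfig(seed=1)
    metabolome = synthgen.generate_metabolome(cfg)
    bundle, truth = synthgen.generate_network(cfg, metabolome)
    return cfg, metabolome, bundle, truth


def write_toy_model(tmpdir):
    """Six metabolites, three reactions, no inhibition annotations yet."""
    (tmpdir / "metabolites.tsv").write_text(
        "id\tname\tkegg_id\thmdb_id\tsmiles\n"
        "m1\tpyruvate\tC00022\tHMDB0000243\tCC(=O)C(=O)O\n"
        "m2\toxaloacetate\tC00036\tHMDB0000223\tOC(=O)CC(=O)C(=O)O\n"
        "m3\tmalonate\tC00383\tHMDB0000691\tOC(=O)CC(=O)O\n"
        "m4\tlactate\tC00186\tHMDB0000190\tCC(O)C(=O)O\n"
        "m5\tatp_like\tC00002\tHMDB0000538\tOP(=O)(O)OP(=O)(O)OP(=O)(O)OCC1OC(O)C(O)C1O\n"
        "m6\tacetate\tC00033\tHMDB0000042\tCC(=O)O\n")
    (tmpdir / "reactions.tsv").write_text(
        "ec\tsubstrates\tproducts\tgenes\tpathways\n"
        "1.1.1.27\tm1;m5\tm4\tgA\tPWY_A\n"
        "2.6.1.1\tm2\tm1\tgB\tPWY_A\n"
        "3.1.3.3\tm3;m6\tm2\tgC;gD\tPWY_B\n")
    (tmpdir / "superclass.tsv").write_text(
        "metabolite_id\tsuperclass\n"
        "m1\tOrganic Acids and Derivatives\n"
        "m2\tOrganic Acids and Derivatives\n"
        "m3\tOrganic Acids and Derivatives\n"
        "m5\tNucleosides, Nucleotides, and Analogues\n")
    return tmpdir


@pytest.fixture()
def toy_model_dir(tmp_path):
    return write_toy_model(tmp_path)


@pytest.fixture()
def toy_bundle(toy_model_dir):
    return netcore.load_model(toy_model_dir, superclass_map=toy_model_dir / "superclass.tsv")


def build_network(metabolite_classes: dict[str, str],
                  reactions: dict[str, dict],
                  edges: list[tuple[str, str, str]]) -> netcore.InhibitionNetwork:
    """Hand-build a network: classes by metabolite, reactions keyed by EC."""
    mets = {mid: netcore.Metabolite(id=mid, name=mid, superclass=cls)
            for mid, cls in metabolite_classes.items()}
    rxns = {ec: netcore.EnzymeReaction(ec_number=ec, **fields)
            for ec, fields in reactions.items()}
    net = netcore.InhibitionNetwork(metabolites=mets, reactions=rxns)
    for mid, ec, mech in edges:
        net.add_edge(netcore.InhibitionEdge(metabolite_id=mid, ec_number=ec,
                                            mechanism=mech))
    return net


# ---------------------------------------------------------------------------
# Exhaustive MCS oracle, independent of the search engine: enumerate every
# connected atom subset of the smaller molecule (largest first) and test for
# an induced, label- and bond-order-preserving embedding by brute force.
# ---------------------------------------------------------------------------


def mcs_size_exhaustive(a: chemsim.MolecularGraph, b: chemsim.MolecularGraph) -> int:
    small, big = (a, b) if a.n_atoms <= b.n_atoms else (b, a)
    n = small.n_atoms

    subsets: set[frozenset] = set()

    def enum(cur: frozenset, cand: set, banned: frozenset) -> None:
        subsets.add(cur)
        cand = set(cand)
        while cand:
            v = min(cand)
            cand.remove(v)
            enum(cur | {v}, (cand | (small.adjacency[v] - cur)) - banned - {v},
                 banned | {v})
            banned = banned | {v}

    for s in range(n):
        enum(frozenset([s]), set(small.adjacency[s]) - set(range(s + 1)),
             frozenset(range(s)))

    def embeds(subset: list[int]) -> bool:
        def place(k: int, assign: dict) -> bool:
            if k == len(subset):
                return True
            i = subset[k]
            for j in range(big.n_atoms):
                if j in assign.values() or small.atoms[i] != big.atoms[j]:
                    continue
                if all(small.bond(i, i2) == big.bond(j, assign[i2]) for i2 in subset[:k]):
                    assign[i] = j
                    if place(k + 1, assign):
                        return True
                    del assign[i]
            return False

        return place(0, {})

    for size in range(n, 0, -1):
        for sub in sorted(map(tuple, (sorted(s) for s in subsets if len(s) == size))):
            if embeds(list(sub)):
                return size
    return 0


@pytest.fixture(scope="session")
def mcs_oracle():
    return mcs_size_exhaustive


def all_fixture_pairs():
    names = sorted(FIXTURE_SMILES)
    return list(itertools.combinations(names, 2))
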