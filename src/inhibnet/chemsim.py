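"""Molecular graphs, maximum-common-substructure and fingerprint similarity.

The central quantity is the maximum common connected substructure (MCS)
between two heavy-atom molecular graphs under exact element/charge and
bond-order matching (aromatic bonds match only aromatic bonds), from which
two coefficients are derived:

* overlap coefficient = |MCS| / min(|A|, |B|)  (1 when the smaller molecule
  embeds entirely in the larger), and
* MCS Tanimoto        = |MCS| / (|A| + |B| - |MCS|).

A hashed-path fingerprint with bitwise Tanimoto, and a simple atom-pair
similarity, complement the MCS metrics.  ``best_substrate_similarity``
implements the best-substrate-match convention used to compare inhibitors
against enzyme substrates, and ``random_similarity_null`` the pool-size
corrected resampling null (k random metabolites, 50 repeats).
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass, field

import numpy as np

METRICS = ("fp_tanimoto", "mcs_tanimoto", "mcs_overlap", "atompair")

BondOrder = object  # int 1|2|3 or the string "ar"


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class MolecularGraph:
    """Hydrogen-suppressed molecular graph.

    atoms: tuple of (element symbol, formal charge); bonds: mapping of
    index pairs (i < j) to bond order (1, 2, 3 or "ar" for aromatic).
    """

    atoms: tuple[tuple[str, int], ...]
    bonds: dict[tuple[int, int], object]
    adjacency: tuple[frozenset, ...] = field(default=(), compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def bond(self, i: int, j: int):
        return self.bonds.get((i, j) if i < j else (j, i))


def _graph_from_rdkit(mol) -> MolecularGraph:
    atoms = tuple((a.GetSymbol(), a.GetFormalCharge()) for a in mol.GetAtoms())
    bonds = {}
    adj = [set() for _ in atoms]
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        order = "ar" if b.GetIsAromatic() else int(b.GetBondTypeAsDouble())
        bonds[(min(i, j), max(i, j))] = order
        adj[i].add(j)
        adj[j].add(i)
    return MolecularGraph(atoms=atoms, bonds=bonds,
                          adjacency=tuple(frozenset(s) for s in adj))


def parse_structure(text: str) -> MolecularGraph:
    """Parse a SMILES string or an SDF (V2000 molfile) record.

    Heavy-atom graph with aromatic perception; hydrogens suppressed.
    Raises :class:`ParseError` naming the offending record on invalid input.
    """
    from rdkit import Chem

    if not text or not text.strip():
        raise ParseError("empty structure record")
    if "V2000" in text or text.count("\n") > 2:
        mol = Chem.MolFromMolBlock(text, sanitize=True)
    else:
        mol = Chem.MolFromSmiles(text.strip())
    if mol is None:
        raise ParseError(f"could not parse structure record: {text.strip()[:60]!r}")
    return _graph_from_rdkit(mol)


# ---------------------------------------------------------------------------
# Maximum common connected substructure
# ---------------------------------------------------------------------------


@dataclass
class MCSResult:
    size: int
    atoms_a: int
    atoms_b: int
    mapping: tuple[tuple[int, int], ...]
    approximate: bool = False


@dataclass
class SimilarityResult:
    score: float
    metric: str


def mcs(a: MolecularGraph, b: MolecularGraph, timeout_s: float | None = None,
        atom_budget: int = 60, node_budget: int = 15_000) -> MCSResult:
    """Maximum common connected induced substructure of two molecules.

    Matching is exact on (element, formal charge) and on bond order, with
    aromatic bonds matching only aromatic bonds; the matched subgraph must be
    connected and induced (a bond between two matched atoms must be present
    with the same order in both molecules, or absent in both).  The search is
    a branch-and-bound extension of atom-pair mappings, explored in sorted
    index order so the returned witness mapping is deterministic (the first
    maximum encountered in lexicographic order).

    The search is bounded by a deterministic expansion budget
    (``node_budget``) rather than wall-clock time, so identical inputs give
    identical results on any machine; an optional ``timeout_s`` adds a
    wall-clock cap on top.  Exhausting either budget, or molecules beyond
    ``atom_budget`` heavy atoms, return the best mapping found so far with
    ``approximate=True``.
    """
    if a.n_atoms < 1 or b.n_atoms < 1:
        raise ValueError("both molecules must have at least one heavy atom")

    # search from the smaller side for a tighter bound; remember orientation
    swapped = a.n_atoms > b.n_atoms
    A, B = (b, a) if swapped else (a, b)
    approximate = A.n_atoms > atom_budget or B.n_atoms > atom_budget
    deadline = time.monotonic() + timeout_s if timeout_s is not None else None

    nA, nB = A.n_atoms, B.n_atoms
    compat = [[A.atoms[i] == B.atoms[j] for j in range(nB)] for i in range(nA)]
    # O(1) bond-order lookup tables
    BA = [[None] * nA for _ in range(nA)]
    for (i, j), o in A.bonds.items():
        BA[i][j] = BA[j][i] = o
    BB = [[None] * nB for _ in range(nB)]
    for (i, j), o in B.bonds.items():
        BB[i][j] = BB[j][i] = o

    # element-count ceiling on any common subgraph size, maintained
    # incrementally as atoms are consumed
    from collections import Counter

    rem_a = Counter(A.atoms)
    rem_b = Counter(B.atoms)
    upper_total = sum(min(rem_a[k], rem_b[k]) for k in rem_a)
    labels = list(rem_a.keys())

    best_map: list[tuple[int, int]] = []
    budget = [node_budget]
    out_of_budget = False

    def extend(mapping: dict[int, int], used_b: set[int]) -> None:
        nonlocal best_map, out_of_budget
        if out_of_budget:
            return
        budget[0] -= 1
        if budget[0] <= 0 or (deadline is not None and time.monotonic() > deadline):
            out_of_budget = True
            return
        if len(mapping) > len(best_map):
            best_map = sorted(mapping.items())
            if len(best_map) == upper_total:
                return
        headroom = sum(min(rem_a[k], rem_b[k]) for k in labels)
        if len(mapping) + headroom <= len(best_map):
            return
        frontier_a = sorted({i for i2 in mapping for i in A.adjacency[i2] if i not in mapping})
        image_adj = sorted({j for j2 in mapping.values() for j in B.adjacency[j2]
                            if j not in used_b})
        items = list(mapping.items())
        cands = []
        for i in frontier_a:
            rowA = BA[i]
            crow = compat[i]
            for j in image_adj:
                if not crow[j]:
                    continue
                rowB = BB[j]
                ok = True
                touches = False
                for i2, j2 in items:
                    oa = rowA[i2]
                    if oa != rowB[j2]:
                        ok = False
                        break
                    if oa is not None:
                        touches = True
                if ok and touches:
                    cands.append((i, j))
        for i, j in cands:
            if len(best_map) == upper_total or out_of_budget:
                return
            la, lb = A.atoms[i], B.atoms[j]
            mapping[i] = j
            used_b.add(j)
            rem_a[la] -= 1
            rem_b[lb] -= 1
            extend(mapping, used_b)
            rem_a[la] += 1
            rem_b[lb] += 1
            del mapping[i]
            used_b.discard(j)

    for i in range(nA):
        if len(best_map) == upper_total or out_of_budget:
            break
        la = A.atoms[i]
        for j in range(nB):
            if compat[i][j]:
                if not best_map:
                    best_map = [(i, j)]
                rem_a[la] -= 1
                rem_b[B.atoms[j]] -= 1
                extend({i: j}, {j})
                rem_a[la] += 1
                rem_b[B.atoms[j]] += 1
            if len(best_map) == upper_total or out_of_budget:
                break

    mapping = tuple((j, i) for i, j in best_map) if swapped else tuple(best_map)
    mapping = tuple(sorted(mapping))
    return MCSResult(size=len(best_map), atoms_a=a.n_atoms, atoms_b=b.n_atoms,
                     mapping=mapping, approximate=approximate or out_of_budget)


def mcs_overlap(r: MCSResult) -> SimilarityResult:
    """Overlap coefficient: MCS size over the smaller molecule's size."""
    return SimilarityResult(score=r.size / min(r.atoms_a, r.atoms_b), metric="mcs_overlap")


def mcs_tanimoto(r: MCSResult) -> SimilarityResult:
    """MCS Tanimoto: common atoms over total distinct atoms."""
    return SimilarityResult(score=r.size / (r.atoms_a + r.atoms_b - r.size),
                            metric="mcs_tanimoto")


# ---------------------------------------------------------------------------
# Hashed-path fingerprint
# ---------------------------------------------------------------------------

FP_NBITS = 1024
FP_SCHEME = f"hashed-paths-0-7/{FP_NBITS}"


@dataclass
class Fingerprint:
    bits: np.ndarray  # boolean vector of length FP_NBITS
    scheme: str = FP_SCHEME


def fingerprint(m: MolecularGraph, n_bits: int = FP_NBITS) -> Fingerprint:
    """Hashed-path fingerprint.

    All simple paths of 1..8 atoms (length 0-7 bonds) are enumerated; each
    path is labelled by its sequence of (element, charge) atom labels
    interleaved with bond orders, canonicalized to the lexicographically
    smaller read direction, and hashed (CRC32) onto a fixed-length bit
    vector.  Any molecule with >= 1 atom sets at least one bit (its single
    atoms are length-0 paths).
    """
    bits = np.zeros(n_bits, dtype=bool)

    def label(path: list[int]) -> str:
        toks = []
        for k, idx in enumerate(path):
            sym, chg = m.atoms[idx]
            toks.append(f"{sym}{chg:+d}" if chg else sym)
            if k + 1 < len(path):
                toks.append(str(m.bond(idx, path[k + 1])))
        forward = "|".join(toks)
        backward = "|".join(reversed(toks))
        return min(forward, backward)

    def walk(path: list[int]) -> None:
        bits[zlib.crc32(label(path).encode()) % n_bits] = True
        if len(path) == 8:
            return
        for nxt in sorted(m.adjacency[path[-1]]):
            if nxt not in path:
                walk(path + [nxt])

    for start in range(m.n_atoms):
        walk([start])
    return Fingerprint(bits=bits)


def fp_tanimoto(f1: Fingerprint, f2: Fingerprint) -> SimilarityResult:
    """Bitwise Tanimoto |AND|/|OR|; defined as 1.0 for two all-zero vectors."""
    union = np.logical_or(f1.bits, f2.bits).sum()
    if union == 0:
        return SimilarityResult(score=1.0, metric="fp_tanimoto")
    inter = np.logical_and(f1.bits, f2.bits).sum()
    return SimilarityResult(score=inter / union, metric="fp_tanimoto")


def _atom_pairs(m: MolecularGraph) -> dict:
    """Multiset of (element_i, element_j, topological distance) descriptors."""
    from collections import Counter, deque

    pairs: Counter = Counter()
    for src in range(m.n_atoms):
        dist = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            for v in m.adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        for dst, d in dist.items():
            if dst > src:
                e1, e2 = sorted((m.atoms[src][0], m.atoms[dst][0]))
                pairs[(e1, e2, d)] += 1
    return pairs


def atompair_similarity(a: MolecularGraph, b: MolecularGraph) -> SimilarityResult:
    """Tanimoto over atom-pair descriptor multisets (ordering-compatible stub)."""
    pa, pb = _atom_pairs(a), _atom_pairs(b)
    inter = sum(min(pa[k], pb[k]) for k in pa.keys() & pb.keys())
    union = sum(pa.values()) + sum(pb.values()) - inter
    if union == 0:
        return SimilarityResult(score=1.0, metric="atompair")
    return SimilarityResult(score=inter / union, metric="atompair")


# ---------------------------------------------------------------------------
# Pairwise dispatch with caching
# ---------------------------------------------------------------------------


class SimilarityEngine:
    """Caches parsed graphs, fingerprints and pairwise scores for a network."""

    def __init__(self, structures: dict[str, str], metric: str = "mcs_overlap",
                 timeout_s: float | None = None):
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        self.metric = metric
        self.timeout_s = timeout_s
        self._smiles = structures
        self._graphs: dict[str, MolecularGraph | None] = {}
        self._fps: dict[str, Fingerprint] = {}
        self._pair_cache: dict[tuple[str, str], float] = {}

    def graph(self, mid: str) -> MolecularGraph | None:
        if mid not in self._graphs:
            smi = self._smiles.get(mid)
            try:
                self._graphs[mid] = parse_structure(smi) if smi else None
            except ParseError:
                self._graphs[mid] = None
        return self._graphs[mid]

    def _fp(self, mid: str) -> Fingerprint:
        if mid not in self._fps:
            self._fps[mid] = fingerprint(self.graph(mid))
        return self._fps[mid]

    def pair_score(self, m1: str, m2: str) -> float | None:
        """Similarity between two metabolites by ID; None if either lacks structure."""
        key = (m1, m2) if m1 <= m2 else (m2, m1)
        if key in self._pair_cache:
            return self._pair_cache[key]
        g1, g2 = self.graph(m1), self.graph(m2)
        if g1 is None or g2 is None:
            return None
        if self.metric == "fp_tanimoto":
            score = fp_tanimoto(self._fp(m1), self._fp(m2)).score
        elif self.metric == "atompair":
            score = atompair_similarity(g1, g2).score
        else:
            r = mcs(g1, g2, timeout_s=self.timeout_s)
            score = (mcs_overlap(r) if self.metric == "mcs_overlap" else mcs_tanimoto(r)).score
        self._pair_cache[key] = score
        return score


def similarity(a: MolecularGraph, b: MolecularGraph, metric: str = "mcs_overlap",
               timeout_s: float | None = None) -> SimilarityResult:
    """One-shot pairwise similarity under any supported metric."""
    if metric == "fp_tanimoto":
        return fp_tanimoto(fingerprint(a), fingerprint(b))
    if metric == "atompair":
        return atompair_similarity(a, b)
    r = mcs(a, b, timeout_s=timeout_s)
    if metric == "mcs_overlap":
        return mcs_overlap(r)
    if metric == "mcs_tanimoto":
        return mcs_tanimoto(r)
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# Best-substrate match and resampling null
# ---------------------------------------------------------------------------


def _engine_for(network, metric: str) -> SimilarityEngine:
    structures = {mid: m.smiles for mid, m in network.metabolites.items() if m.smiles}
    return SimilarityEngine(structures, metric=metric)


def best_substrate_similarity(inhibitor_id: str, ec: str, network,
                              metric: str = "mcs_overlap",
                              engine: SimilarityEngine | None = None) -> SimilarityResult | None:
    """Best match between an inhibitor and the enzyme's substrates.

    The maximum pairwise similarity over the reaction's substrate list; a
    substrate identical to the inhibitor is excluded from the comparison.
    Returns None when no substrate with a structure remains.
    """
    eng = engine or _engine_for(network, metric)
    rxn = network.reactions[ec]
    scores = []
    for sub in rxn.substrates:
        if sub == inhibitor_id:
            continue
        s = eng.pair_score(inhibitor_id, sub)
        if s is not None:
            scores.append(s)
    if not scores:
        return None
    return SimilarityResult(score=max(scores), metric=eng.metric)


def random_similarity_null(inhibitor_id: str, k: int, pool: list[str],
                           repeats: int = 50, seed: int | None = None,
                           metric: str = "mcs_overlap",
                           engine: SimilarityEngine | None = None,
                           network=None) -> list[float]:
    """Pool-size corrected resampling null for best-match similarity.

    Per repeat, ``k`` metabolites are drawn uniformly without replacement
    from ``pool`` (the inhibitor itself excluded) and the best pairwise
    similarity to the inhibitor is recorded; returns one score per repeat.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    eligible = sorted(set(pool) - {inhibitor_id})
    if len(eligible) < k:
        raise ValueError(f"pool of {len(eligible)} (after excluding the inhibitor) < k={k}")
    eng = engine
    if eng is None:
        if network is None:
            raise ValueError("provide either an engine or a network")
        eng = _engine_for(network, metric)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        sample = rng.choice(eligible, size=k, replace=False)
        scores = [s for s in (eng.pair_score(inhibitor_id, m) for m in sample) if s is not None]
        out.append(max(scores) if scores else float("nan"))
    return out


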