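"""Hypergeometric enrichment with permutation FDR, essentiality comparisons,
pathway-level statistics and gold-standard mechanism tallies.

The enrichment universe is edge-level: N counts inhibitory interactions, not
metabolites, so a metabolite inhibiting ten enzymes contributes ten draws.
Significance is the exact hypergeometric upper tail P(X >= k); the false
discovery rate for a class pair is estimated by reshuffling the inhibitor
class labels (class sizes preserved) n_perm times and counting permutations
whose p-value ties or beats the observed one (FDR = counter / n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .netcore import ENZYME_CLASS_NAMES, MECHANISMS, SUPERCLASS_GROUPS, UNCLASSIFIED


@dataclass
class EnrichmentResult:
    from_group: str
    to_group: str
    k: int
    K: int
    n: int
    N: int
    p: float
    fdr: float | None = None
    flagged: bool = False  # True when a margin is empty (p forced to 1)


@dataclass
class MechanismTally:
    counts: dict[str, int]
    fractions: dict[str, float]
    n: int
    dropped: int


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact over-representation tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"inconsistent hypergeometric parameters k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


# ---------------------------------------------------------------------------
# Inhibitor-class x enzyme-class enrichment
# ---------------------------------------------------------------------------


def _edge_class_table(network, class_of: dict[str, str] | None = None) -> pd.DataFrame:
    """One row per inhibitory interaction with its inhibitor and enzyme class."""
    rows = []
    for e in network.edges:
        met = network.metabolites[e.metabolite_id]
        sclass = class_of[e.metabolite_id] if class_of else met.superclass
        rows.append({"metabolite_id": e.metabolite_id, "ec": e.ec_number,
                     "inhibitor_class": sclass,
                     "enzyme_class": ENZYME_CLASS_NAMES[network.reactions[e.ec_number].enzyme_class]})
    return pd.DataFrame(rows, columns=["metabolite_id", "ec", "inhibitor_class", "enzyme_class"])


def _pair_pvalues(table: pd.DataFrame, from_groups, to_groups) -> list[EnrichmentResult]:
    N = len(table)
    K_of = table["inhibitor_class"].value_counts().to_dict()
    n_of = table["enzyme_class"].value_counts().to_dict()
    k_of = table.groupby(["inhibitor_class", "enzyme_class"]).size().to_dict()
    out = []
    for c in from_groups:
        for ez in to_groups:
            K = K_of.get(c, 0)
            n = n_of.get(ez, 0)
            k = k_of.get((c, ez), 0)
            if K == 0 or n == 0 or N == 0:
                out.append(EnrichmentResult(c, ez, k, K, n, N, p=1.0, flagged=True))
            else:
                out.append(EnrichmentResult(c, ez, k, K, n, N,
                                            p=hypergeom_upper_tail(k, K, n, N)))
    return out


def class_enrichment(network, alpha: float = 0.05) -> list[EnrichmentResult]:
    """Enrichment of the 8 inhibitor superclasses against the 6 enzyme classes.

    For each (superclass C, enzyme class E) pair: k = interactions from C to
    E, K = all interactions from C, n = all interactions to E, N = all
    interactions.  Pairs with an empty margin get p = 1 and are flagged.
    Metabolites without a superclass annotation enter as "unclassified".
    """
    table = _edge_class_table(network)
    groups = list(SUPERCLASS_GROUPS)
    if (table["inhibitor_class"] == UNCLASSIFIED).any():
        groups.append(UNCLASSIFIED)
    return _pair_pvalues(table, groups, list(ENZYME_CLASS_NAMES.values()))


def permutation_fdr(network, observed: list[EnrichmentResult], n_perm: int = 100,
                    seed: int | None = None) -> list[EnrichmentResult]:
    """Permutation FDR by reshuffling inhibitor class labels.

    Inhibitor metabolites are randomly reassigned to classes with class sizes
    preserved; for each observed pair, FDR = (#permutations with p <= observed
    p) / n_perm.  Ties count against the pair (conservative).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    inhibitors = sorted({e.metabolite_id for e in network.edges})
    labels = [network.metabolites[m].superclass for m in inhibitors]
    from_groups = sorted({r.from_group for r in observed})
    to_groups = sorted({r.to_group for r in observed})

    counter = {(r.from_group, r.to_group): 0 for r in observed}
    obs_p = {(r.from_group, r.to_group): r.p for r in observed}
    for _ in range(n_perm):
        shuffled = list(labels)
        rng.shuffle(shuffled)
        class_of = dict(zip(inhibitors, shuffled))
        table = _edge_class_table(network, class_of=class_of)
        for r in _pair_pvalues(table, from_groups, to_groups):
            key = (r.from_group, r.to_group)
            if key in counter and r.p <= obs_p[key]:
                counter[key] += 1

    out = []
    for r in observed:
        fdr = counter[(r.from_group, r.to_group)] / n_perm
        out.append(EnrichmentResult(r.from_group, r.to_group, r.k, r.K, r.n, r.N,
                                    p=r.p, fdr=fdr, flagged=r.flagged))
    return out


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"from_class": r.from_group, "to_class": r.to_group, "k": r.k, "K": r.K,
          "n": r.n, "N": r.N, "p": r.p, "fdr": r.fdr} for r in results])


# ---------------------------------------------------------------------------
# Pathway-level statistics
# ---------------------------------------------------------------------------


def _pathway_members(network) -> dict[str, set[str]]:
    """pathway -> set of metabolite ids participating in its reactions."""
    members: dict[str, set[str]] = {}
    for r in network.reactions.values():
        for pw in r.pathways:
            members.setdefault(pw, set()).update(r.substrates, r.products)
    return members


def pathway_pair_similarity(network, pathway_a: str, pathway_b: str,
                            metric: str = "fp_tanimoto",
                            engine=None) -> float | None:
    """Mean structural similarity between two pathways' metabolites.

    Shared compounds (currency metabolites present in both pathways) and
    metabolites that are not inhibitors in the network are excluded; the
    score is the mean pairwise similarity over the remaining cross-pathway
    pairs (within-pathway pairs when a pathway is compared with itself).
    Returns None when no eligible pair remains.
    """
    from .chemsim import SimilarityEngine

    members = _pathway_members(network)
    if pathway_a not in members or pathway_b not in members:
        raise KeyError(f"unknown pathway {pathway_a!r} or {pathway_b!r}")
    inhibitors = {e.metabolite_id for e in network.edges}
    shared = members[pathway_a] & members[pathway_b] if pathway_a != pathway_b else set()
    set_a = sorted((members[pathway_a] - shared) & inhibitors)
    set_b = sorted((members[pathway_b] - shared) & inhibitors)
    if engine is None:
        structures = {m: network.metabolites[m].smiles
                      for m in network.metabolites if network.metabolites[m].smiles}
        engine = SimilarityEngine(structures, metric=metric)
    if pathway_a == pathway_b:
        pairs = [(x, y) for i, x in enumerate(set_a) for y in set_a[i + 1:]]
    else:
        pairs = [(x, y) for x in set_a for y in set_b if x != y]
    scores = [s for s in (engine.pair_score(x, y) for x, y in pairs) if s is not None]
    if not scores:
        return None
    return float(np.mean(scores))


def pathway_inhibition_enrichment(network, p_threshold: float = 0.01) -> list[EnrichmentResult]:
    """Significant directed pathway->pathway inhibition pairs.

    An interaction counts from pathway P to pathway Q when the inhibitor
    participates in P and the inhibited reaction belongs to Q; metabolites
    common to both pathways are excluded.  Hypergeometric upper tail on the
    pathway margins, retained at p < ``p_threshold``.
    """
    members = _pathway_members(network)
    interactions = []  # (from_pathway, to_pathway) per edge-pathway pair
    for e in network.edges:
        met_pathways = {pw for pw, mem in members.items() if e.metabolite_id in mem}
        rxn_pathways = set(network.reactions[e.ec_number].pathways)
        for p_from in met_pathways:
            for p_to in rxn_pathways:
                if p_from != p_to and e.metabolite_id in members.get(p_to, set()):
                    continue  # common metabolite of both pathways: excluded
                interactions.append((p_from, p_to))
    if not interactions:
        return []
    table = pd.DataFrame(interactions, columns=["inhibitor_class", "enzyme_class"])
    table["metabolite_id"] = ""
    table["ec"] = ""
    results = _pair_pvalues(table, sorted({i for i, _ in interactions}),
                            sorted({j for _, j in interactions}))
    return [r for r in results if r.p < p_threshold]


# ---------------------------------------------------------------------------
# Essentiality
# ---------------------------------------------------------------------------


def annotate_essentiality(bundle, essential_genes: set[str] | list[str]) -> None:
    """Flag metabolites and enzymes as essential from an essential-gene list.

    An enzyme is essential iff any of its associated genes is essential; a
    metabolite is essential iff any gene of any reaction it participates in
    (as substrate or product) is essential.  An empty list flags everything
    False.
    """
    essential = set(essential_genes)
    net = bundle.network
    for r in net.reactions.values():
        r.essential = bool(set(r.genes) & essential)
    for mid, m in net.metabolites.items():
        genes: set[str] = set()
        for r in net.reactions.values():
            if mid in r.substrates or mid in r.products:
                genes.update(r.genes)
        m.essential = bool(genes & essential)


@dataclass
class EssentialityComparison:
    group_means: dict[str, float]
    t: float
    p: float
    n_essential: int
    n_nonessential: int


def compare_by_essentiality(network) -> dict[str, EssentialityComparison | None]:
    """Welch two-sample comparison of inhibition degree by essentiality.

    Returns the metabolite comparison (inhibition degree of essential vs
    non-essential metabolites) and the enzyme comparison (inhibited degree of
    essential vs non-essential enzymes).  A degenerate split (empty group or
    zero variance in both groups) yields None for that comparison.
    """
    def welch(ess: list[float], non: list[float]) -> EssentialityComparison | None:
        if len(ess) < 2 or len(non) < 2:
            return None
        if np.std(ess) == 0 and np.std(non) == 0:
            return None
        t, p = stats.ttest_ind(ess, non, equal_var=False)
        return EssentialityComparison(
            group_means={"essential": float(np.mean(ess)), "nonessential": float(np.mean(non))},
            t=float(t), p=float(p), n_essential=len(ess), n_nonessential=len(non))

    met_ess, met_non, enz_ess, enz_non = [], [], [], []
    for mid, m in network.metabolites.items():
        (met_ess if m.essential else met_non).append(network.metabolite_degree(mid))
    for ec, r in network.reactions.items():
        (enz_ess if r.essential else enz_non).append(network.reaction_degree(ec))
    return {"metabolites": welch(met_ess, met_non), "enzymes": welch(enz_ess, enz_non)}


# ---------------------------------------------------------------------------
# Gold-standard mechanism tally
# ---------------------------------------------------------------------------


def mechanism_tally(gold_table: pd.DataFrame | str) -> MechanismTally:
    """Counts and fractions of mechanisms over a gold-standard table.

    One row per single-experiment mechanism determination, with a
    ``mechanism`` column; rows with labels outside the closed vocabulary
    (competitive/noncompetitive/uncompetitive) are dropped and counted.
    """
    if not isinstance(gold_table, pd.DataFrame):
        gold_table = pd.read_csv(gold_table, sep="\t", dtype=str, keep_default_na=False)
    if len(gold_table) == 0:
        raise ValueError("empty gold-standard table")
    vocab = sorted(MECHANISMS - {"unknown"})
    labels = gold_table["mechanism"].str.strip().str.lower()
    kept = labels[labels.isin(vocab)]
    dropped = int(len(labels) - len(kept))
    counts = {m: int((kept == m).sum()) for m in vocab}
    n = len(kept)
    if n == 0:
        raise ValueError("no rows with a recognized mechanism label")
    fractions = {m: counts[m] / n for m in vocab}
    return MechanismTally(counts=counts, fractions=fractions, n=n, dropped=dropped)
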