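"""Subcellular compartment assignment and compartment-level inhibition analyses.

Co-localization is modelled as set intersection: an inhibitory interaction
can take place iff metabolite and enzyme share at least one compartment.
The module builds the compartment-compartment inhibition count matrix (with
compartment-specific inhibitors on the diagonal), derives the significant
compartment-pair network (hypergeometric + permutation FDR), accounts for
co-localization loss per compartment, and simulates the effect of a random
compartmentalization in which each node joins n compartments with n drawn
from a floored Pareto(shape a, scale b) truncated at the compartment count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrich import hypergeom_upper_tail

#: default 7-compartment vocabulary of the human reconstruction
DEFAULT_COMPARTMENTS = ("cytoplasm", "Golgi", "lysosome", "mitochondria",
                        "nucleus", "ER", "peroxisome")


@dataclass
class CompartmentMatrix:
    labels: list[str]
    matrix: np.ndarray  # counts, matrix[i][j] = interactions from compartment i metabolites onto compartment j enzymes
    include_multi: bool = True


@dataclass
class RandomCompartmentConfig:
    rc: int = 8              # number of random compartments (2..50 in the sweep)
    repeats: int = 50
    a: float = 0.5           # Pareto shape
    b: float = 1.0           # Pareto scale
    seed: int | None = None

    def __post_init__(self):
        if self.rc < 1:
            raise ValueError("rc must be >= 1")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Pareto shape and scale must be positive")


@dataclass
class CompartmentReport:
    per_compartment: pd.DataFrame  # inhibitors, interactions, pct_inhibitors_losing_colocalization, pct_interactions_removed
    surviving_interactions: int
    total_interactions: int


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------


def assign_compartments(bundle, pathway_locations: str | pd.DataFrame) -> None:
    """Assign compartments from pathway localizations (in place).

    ``pathway_locations`` maps pathway -> compartment (TSV with columns
    pathway, compartment; a pathway may appear on several rows).  A reaction
    localizes to the union of its pathways' compartments; a metabolite to the
    union over the reactions it participates in.  Reactions whose pathways
    all lack a location are flagged unlocalized and excluded from the
    compartment analyses.
    """
    if not isinstance(pathway_locations, pd.DataFrame):
        pathway_locations = pd.read_csv(pathway_locations, sep="\t", dtype=str,
                                        keep_default_na=False)
    loc: dict[str, set[str]] = {}
    for _, row in pathway_locations.iterrows():
        loc.setdefault(row["pathway"], set()).add(row["compartment"])

    net = bundle.network
    for r in net.reactions.values():
        comps: set[str] = set()
        for pw in r.pathways:
            comps |= loc.get(pw, set())
        r.compartments = comps
        r.unlocalized = not comps
    for mid, m in net.metabolites.items():
        comps = set()
        for r in net.reactions.values():
            if mid in r.substrates or mid in r.products:
                comps |= r.compartments
        m.compartments = comps


# ---------------------------------------------------------------------------
# Compartment-compartment matrix and significance network
# ---------------------------------------------------------------------------


def _localized_edges(network):
    for e in network.edges:
        met = network.metabolites[e.metabolite_id]
        rxn = network.reactions[e.ec_number]
        if met.compartments and rxn.compartments and not rxn.unlocalized:
            yield e, met, rxn


def compartment_matrix(network, labels: list[str] | None = None,
                       include_multi: bool = True) -> CompartmentMatrix:
    """Count matrix of metabolites (rows) inhibiting enzymes (columns).

    Off-diagonal M[i][j] counts interactions whose metabolite localizes to i
    and enzyme to j; the diagonal M[i][i] is restricted to compartment-
    specific inhibitors (metabolites localized to exactly one compartment).
    With ``include_multi=False`` multi-localized metabolites are excluded
    from the matrix entirely.
    """
    if labels is None:
        labels = sorted({c for m in network.metabolites.values() for c in m.compartments} |
                        {c for r in network.reactions.values() for c in r.compartments})
    idx = {c: i for i, c in enumerate(labels)}
    M = np.zeros((len(labels), len(labels)), dtype=int)
    for e, met, rxn in _localized_edges(network):
        if not include_multi and len(met.compartments) > 1:
            continue
        for cm in met.compartments:
            for ce in rxn.compartments:
                if cm not in idx or ce not in idx:
                    continue
                if cm == ce and len(met.compartments) > 1:
                    continue  # diagonal reserved for compartment-specific inhibitors
                M[idx[cm], idx[ce]] += 1
    return CompartmentMatrix(labels=list(labels), matrix=M, include_multi=include_multi)


@dataclass
class CompartmentPair:
    from_compartment: str
    to_compartment: str
    k: int
    p: float
    fdr: float | None = None
    skipped: bool = False


def compartment_network(network, n_perm: int = 100, seed: int | None = None,
                        labels: list[str] | None = None,
                        include_multi: bool = True,
                        alpha: float = 0.05) -> list[CompartmentPair]:
    """Significant compartment->compartment inhibition pairs.

    Each cell of the compartment matrix is tested with the hypergeometric
    upper tail against its margins (k = M[i][j], K = row i total, n = column
    j total, N = grand total).  The permutation FDR reassigns metabolites to
    compartments at random with per-compartment membership counts preserved,
    rebuilds the matrix, and counts permutations whose cell p ties or beats
    the observed one (FDR = counter / n_perm).  Pairs with a degenerate
    margin are skipped (flagged).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    cm = compartment_matrix(network, labels=labels, include_multi=include_multi)
    labels = cm.labels

    def cell_pvalues(M: np.ndarray) -> np.ndarray:
        N = int(M.sum())
        P = np.ones_like(M, dtype=float)
        for i in range(len(labels)):
            for j in range(len(labels)):
                K, n = int(M[i].sum()), int(M[:, j].sum())
                if N == 0 or K == 0 or n == 0:
                    P[i, j] = np.nan
                else:
                    P[i, j] = hypergeom_upper_tail(min(int(M[i, j]), min(K, n)), K, n, N)
        return P

    obs_p = cell_pvalues(cm.matrix)

    # permutation: shuffle the metabolite -> compartment-set assignment among
    # metabolites (membership multiset preserved), keep enzymes fixed
    rng = np.random.default_rng(seed)
    mids = sorted(m for m, met in network.metabolites.items() if met.compartments)
    comp_sets = [frozenset(network.metabolites[m].compartments) for m in mids]
    counter = np.zeros_like(obs_p)
    originals = {m: network.metabolites[m].compartments for m in mids}
    try:
        for _ in range(n_perm):
            perm = rng.permutation(len(mids))
            for pos, m in enumerate(mids):
                network.metabolites[m].compartments = set(comp_sets[perm[pos]])
            perm_p = cell_pvalues(compartment_matrix(network, labels=labels,
                                                     include_multi=include_multi).matrix)
            with np.errstate(invalid="ignore"):
                counter += (perm_p <= obs_p).astype(float)
    finally:
        for m in mids:
            network.metabolites[m].compartments = originals[m]

    out = []
    for i, ci in enumerate(labels):
        for j, cj in enumerate(labels):
            if np.isnan(obs_p[i, j]):
                out.append(CompartmentPair(ci, cj, int(cm.matrix[i, j]), p=1.0, skipped=True))
            else:
                out.append(CompartmentPair(ci, cj, int(cm.matrix[i, j]),
                                           p=float(obs_p[i, j]),
                                           fdr=float(counter[i, j] / n_perm)))
    return out


# ---------------------------------------------------------------------------
# Co-localization loss
# ---------------------------------------------------------------------------


def colocalization_loss(network) -> CompartmentReport:
    """Per-compartment co-localization accounting.

    For each compartment c: the inhibitors localized in c, the interactions
    targeting enzymes of c, the percentage of c's inhibitors that share no
    compartment with any enzyme they inhibit, and the percentage of c's
    interactions removed because metabolite and enzyme share no compartment.
    """
    labels = sorted({c for m in network.metabolites.values() for c in m.compartments} |
                    {c for r in network.reactions.values() for c in r.compartments})
    edges = list(_localized_edges(network))
    surviving = sum(1 for e, met, rxn in edges if met.compartments & rxn.compartments)
    total = len(edges)

    inhibitor_targets: dict[str, list] = {}
    for e, met, rxn in edges:
        inhibitor_targets.setdefault(e.metabolite_id, []).append(rxn)

    rows = []
    for c in labels:
        inhibitors_c = [m for m in inhibitor_targets
                        if c in network.metabolites[m].compartments]
        lost = sum(1 for m in inhibitors_c
                   if not any(network.metabolites[m].compartments & r.compartments
                              for r in inhibitor_targets[m]))
        inter_c = [(e, met, rxn) for e, met, rxn in edges if c in rxn.compartments]
        removed = sum(1 for e, met, rxn in inter_c
                      if not met.compartments & rxn.compartments)
        rows.append({
            "compartment": c,
            "inhibitors": len(inhibitors_c),
            "interactions": len(inter_c),
            "pct_inhibitors_losing_colocalization":
                100.0 * lost / len(inhibitors_c) if inhibitors_c else 0.0,
            "pct_interactions_removed":
                100.0 * removed / len(inter_c) if inter_c else 0.0,
        })
    return CompartmentReport(per_compartment=pd.DataFrame(rows),
                             surviving_interactions=surviving,
                             total_interactions=total)


# ---------------------------------------------------------------------------
# Random-compartmentalization simulation
# ---------------------------------------------------------------------------


def pareto_floor_pmf(k: int, a: float = 0.5, b: float = 1.0) -> float:
    """P(floor(X) = k) for X ~ Pareto(shape a, scale b), untruncated.

    From the Pareto CDF 1 - (b/x)^a: P(floor = k) = (b/k)^a - (b/(k+1))^a
    for integer k >= b.  With a = 0.5, b = 1 this gives
    P(1) = 1 - 2^-0.5 ~= 0.293.
    """
    if k < b:
        return 0.0
    return (b / k) ** a - (b / (k + 1)) ** a


def _draw_membership(n_nodes: int, rc: int, a: float, b: float, rng) -> list[set[int]]:
    # floor-Pareto membership count truncated to [1, rc] by inverse CDF:
    # P(floor(X)=k) ∝ (b/k)^a - (b/(k+1))^a restricted to k <= rc
    u = rng.random(n_nodes)
    z = 1.0 - (b / (rc + 1)) ** a  # mass of the truncated support
    n = np.ceil((1.0 - u * z) ** (-1.0 / a) * b).astype(int) - 1
    n = np.clip(n, 1, rc)
    return [set(rng.choice(rc, size=int(ni), replace=False)) for ni in n]


def simulate_random_compartmentalization(network, config: RandomCompartmentConfig) -> pd.DataFrame:
    """Random-compartmentalization simulation at a fixed compartment count.

    Per repeat, every metabolite and enzyme is placed into n distinct
    uniformly chosen compartments out of ``config.rc``, with n drawn from a
    floored Pareto(a, b) truncated to [1, rc]; an interaction survives iff
    its endpoints share a compartment.  Returns a row per repeat with
    surviving and removed counts (surviving + removed = total, every repeat).
    """
    rng = np.random.default_rng(config.seed)
    edges = [(e.metabolite_id, e.ec_number) for e in network.edges]
    mids = sorted({m for m, _ in edges})
    ecs = sorted({e for _, e in edges})
    midx = {m: i for i, m in enumerate(mids)}
    eidx = {e: i for i, e in enumerate(ecs)}
    rows = []
    for rep in range(config.repeats):
        met_comp = _draw_membership(len(mids), config.rc, config.a, config.b, rng)
        enz_comp = _draw_membership(len(ecs), config.rc, config.a, config.b, rng)
        surviving = sum(1 for m, e in edges if met_comp[midx[m]] & enz_comp[eidx[e]])
        rows.append({"rc": config.rc, "repeat": rep,
                     "surviving": surviving, "removed": len(edges) - surviving})
    return pd.DataFrame(rows)


def compartmentalization_sweep(network, rc_values=(2, 4, 8, 16, 32), repeats: int = 50,
                               a: float = 0.5, b: float = 1.0,
                               seed: int | None = None) -> pd.DataFrame:
    """Run the simulation across a range of compartment counts."""
    rng = np.random.default_rng(seed)
    frames = []
    for rc in rc_values:
        cfg = RandomCompartmentConfig(rc=int(rc), repeats=repeats, a=a, b=b,
                                      seed=int(rng.integers(2 ** 31)))
        frames.append(simulate_random_compartmentalization(network, cfg))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Mechanism-dependent co-localization
# ---------------------------------------------------------------------------


@dataclass
class ColocalizationRatio:
    mechanism_group: str
    colocalized: int
    not_colocalized: int

    @property
    def ratio(self) -> float:
        if self.not_colocalized == 0:
            return float("inf")
        return self.colocalized / self.not_colocalized


def mechanism_colocalization_ratio(network, gold_table: pd.DataFrame) -> dict[str, ColocalizationRatio]:
    """Same-compartment vs different-compartment ratio per mechanism group.

    The gold table (metabolite_id, ec, mechanism) supplies mechanism labels;
    pairs are grouped as competitive vs allosteric (noncompetitive +
    uncompetitive).  A pair is co-localized when metabolite and enzyme share
    at least one compartment.  A zero denominator reports an infinite ratio
    (counts retained).
    """
    groups = {"competitive": ["competitive"],
              "allosteric": ["noncompetitive", "uncompetitive"]}
    out = {}
    for gname, mechs in groups.items():
        co, not_co = 0, 0
        for _, row in gold_table.iterrows():
            if row["mechanism"].strip().lower() not in mechs:
                continue
            met = network.metabolites.get(row["metabolite_id"])
            rxn = network.reactions.get(row["ec"])
            if met is None or rxn is None or not met.compartments or not rxn.compartments:
                continue
            if met.compartments & rxn.compartments:
                co += 1
            else:
                not_co += 1
        out[gname] = ColocalizationRatio(mechanism_group=gname, colocalized=co,
                                         not_colocalized=not_co)
    return out
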