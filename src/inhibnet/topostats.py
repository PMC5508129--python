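"""Degree-distribution analysis and topology statistics of the inhibition network.

Implements discrete heavy-tail fitting: the degree sequence is fit to a
discrete power law p(x) = x^-gamma / zeta(gamma, xmin) by maximum likelihood,
with the lower cut-off xmin selected to minimize the Kolmogorov-Smirnov
distance between the empirical and fitted tail CDFs.  Candidate cut-offs
whose tail would retain fewer than ``min_tail`` observations (default 50)
are excluded, following the standard reliability guidance for tail fits;
ties break toward the smaller xmin.  Competing tail models (log-normal,
Poisson, exponential, all discretized and fit on the same tail) are compared
with a normalized log-likelihood-ratio (Vuong) test.

The random-graph null is the uniform G(n, m) model with the node and edge
counts of the observed network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln, zeta

TAIL_MODELS = ("power_law", "lognormal", "poisson", "exponential")

#: smallest tail considered reliable for xmin selection
MIN_TAIL = 50


@dataclass
class DegreeDistribution:
    node_class: str  # "metabolite" | "enzyme" | "all"
    counts: list[tuple[int, int]]  # sorted (degree, frequency)

    @property
    def degrees(self) -> np.ndarray:
        """Expanded degree sequence."""
        return np.repeat([d for d, _ in self.counts], [f for _, f in self.counts])

    @property
    def n_nodes(self) -> int:
        return sum(f for _, f in self.counts)


@dataclass
class PowerLawFit:
    gamma: float
    xmin: int
    loglik: float
    n_tail: int
    ks: float


@dataclass
class DistComparison:
    model_a: str
    model_b: str
    statistic: float  # positive favours model_a, negative model_b
    p: float


def degree_distribution(network, node_class: str = "all") -> DegreeDistribution:
    """Exact degree tally over the bipartite inhibition graph."""
    if node_class not in ("all", "metabolite", "enzyme"):
        raise ValueError(f"unknown node class {node_class!r}")
    degs = []
    if node_class in ("all", "metabolite"):
        degs += [network.metabolite_degree(m) for m in network.metabolites]
    if node_class in ("all", "enzyme"):
        degs += [network.reaction_degree(e) for e in network.reactions]
    vals, freqs = np.unique(np.asarray(degs, dtype=int), return_counts=True)
    return DegreeDistribution(node_class=node_class,
                              counts=[(int(v), int(f)) for v, f in zip(vals, freqs)])


# ---------------------------------------------------------------------------
# Discrete power law
# ---------------------------------------------------------------------------


def _powerlaw_mle(x: np.ndarray, xmin: int) -> tuple[float, float]:
    """MLE exponent and log-likelihood for the zeta tail at fixed xmin."""
    tail = x[x >= xmin]
    n = len(tail)
    slx = float(np.sum(np.log(tail)))

    def nll(g: float) -> float:
        return n * np.log(zeta(g, xmin)) + g * slx

    res = optimize.minimize_scalar(nll, bounds=(1.0001, 40.0), method="bounded")
    return float(res.x), -float(res.fun)


def _powerlaw_ks(x: np.ndarray, xmin: int, gamma: float) -> float:
    tail = np.sort(x[x >= xmin])
    xs = np.arange(xmin, tail.max() + 1)
    cdf = np.cumsum(xs ** (-gamma) / zeta(gamma, xmin))
    ecdf = np.searchsorted(tail, xs, side="right") / len(tail)
    return float(np.max(np.abs(ecdf - cdf)))


def fit_discrete_powerlaw(dd: DegreeDistribution | np.ndarray,
                          min_tail: int = MIN_TAIL) -> PowerLawFit:
    """Discrete power-law fit with KS-selected xmin.

    Degrees of zero are excluded (the discrete power law is undefined at 0).
    Raises on a constant degree sequence.  If no candidate xmin leaves
    ``min_tail`` observations the floor falls back to 2, so small fixtures
    remain fittable.
    """
    x = dd.degrees if isinstance(dd, DegreeDistribution) else np.asarray(dd, dtype=int)
    x = x[x > 0]
    uniq = np.unique(x)
    if len(uniq) < 2:
        raise ValueError("all degrees equal: power-law exponent undefined")

    floor = min_tail if np.sum(x >= uniq[0]) >= min_tail else 2
    best: PowerLawFit | None = None
    for xmin in uniq:
        n_tail = int(np.sum(x >= xmin))
        if n_tail < floor or len(np.unique(x[x >= xmin])) < 2:
            continue
        gamma, ll = _powerlaw_mle(x, int(xmin))
        ks = _powerlaw_ks(x, int(xmin), gamma)
        if best is None or ks < best.ks - 1e-12:  # ties keep the smaller xmin
            best = PowerLawFit(gamma=gamma, xmin=int(xmin), loglik=ll,
                               n_tail=n_tail, ks=ks)
    if best is None:
        raise ValueError("no admissible xmin (tail too short)")
    return best


def sample_discrete_powerlaw(gamma: float, n: int, seed: int | None = None,
                             xmin: int = 1, xmax: int = 10 ** 6) -> np.ndarray:
    """Inverse-CDF sampler for the zeta distribution (support truncated at xmax)."""
    xs = np.arange(xmin, xmax + 1, dtype=float)
    pmf = xs ** (-gamma)
    cdf = np.cumsum(pmf / pmf.sum())
    rng = np.random.default_rng(seed)
    return (xmin + np.searchsorted(cdf, rng.random(n))).astype(int)


# ---------------------------------------------------------------------------
# Alternative tail models and the Vuong comparison
# ---------------------------------------------------------------------------


def _tail_loglik_pointwise(model: str, x: np.ndarray, xmin: int) -> np.ndarray:
    """Per-observation log-likelihood of the MLE fit of ``model`` on the tail."""
    tail = x[x >= xmin].astype(float)

    if model == "power_law":
        gamma, _ = _powerlaw_mle(x, xmin)
        return -gamma * np.log(tail) - np.log(zeta(gamma, xmin))

    if model == "exponential":
        # discrete (geometric-type) tail: p(x) ∝ exp(-lam*x), x >= xmin
        mean_excess = tail.mean() - xmin
        if mean_excess <= 0:
            lam = 50.0
        else:
            lam = float(np.log(1.0 + 1.0 / mean_excess))
        logz = -lam * xmin - np.log1p(-np.exp(-lam))
        return -lam * tail - logz

    if model == "poisson":
        def nll(mu: float) -> float:
            logpmf = tail * np.log(mu) - mu - gammaln(tail + 1)
            k = np.arange(0, xmin)
            logtail = np.log1p(-np.sum(np.exp(k * np.log(mu) - mu - gammaln(k + 1)))) \
                if xmin > 1 else 0.0
            return float(-(np.sum(logpmf) - len(tail) * logtail))
        res = optimize.minimize_scalar(nll, bounds=(1e-6, float(tail.max()) + 10),
                                       method="bounded")
        mu = float(res.x)
        k = np.arange(0, xmin)
        logtail = np.log1p(-np.sum(np.exp(k * np.log(mu) - mu - gammaln(k + 1)))) \
            if xmin > 1 else 0.0
        return tail * np.log(mu) - mu - gammaln(tail + 1) - logtail

    if model == "lognormal":
        # discretized by CDF differences, conditioned on x >= xmin
        logt = np.log(tail)

        def nll(theta) -> float:
            mu, sig = theta
            if sig <= 0:
                return np.inf
            upper = stats.norm.logcdf(-(np.log(xmin - 0.5) - mu) / sig) if xmin > 1 \
                else 0.0
            hi = stats.norm.cdf((np.log(tail + 0.5) - mu) / sig)
            lo = stats.norm.cdf((np.log(np.maximum(tail - 0.5, 1e-12)) - mu) / sig)
            p = np.maximum(hi - lo, 1e-300)
            return float(-(np.sum(np.log(p)) - len(tail) * upper))

        res = optimize.minimize(nll, x0=np.array([logt.mean(), max(logt.std(), 0.1)]),
                                method="Nelder-Mead")
        mu, sig = res.x
        upper = stats.norm.logcdf(-(np.log(xmin - 0.5) - mu) / sig) if xmin > 1 else 0.0
        hi = stats.norm.cdf((np.log(tail + 0.5) - mu) / sig)
        lo = stats.norm.cdf((np.log(np.maximum(tail - 0.5, 1e-12)) - mu) / sig)
        return np.log(np.maximum(hi - lo, 1e-300)) - upper

    raise ValueError(f"unknown tail model {model!r}")


def compare_distributions(dd: DegreeDistribution | np.ndarray, model_a: str,
                          model_b: str, xmin: int | None = None) -> DistComparison:
    """Vuong-style normalized log-likelihood-ratio test between two tail models.

    Both models are fit by MLE on the same tail (x >= xmin; by default the
    KS-selected power-law xmin).  Positive statistic favours ``model_a``;
    the two-sided p comes from the standard normal limit.  Comparing a model
    with itself returns statistic 0, p = 1.
    """
    for m in (model_a, model_b):
        if m not in TAIL_MODELS:
            raise ValueError(f"unknown tail model {m!r}")
    x = dd.degrees if isinstance(dd, DegreeDistribution) else np.asarray(dd, dtype=int)
    x = x[x > 0]
    if xmin is None:
        xmin = fit_discrete_powerlaw(x).xmin
    if np.sum(x >= xmin) < 2:
        raise ValueError("tail shorter than 2 observations")
    if model_a == model_b:
        return DistComparison(model_a=model_a, model_b=model_b, statistic=0.0, p=1.0)

    la = _tail_loglik_pointwise(model_a, x, xmin)
    lb = _tail_loglik_pointwise(model_b, x, xmin)
    d = la - lb
    n = len(d)
    sd = float(d.std(ddof=0))
    if sd == 0:
        return DistComparison(model_a=model_a, model_b=model_b, statistic=0.0, p=1.0)
    statistic = float(d.sum() / (sd * np.sqrt(n)))
    p = float(2 * stats.norm.sf(abs(statistic)))
    return DistComparison(model_a=model_a, model_b=model_b, statistic=statistic, p=p)


# ---------------------------------------------------------------------------
# Random-graph null
# ---------------------------------------------------------------------------


def erdos_renyi_null(n_nodes: int, n_edges: int, seed: int | None = None) -> nx.Graph:
    """Uniform simple graph with exactly ``n_edges`` edges (G(n, m))."""
    if n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError("edge count exceeds the simple-graph maximum")
    return nx.gnm_random_graph(n_nodes, n_edges, seed=seed)


def random_network_gamma(n_nodes: int = 1303, n_edges: int = 5989,
                         replicates: int = 20, seed: int | None = None,
                         min_tail: int = MIN_TAIL) -> tuple[float, list[float]]:
    """Replicate-mean power-law exponent of same-size G(n, m) random graphs."""
    rng = np.random.default_rng(seed)
    gammas = []
    for _ in range(replicates):
        g = erdos_renyi_null(n_nodes, n_edges, seed=int(rng.integers(2 ** 31)))
        degs = np.array([d for _, d in g.degree()])
        gammas.append(fit_discrete_powerlaw(degs, min_tail=min_tail).gamma)
    return float(np.mean(gammas)), gammas


# ---------------------------------------------------------------------------
# Paths and correlations
# ---------------------------------------------------------------------------


def shortest_path_profile(network) -> dict[str, dict[str, float]]:
    """Unweighted BFS distances from every metabolite to every enzyme node.

    Distances are measured on the bipartite inhibition graph; unreachable
    pairs are infinite.
    """
    g = network.bipartite_graph()
    out: dict[str, dict[str, float]] = {}
    for mid in network.metabolites:
        dists = nx.single_source_shortest_path_length(g, mid) if mid in g else {}
        out[mid] = {ec: float(dists.get("EC:" + ec, np.inf)) for ec in network.reactions}
    return out


def metabolic_distance_profile(network) -> dict[str, dict[str, float]]:
    """BFS distances on the *metabolic* bipartite graph (substrate/product links).

    A metabolite is adjacent to every reaction it participates in, so the
    substrates of an enzyme sit at distance 1 from it.
    """
    g = nx.Graph()
    for mid in network.metabolites:
        g.add_node(mid)
    for ec, r in network.reactions.items():
        g.add_node("EC:" + ec)
        for m in set(r.substrates) | set(r.products):
            g.add_edge(m, "EC:" + ec)
    out: dict[str, dict[str, float]] = {}
    for mid in network.metabolites:
        dists = nx.single_source_shortest_path_length(g, mid) if mid in g else {}
        out[mid] = {ec: float(dists.get("EC:" + ec, np.inf)) for ec in network.reactions}
    return out


def inhibition_by_distance(network) -> dict[float, tuple[int, int, float]]:
    """Fraction of (metabolite, enzyme) pairs at each metabolic distance that
    are annotated inhibitory interactions.

    Returns {distance: (n_inhibiting, n_pairs, fraction)}.  Distances on the
    metabolic graph are odd for metabolite-enzyme pairs (1 = own substrate/
    product neighbourhood, 3 = one conversion away, ...).
    """
    prof = metabolic_distance_profile(network)
    edges = {(e.metabolite_id, e.ec_number) for e in network.edges}
    tally: dict[float, list[int]] = {}
    for mid, row in prof.items():
        for ec, d in row.items():
            t = tally.setdefault(d, [0, 0])
            t[1] += 1
            if (mid, ec) in edges:
                t[0] += 1
    return {d: (k, n, k / n if n else float("nan")) for d, (k, n) in sorted(tally.items())}


def inhibition_reaction_correlation(network) -> tuple[float, float]:
    """Pearson correlation between per-metabolite inhibition degree and the
    number of metabolic reactions the metabolite participates in."""
    mids = sorted(network.metabolites)
    if len(mids) < 3:
        raise ValueError("need at least 3 metabolites")
    inh = np.array([network.metabolite_degree(m) for m in mids], dtype=float)
    rxn = np.array([len(network.reactions_of_metabolite(m)) for m in mids], dtype=float)
    if inh.std() == 0 or rxn.std() == 0:
        raise ValueError("zero variance in degrees: correlation undefined")
    r, p = stats.pearsonr(inh, rxn)
    return float(r), float(p)
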