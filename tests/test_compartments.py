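"""Compartment assignment, the compartment matrix, co-localization and the
random-compartmentalization simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inhibnet import compartments, netcore, synthgen

from conftest import build_network


def localized_toy():
    mets = {"a": "Lipids", "b": "Lipids", "h": "Lipids"}
    rxns = {
        "1.1.1.1": {"substrates": ["a"], "products": ["b"], "pathways": ["P_cyt"]},
        "2.2.2.2": {"substrates": ["b"], "products": ["h"], "pathways": ["P_mito"]},
        "3.3.3.3": {"substrates": ["h"], "pathways": ["P_unknown"]},
    }
    net = build_network(mets, rxns, [("a", "1.1.1.1", "unknown"),
                                     ("a", "2.2.2.2", "unknown")])
    bundle = netcore.ModelBundle(network=net)
    locations = pd.DataFrame([
        {"pathway": "P_cyt", "compartment": "cytoplasm"},
        {"pathway": "P_mito", "compartment": "mitochondria"},
    ])
    return bundle, locations


class TestAssignCompartments:
    def test_single_pathway_single_compartment(self):
        bundle, locations = localized_toy()
        compartments.assign_compartments(bundle, locations)
        assert bundle.network.reactions["1.1.1.1"].compartments == {"cytoplasm"}

    def test_metabolite_union_over_reactions(self):
        bundle, locations = localized_toy()
        compartments.assign_compartments(bundle, locations)
        assert bundle.network.metabolites["b"].compartments == {"cytoplasm",
                                                                "mitochondria"}

    def test_unlocated_pathway_flags_reaction(self):
        bundle, locations = localized_toy()
        compartments.assign_compartments(bundle, locations)
        assert bundle.network.reactions["3.3.3.3"].unlocalized

    def test_hubs_span_compartments(self, synth_default):
        cfg, metabolome, bundle, _ = synth_default
        net = bundle.network
        spans = [len(net.metabolites[h].compartments) for h in metabolome.hub_ids]
        assert max(spans) == cfg.n_compartments


class TestCompartmentMatrix:
    def test_single_compartment_network_is_diagonal(self):
        bundle, _ = localized_toy()
        locations = pd.DataFrame([{"pathway": p, "compartment": "cytoplasm"}
                                  for p in ("P_cyt", "P_mito", "P_unknown")])
        compartments.assign_compartments(bundle, locations)
        cm = compartments.compartment_matrix(bundle.network)
        assert cm.labels == ["cytoplasm"]
        assert cm.matrix[0, 0] == 2

    def test_multi_localized_metabolite_excluded_from_diagonal(self):
        """A metabolite in {A, B} inhibiting an enzyme in B counts in M[A][B]
        but not in M[B][B]."""
        mets = {"x": "Lipids"}
        rxns = {"1.1.1.1": {"substrates": ["x"], "pathways": ["pA", "pB"]},
                "2.2.2.2": {"substrates": ["x"], "pathways": ["pB"]}}
        net = build_network(mets, rxns, [("x", "2.2.2.2", "unknown")])
        bundle = netcore.ModelBundle(network=net)
        compartments.assign_compartments(bundle, pd.DataFrame([
            {"pathway": "pA", "compartment": "A"},
            {"pathway": "pB", "compartment": "B"}]))
        cm = compartments.compartment_matrix(net)
        a, b = cm.labels.index("A"), cm.labels.index("B")
        assert cm.matrix[a, b] == 1
        assert cm.matrix[b, b] == 0

    def test_matrix_total_counts_colocalizable_pairs(self):
        bundle, locations = localized_toy()
        compartments.assign_compartments(bundle, locations)
        cm = compartments.compartment_matrix(bundle.network)
        # edge a->1.1.1.1: a in {cyt, mito}, enzyme in {cyt}: a is
        # multi-localized so the (cyt, cyt) diagonal is excluded; (mito, cyt)
        # counts.  edge a->2.2.2.2: enzyme in {mito}: (cyt, mito) and the
        # (mito, mito) diagonal again excluded -> 2 cells total.
        assert cm.matrix.sum() == 2


class TestCompartmentNetwork:
    def test_only_cytoplasm_self_inhibition_enriched(self, synth_default):
        """Planted condition: self-inhibition enriches in the cytoplasm and in
        no organelle (compartment-specific inhibitors, as in the analysis)."""
        _, _, bundle, _ = synth_default
        pairs = compartments.compartment_network(bundle.network, n_perm=50, seed=0,
                                                 include_multi=False)
        diag = {p.from_compartment: p for p in pairs
                if p.from_compartment == p.to_compartment}
        assert diag["cytoplasm"].p < 0.05
        assert diag["cytoplasm"].fdr <= 0.05
        for organelle in ("Golgi", "lysosome", "mitochondria"):
            assert diag[organelle].p >= 0.05

    def test_zero_permutations_raise(self, synth_default):
        _, _, bundle, _ = synth_default
        with pytest.raises(ValueError):
            compartments.compartment_network(bundle.network, n_perm=0)

    def test_uniform_placement_calibration(self):
        """~5% of compartment pairs significant under random placement."""
        rng = np.random.default_rng(42)
        n_sig = 0
        n_pairs = 0
        for _ in range(100):
            mets = {f"m{i}": "Lipids" for i in range(40)}
            rxns = {f"{(i % 6) + 1}.1.1.{i}": {"substrates": [f"m{i}"],
                                               "pathways": [f"pw{i}"]}
                    for i in range(40)}
            edges = [(f"m{int(rng.integers(40))}",
                      sorted(rxns)[int(rng.integers(40))], "unknown")
                     for _ in range(120)]
            net = build_network(mets, rxns, sorted(set(edges)))
            bundle = netcore.ModelBundle(network=net)
            comps = ["c1", "c2", "c3"]
            compartments.assign_compartments(bundle, pd.DataFrame(
                [{"pathway": f"pw{i}", "compartment": comps[int(rng.integers(3))]}
                 for i in range(40)]))
            cm = compartments.compartment_matrix(net)
            N = int(cm.matrix.sum())
            if N == 0:
                continue
            for i in range(len(cm.labels)):
                for j in range(len(cm.labels)):
                    K, n = int(cm.matrix[i].sum()), int(cm.matrix[:, j].sum())
                    if K and n:
                        n_pairs += 1
                        from inhibnet.enrich import hypergeom_upper_tail
                        n_sig += hypergeom_upper_tail(int(cm.matrix[i, j]),
                                                      K, n, N) < 0.05
        rate = n_sig / n_pairs
        assert rate < 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / n_pairs)


class TestColocalizationLoss:
    def test_fully_colocalized_toy_loses_nothing(self):
        bundle, _ = localized_toy()
        locations = pd.DataFrame([{"pathway": p, "compartment": "cytoplasm"}
                                  for p in ("P_cyt", "P_mito", "P_unknown")])
        compartments.assign_compartments(bundle, locations)
        rep = compartments.colocalization_loss(bundle.network)
        assert (rep.per_compartment["pct_inhibitors_losing_colocalization"] == 0).all()
        assert rep.surviving_interactions == rep.total_interactions

    def test_cytoplasm_only_inhibitor_of_organelle_enzyme_is_removed(self):
        mets = {"c": "Lipids"}
        rxns = {"1.1.1.1": {"substrates": ["c"], "pathways": ["pC"]},
                "2.2.2.2": {"pathways": ["pM"]}}
        net = build_network(mets, rxns, [("c", "2.2.2.2", "unknown")])
        bundle = netcore.ModelBundle(network=net)
        compartments.assign_compartments(bundle, pd.DataFrame([
            {"pathway": "pC", "compartment": "cytoplasm"},
            {"pathway": "pM", "compartment": "mitochondria"}]))
        rep = compartments.colocalization_loss(net)
        row = rep.per_compartment.set_index("compartment")
        assert row.loc["mitochondria", "pct_interactions_removed"] == 100.0
        assert rep.surviving_interactions == 0

    def test_organelles_lose_more_than_cytoplasm(self, synth_default):
        _, _, bundle, _ = synth_default
        rep = compartments.colocalization_loss(bundle.network)
        row = rep.per_compartment.set_index("compartment")
        cyt = row.loc["cytoplasm", "pct_inhibitors_losing_colocalization"]
        for organelle in ("Golgi", "lysosome", "mitochondria"):
            assert row.loc[organelle, "pct_inhibitors_losing_colocalization"] > cyt


class TestRandomCompartmentalization:
    def test_pareto_floor_closed_form(self):
        assert compartments.pareto_floor_pmf(1) == pytest.approx(1 - 2 ** -0.5)
        total = sum(compartments.pareto_floor_pmf(k) for k in range(1, 10 ** 6))
        assert total == pytest.approx(1.0, abs=1e-2)

    def test_sampler_matches_closed_form_tail(self):
        """Empirical floor(X) distribution vs the Pareto tail (chi^2)."""
        rng = np.random.default_rng(0)
        u = rng.random(10 ** 6)
        draws = np.floor(u ** (-1.0 / 0.5)).astype(int)
        observed = np.array([(draws == k).sum() for k in range(1, 11)])
        expected = np.array([compartments.pareto_floor_pmf(k) for k in range(1, 11)])
        # condition on the window 1..10 for a proper chi-square
        mask = draws <= 10
        chi = stats.chisquare(observed, expected / expected.sum() * mask.sum())
        assert chi.pvalue > 0.01

    def test_single_compartment_removes_nothing(self, synth_default):
        _, _, bundle, _ = synth_default
        cfg = compartments.RandomCompartmentConfig(rc=1, repeats=5, seed=0)
        out = compartments.simulate_random_compartmentalization(bundle.network, cfg)
        assert (out["removed"] == 0).all()

    def test_conservation_every_repeat(self, synth_default):
        _, _, bundle, _ = synth_default
        cfg = compartments.RandomCompartmentConfig(rc=8, repeats=10, seed=1)
        out = compartments.simulate_random_compartmentalization(bundle.network, cfg)
        total = len(bundle.network.edges)
        assert ((out["surviving"] + out["removed"]) == total).all()

    def test_invalid_rc_raises(self):
        with pytest.raises(ValueError):
            compartments.RandomCompartmentConfig(rc=0)

    def test_removal_increases_then_saturates_with_rc(self, synth_default):
        """More compartments remove more interactions, flattening beyond ~8."""
        _, _, bundle, _ = synth_default
        sweep = compartments.compartmentalization_sweep(
            bundle.network, rc_values=(2, 4, 8, 16, 32), repeats=50, seed=0)
        means = sweep.groupby("rc")["removed"].mean()
        assert means.is_monotonic_increasing
        gains = np.diff(means.values)  # per doubling of rc
        assert max(gains[2:]) < min(gains[:2])  # beyond 8 vs up to 8


class TestMechanismColocalizationRatio:
    def test_all_colocalized_reports_infinite(self):
        bundle, _ = localized_toy()
        locations = pd.DataFrame([{"pathway": p, "compartment": "cytoplasm"}
                                  for p in ("P_cyt", "P_mito", "P_unknown")])
        compartments.assign_compartments(bundle, locations)
        gold = pd.DataFrame([{"metabolite_id": "a", "ec": "1.1.1.1",
                              "mechanism": "competitive"}])
        out = compartments.mechanism_colocalization_ratio(bundle.network, gold)
        assert out["competitive"].ratio == float("inf")

    def test_small_ratio_arithmetic(self):
        mets = {f"m{i}": "Lipids" for i in range(6)}
        rxns = {f"1.1.1.{i}": {"pathways": ["pA" if i < 4 else "pB"]}
                for i in range(6)}
        net = build_network(mets, rxns, [])
        bundle = netcore.ModelBundle(network=net)
        compartments.assign_compartments(bundle, pd.DataFrame([
            {"pathway": "pA", "compartment": "A"},
            {"pathway": "pB", "compartment": "B"}]))
        for i, m in enumerate(mets):
            net.metabolites[m].compartments = {"A"}
        gold = pd.DataFrame([{"metabolite_id": f"m{i}", "ec": f"1.1.1.{i}",
                              "mechanism": "competitive"} for i in range(6)])
        out = compartments.mechanism_colocalization_ratio(net, gold)
        assert out["competitive"].colocalized == 4
        assert out["competitive"].not_colocalized == 2
        assert out["competitive"].ratio == pytest.approx(2.0)

    def test_competitive_more_colocalized_than_allosteric(self, synth_default):
        _, _, bundle, _ = synth_default
        gold = synthgen.gold_standard_table(bundle.network)
        out = compartments.mechanism_colocalization_ratio(bundle.network, gold)
        assert out["competitive"].ratio > out["allosteric"].ratio
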