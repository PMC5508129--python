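# inhibnet

Metabolic enzymes are inhibited not only by dedicated regulators but by
ordinary metabolites that happen to resemble their substrates. `inhibnet`
is an analysis pipeline for studying this phenomenon at genome scale: it
assembles a bipartite **metabolite → enzyme inhibition network** from
inhibitor-annotation snapshots mapped onto a metabolic reconstruction, and
asks why the network looks the way it does — structural similarity between
inhibitors and substrates, network topology, enzyme/metabolite essentiality,
subcellular compartmentalization, and the kinetic mechanism of individual
inhibitors.

It is written for systems biologists who want to rebuild this kind of
analysis on their own curated snapshots (BRENDA-style inhibitor tables plus
a Recon2-style reconstruction) or on fully synthetic data: a first-class
generator emits model tables, molecular structures, annotations,
essentiality labels, compartments and kinetics with the statistical
structure the analyses assume, so the entire pipeline is testable offline.

## The quantities at the core

* **Structural similarity.** Two molecules are compared through their
  maximum common connected substructure (MCS) under exact element and
  bond-order matching. With heavy-atom counts |A|, |B| and MCS size m:
  overlap coefficient `m / min(|A|, |B|)` and MCS Tanimoto
  `m / (|A| + |B| − m)`. An inhibitor is scored against an enzyme by its
  **best substrate match**, and that score is referenced against a
  pool-size-corrected resampling null (k random metabolites, 50 repeats).
* **Enrichment.** Inhibitor superclasses (8 merged HMDB groups) against the
  6 EC enzyme classes, pathway → pathway inhibition, and compartment →
  compartment inhibition are tested with the exact hypergeometric upper
  tail P(X ≥ k); the false-discovery rate is a label-shuffling permutation
  estimate, FDR = counter / n_perm.
* **Topology.** The degree distribution is fit to a discrete power law
  p(x) ∝ x^(−γ) by maximum likelihood with a Kolmogorov–Smirnov-selected
  lower cut-off, and contrasted with uniform G(n, m) random graphs of the
  same size; log-normal, Poisson and exponential tails are compared with a
  Vuong-style normalized likelihood-ratio test.
* **Compartmentalization.** Co-localization is set intersection over
  compartment memberships. A random-compartmentalization simulation places
  every node in n of rc hypothetical compartments, n drawn from a floored
  Pareto(a = 0.5, b = 1) truncated at rc, and counts surviving
  interactions.
* **Kinetics.** Initial-rate data (S, I, v) are fit to the competitive,
  noncompetitive and uncompetitive rate laws; the selected mechanism's
  Ki/Km ratio expresses inhibitory capacity.

## Worked example

The whole analysis is a sequence of numbered drivers over the library:

```
python analysis/01_generate_data.py      # synthetic study inputs
python analysis/02_build_network.py      # network assembly + row accounting
python analysis/03_structural_similarity.py
python analysis/04_topology.py
python analysis/05_enrichment.py
python analysis/06_compartments.py
python analysis/07_kinetics.py
```

`01` writes a model with 54 metabolites, 48 reactions and 452 inhibition
edges (planted causes: 252 hub, 148 similarity-driven, 52 background).
`03` then prints

```
MCS overlap coefficients of the L-LDH inhibitor triangle:
  oxaloacetate - pyruvate: overlap = 1.000 (MCS 6 atoms)
  malonate - oxaloacetate: overlap = 0.857 (MCS 6 atoms)
  malonate - pyruvate: overlap = 0.833 (MCS 5 atoms)

best substrate match over 452 edges: median 0.631 vs resampling null
median 0.417 (Welch p = 4.56e-29)
```

— pyruvate embeds entirely in oxaloacetate (overlap 1), which is why a
structural analogue can inhibit L-lactate dehydrogenase, and across the
network inhibitors resemble their targets' substrates far beyond chance.
`04` reports a heavy-tailed degree distribution (γ = 2.60 on this instance)
against a much steeper random-graph null; `05` finds each planted
inhibitor-class → enzyme-class channel significant with permutation FDR 0
and shows essential metabolites inhibit more enzymes (15.2 vs 4.4 edges,
Welch p = 0.016) while enzyme essentiality is irrelevant (p = 0.63); `06`
shows self-inhibition enriched only in the cytoplasm, organelles losing
33–50% of their inhibitors' co-localization, and the random-
compartmentalization sweep flattening beyond ~8 compartments; `07` recovers
each generating kinetic mechanism and prints the inhibitory capacities
Ki/Km = 7.7 (oxaloacetate-like, Km 0.300 mM, Ki 2.30 mM) and 90 (malonate-
like, Ki 27 mM).

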