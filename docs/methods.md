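# Methods

This note documents the models and conventions behind `inhibnet`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Network assembly (`netcore`)

The inhibition network is bipartite: `Metabolite` nodes and
`EnzymeReaction` nodes (one per EC number) joined by mechanism-annotated
edges, one per distinct (metabolite, EC) pair. Assembly is a two-step
mapping: `load_model` instantiates the reconstruction from TSV tables or
SBML Level 3 (species/reactions with the COBRA-style notes keys
`EC Number`, `GENE_ASSOCIATION`, `SUBSYSTEM`), and `map_inhibitors` resolves
annotation rows (EC, inhibitor name, mechanism, species) onto model
metabolites.

Conventions:

* **ID resolution order** is KEGG > HMDB > exact name/ID match. Rows that
  resolve to nothing, or reference an EC absent from the model, are dropped
  and counted; provenance keeps `mapped + dropped = total rows` as an
  invariant.
* **Mechanism conflicts.** If one (metabolite, EC) pair is reported with
  two different informative mechanisms, the edge mechanism becomes
  `unknown` and the conflicting labels are retained in provenance. Reliable
  mechanism labels are the province of the gold-standard table, which by
  construction holds single-experiment determinations.
* **Superclass merging.** Raw HMDB superclasses are mapped onto a closed
  8-group vocabulary: the three aromatic superclasses become "Aromatic
  Cyclic Compounds", eight enumerated small superclasses become "Others",
  six large superclasses are kept. Unlisted strings also fall into
  "Others" (it is already a catch-all), making the function total;
  metabolites absent from the superclass map stay "unclassified" and are
  excluded from none of the structural analyses.
* **Phosphorylation flag**: a structure is phosphorylated iff it contains a
  phosphorus atom bonded to at least three oxygens (phosphate/phosphonate
  motif).
* TSV dialect: UTF-8, tab-separated, header row, `.` for missing.

## Structural similarity (`chemsim`)

Molecules are hydrogen-suppressed heavy-atom graphs (rdkit handles SMILES/
SDF parsing and aromatic perception). The MCS is the **maximum common
connected induced substructure** under exact (element, formal charge)
matching and exact bond-order matching, aromatic bonds matching only
aromatic bonds. "Induced" means a bond between two matched atoms must be
present with the same order in both molecules or absent from both; this
definition makes the exhaustive test oracle (connected-subset enumeration
plus brute-force embedding) well defined, and it reproduces the canonical
desk values for the pyruvate/malonate/oxaloacetate triangle (overlap 1,
0.857, 0.833).

The search is McGregor-style branch and bound over atom-pair extensions
with an element-count bound, explored in sorted index order so the witness
mapping is deterministic. The primary resource cap is a **node-expansion
budget** (default 15,000 expansions) rather than wall-clock time: a
wall-clock cap would make same-seed runs machine-dependent. Exceeding the
budget (or the 60-heavy-atom molecule budget) returns the best mapping
found with `approximate=True`; on the generator's molecule set the budget
result is identical to a 400,000-expansion search. An optional `timeout_s`
adds a wall-clock cap for interactive use.

The fingerprint is a documented hashed-path scheme — all simple paths of
0–7 bonds over (element, charge) and bond-order labels, canonicalized to
the smaller read direction and CRC32-hashed onto 1024 bits — with bitwise
Tanimoto (defined as 1.0 for two empty vectors). It replaces proprietary
substructure-key schemes whose exact bits are not reproducible here, so all
fingerprint-based conclusions are tested as orderings and distribution
properties, never as exact values. An atom-pair similarity (multiset
Tanimoto over (element, element, topological distance) descriptors) is
provided as an ordering-compatible variant.

`best_substrate_similarity` takes the maximum similarity between an
inhibitor and the enzyme's substrates, excluding a substrate identical to
the inhibitor. The resampling null draws k metabolites (k = the substrate
list size) uniformly without replacement from the inhibitor pool, 50
repeats by default, and records the best match per repeat — the pool-size
correction that makes observed best matches comparable.

## Topology (`topostats`)

Degrees are tallied over the bipartite graph. The discrete power law
p(x) = x^(−γ) / ζ(γ, xmin) is fit by maximum likelihood (Hurwitz zeta via
scipy; γ searched on [1.0001, 40]); xmin is selected by minimizing the KS
distance between the empirical and fitted tail CDFs over observed degrees,
ties toward the smaller xmin, zeros excluded.

**Minimum tail size.** Candidate cut-offs whose tail would keep fewer than
50 observations are excluded (falling back to ≥ 2 when the whole sample is
small). Pure KS minimization on the degree sequences of G(1303, 5989)
random graphs routinely selects tails of 10–40 points whose MLE exponents
explode (replicate means of 15–17 with standard deviation above 6); the
50-point floor follows the standard reliability guidance for heavy-tail
fits and yields stable replicate means near 10–11 while leaving exponent
recovery on 10⁴-point synthetic samples (γ ∈ {2, 2.5, 3}) accurate to
within 5%.

Model comparison is a Vuong-style normalized log-likelihood-ratio test on
per-observation log-likelihood differences, both models fit by MLE on the
same tail; the alternatives are a CDF-differenced discrete log-normal, a
tail-truncated Poisson and a discrete exponential (geometric). The random
null is uniform G(n, m) with exactly the observed node and edge counts
(`networkx.gnm_random_graph`); the replicate-mean exponent convention is
used because a single fit of a single random graph has high variance.

Metabolic distance (for the neighbourhood analysis) is measured on the
substrate/product bipartite graph, so an enzyme's own substrates sit at
distance 1 and metabolite–enzyme distances are odd;
`inhibition_by_distance` reports the fraction of pairs at each distance
that are annotated inhibitions.

## Enrichment and essentiality (`enrich`)

The enrichment universe is **edge-level**: N is the number of inhibitory
interactions, K the interactions from the inhibitor group, n the
interactions onto the enzyme group, k their intersection, with the exact
upper tail P(X ≥ k). Pairs with an empty margin are reported with p = 1
and flagged. The permutation FDR reassigns inhibitors to classes with
class sizes preserved, 100 permutations by default, and counts
permutations whose p ties or beats the observed one (ties count against
the pair — the conservative reading of a one-sided counter).

Because the hypergeometric test is discrete, its attained type-I error
under label shuffling is at or below the nominal 5%; the calibration tests
therefore check that the null false-positive fraction lies below the upper
99% binomial bound of 0.05 without penalizing the conservatism.

Pathway-pair similarity excludes compounds shared between the two pathways
(currency metabolites) and non-inhibitors, then averages pairwise scores.
Pathway → pathway inhibition is the same hypergeometric machinery on
pathway margins at p < 0.01, excluding metabolites common to both
pathways. Essentiality propagates from genes: an enzyme is essential iff
any associated gene is essential, a metabolite iff any gene of any
reaction it participates in is; group comparisons are Welch (unequal
variance) two-sample t tests on inhibition degree.

## Compartments (`compartments`)

Reactions localize to the union of their pathways' compartments, and
metabolites to the union over their reactions; co-localization is
non-empty set intersection (no transport modelling). The compartment
matrix counts interactions from metabolites of compartment i onto enzymes
of compartment j; the diagonal is restricted to compartment-specific
inhibitors (metabolites localized to exactly one compartment), and a
switch excludes multi-localized metabolites globally — the variant used
for the self-inhibition analysis, where multi-compartment currency
metabolites would otherwise dominate every margin. Significance and
permutation FDR mirror the class enrichment, permuting the metabolite →
compartment-set assignment with membership counts preserved.

The random-compartmentalization simulation draws, for every node, a
membership count n from a floored Pareto with shape a = 0.5 and scale
b = 1 — P(floor = k) = (b/k)^a − (b/(k+1))^a, so P(1) = 1 − 2^(−1/2) ≈
0.293 — restricted to [1, rc], then places the node in n distinct uniform
compartments. **Truncation, not capping:** restricting the draw by
resampling mass above rc (implemented as inverse CDF on the truncated
support) makes the removal curve rise steeply up to ~8 compartments and
flatten beyond, the qualitative saturation the analysis is about; capping
floor(X) at rc instead piles 70%+ of the mass onto n = rc for small rc and
keeps removal growing strongly through rc = 50. Surviving + removed =
total interactions holds every repeat by construction.

## Kinetics (`kinetics`)

Single-substrate initial-rate laws with one inhibitor: competitive
v = Vmax·S/(Km(1+I/Ki)+S), noncompetitive v = Vmax·S/((Km+S)(1+I/Ki)),
uncompetitive v = Vmax·S/(Km+S(1+I/Ki)); all reduce to Michaelis–Menten at
I = 0. Mixed/partial models are out of scope. Fitting is least squares on
untransformed rates (reciprocal-space fitting inflates low-rate errors;
the double-reciprocal linearization is used only for starting values),
with positive-parameter bounds and seeded log-normal multi-start. The
mechanism is selected by highest R², with AIC breaking near-ties; data
must span ≥ 2 substrate and ≥ 2 inhibitor levels. The inhibitory capacity
Ki/Km is reported rounded to one decimal below 10 and to an integer above
(the raw ratio is retained on the fit object). The default design grid —
substrate 0.1–3 mM, inhibitor 0, 2.5, 5, 7.5 mM — mirrors a standard
saturation-curve protocol for a dehydrogenase with Km ≈ 0.3 mM.

## The synthetic generator (`synthgen`)

The generator's defaults are the study conditions for every test and
planted-recovery analysis; they were chosen once as a realistic small
instance and are not tuned per test.

* **Chemistry.** Six scaffold families (diacid, polyamine, polyol,
  aromatic, acetal-ether, thioether), each a hand-written head SMILES
  extended by family-specific substituent units, one unit per pathway
  step. Within a pathway the smaller molecule embeds in the larger
  (overlap 1); unit alphabets are disjoint across families so cross-family
  overlap stays below the similarity threshold. Six currency hubs are
  phosphate/nucleotide-like scaffolds (tri/di/mono-phospho-sugars,
  nicotinamide riboside phosphates, a tripeptide), structurally far from
  the chain families.
* **Network.** Pathway p uses family p mod 6 and enzyme class
  (p mod 6) + 1; chains of 8 metabolites give 7 conversions per pathway,
  plus one hub-synthesis reaction per hub carrying an essential gene. The
  two most currency-like hubs drive the first reaction of every pathway
  (so they span all compartments); other reactions couple a hub with
  probability 0.3.
* **Planted inhibition.** An edge (m, r) is planted with probability 0.9
  for hubs (currency metabolites are the most frequent inhibitors), 0.6
  where the best substrate MCS overlap reaches 0.8 (similarity-driven
  inhibition), 0.03 otherwise. Non-hub edges whose co-localization is
  organelle-only are damped by a factor 0.05 — the organellar depletion of
  self-inhibition that the compartment analyses are designed to detect;
  cytoplasmic co-localization is untouched. Mechanisms are drawn
  competitive-heavy (0.85/0.10/0.05) for similarity-driven edges and
  allosteric-leaning (0.35/0.45/0.20) otherwise; 70% of edges carry a
  recorded mechanism (the rest are "unknown" and excluded from the gold
  standard). Even-index pathways are cytosolic, odd ones cycle through the
  organelles; 4 compartments by default.
* **What it does not emulate**: realistic human metabolome chemistry,
  pathway branching, stereochemistry, transport, quantitative Ki values,
  or literature testing bias. Passing the planted-recovery tests shows the
  statistics detect the planted structure at realistic sizes — not that
  any particular biological claim holds in real snapshots.

All randomness flows from one root seed through deterministically derived
child seeds; identical seeds give byte-identical outputs.

## Problem sizes

The default instance (54 metabolites, 48 reactions, ~450 edges) keeps a
full generation-plus-analysis cycle in seconds while leaving every planted
effect statistically detectable; the random-graph null uses the
1303-node/5989-edge size with 20–50 replicates, and calibration loops use
100 label shufflings — the same order as the permutation FDR itself.

## Known limitations

* The MCS is induced and connected; tools that maximize bond counts or
  allow disconnected common fragments will differ on ring-containing
  pairs.
* The discrete log-normal/Poisson/exponential fits are tail-conditioned
  MLEs; they are meant for model comparison on the same tail, not as
  standalone parameter estimates.
* The permutation FDR is the only multiplicity control, by design; no
  BH/Bonferroni layer is added.
* Compartment logic is set intersection; a metabolite present in two
  organelles co-localizes with both, which slightly understates isolation.
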