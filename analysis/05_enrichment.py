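#!/usr/bin/env python
"""Who inhibits whom: class enrichment, pathways, essentiality, mechanisms.

Hypergeometric enrichment of inhibitor superclasses against enzyme classes
with permutation FDR, directed pathway-pathway inhibition, Welch comparisons
of inhibition degree by essentiality, and the gold-standard mechanism tally.
Tables under results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from inhibnet import enrich, netcore

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "enrichment"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = netcore.load_model(ROOT / "data",
                                superclass_map=ROOT / "data" / "superclass.tsv")
    net = netcore.map_inhibitors(bundle, ROOT / "data" / "annotations.tsv",
                                 id_map=ROOT / "data" / "idmap.tsv")

    observed = enrich.class_enrichment(net)
    results = enrich.permutation_fdr(net, observed, n_perm=100, seed=1)
    frame = enrich.results_to_frame(results)
    frame.to_csv(OUT / "class_enrichment.tsv", sep="\t", index=False)
    sig = frame[frame["p"] < 0.05]
    print(f"{len(sig)} of {len(frame)} class pairs significantly enriched:")
    for _, row in sig.iterrows():
        print(f"  {row['from_class']} -> {row['to_class']}: "
              f"p = {row['p']:.2e}, FDR = {row['fdr']:.2f}")

    essential = set((ROOT / "data" / "essential_genes.txt").read_text().split())
    enrich.annotate_essentiality(bundle, essential)
    comp = enrich.compare_by_essentiality(net)
    met, enz = comp["metabolites"], comp["enzymes"]
    print(f"\nessential metabolites inhibit more enzymes: "
          f"{met.group_means['essential']:.1f} vs "
          f"{met.group_means['nonessential']:.1f} edges (Welch p = {met.p:.3f})")
    print(f"enzyme essentiality does not attract inhibition: p = {enz.p:.2f}")

    pw = enrich.pathway_inhibition_enrichment(net)
    pd.DataFrame([{"from": r.from_group, "to": r.to_group, "k": r.k, "p": r.p}
                  for r in pw]).to_csv(OUT / "pathway_inhibition.tsv", sep="\t",
                                       index=False)
    diag = sorted(r.from_group for r in pw if r.from_group == r.to_group)
    print(f"self-inhibiting pathways (p < 0.01): {', '.join(diag)}")

    tally = enrich.mechanism_tally(ROOT / "data" / "gold_standard.tsv")
    print(f"\nmechanism tally over {tally.n} recorded determinations: "
          + ", ".join(f"{m} {100 * f:.1f}%" for m, f in tally.fractions.items()))


if __name__ == "__main__":
    main()
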