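#!/usr/bin/env python
"""Assemble the bipartite inhibition network from the generated snapshot.

Reads the file set written by 01_generate_data.py through the same loaders a
curated BRENDA/Recon2-style snapshot would use, reports the row accounting
(mapped + dropped = total), and writes the network as GraphML and edges.tsv
under results/network/.
"""

from pathlib import Path

from inhibnet import netcore

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "network"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = netcore.load_model(DATA, superclass_map=DATA / "superclass.tsv")
    net = netcore.map_inhibitors(bundle, DATA / "annotations.tsv",
                                 id_map=DATA / "idmap.tsv")
    net.to_graphml(OUT / "network.graphml")
    net.to_edges_tsv(OUT / "edges.tsv")

    c = bundle.provenance.counts
    print(f"model: {c['metabolites']} metabolites, {c['reactions']} reactions "
          f"({c['reactions_dropped']} rows dropped, {c['reactions_merged']} merged)")
    print(f"annotations: {c['annotation_rows']} rows -> "
          f"{c['annotation_rows_mapped']} mapped + {c['annotation_rows_dropped']} "
          f"dropped; {c['edges']} distinct (metabolite, EC) edges")
    n_inhibitors = len({e.metabolite_id for e in net.edges})
    n_inhibited = len({e.ec_number for e in net.edges})
    print(f"{n_inhibitors} metabolites inhibit {n_inhibited} of "
          f"{len(net.reactions)} reactions "
          f"({100 * n_inhibited / len(net.reactions):.0f}%)")


if __name__ == "__main__":
    main()
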