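#!/usr/bin/env python
"""Whole-cohort semantic map: Auto-CM training, MST backbone, MRG.

Reads the cohort written by 01_generate_cohort.py, expands it into the 32
complementary high/low nodes, trains the Auto-Contractive Map, and extracts
the minimum-spanning-tree backbone and the maximally regular graph.  Writes
edge lists and hub rankings under results/ and reports where the fracture
node attaches.
"""

import networkx as nx
import pandas as pd

from osteomap.autocm import train_autocm, weights_to_distances
from osteomap.cohort import read_cohort_csv
from osteomap.graphs import (
    find_hubs,
    maximally_regular_graph,
    minimum_spanning_tree,
    write_edgelist_csv,
)
from osteomap.scaling import expand_complementary

cohort = read_cohort_csv("results/cohort.csv")
scaled = expand_complementary(cohort)
print(f"scaled matrix: {scaled.n_records} records x {scaled.n_nodes} nodes")

wm = train_autocm(scaled)
print(f"Auto-CM: {wm.epochs_run} epochs, converged={wm.converged}")
dm = weights_to_distances(wm)

mst = minimum_spanning_tree(dm)
mrg = maximally_regular_graph(dm, mst)
write_edgelist_csv(mst, "results/mst_edges.csv")
write_edgelist_csv(mrg, "results/mrg_edges.csv")

hubs = find_hubs(mst)
pd.DataFrame(
    {"node": hubs, "degree": [mst.degree(n) for n in hubs]}
).to_csv("results/mst_hubs.csv", index=False)

print(f"\nMST: {mst.n_edges} edges; MRG: {mrg.n_edges} edges "
      f"({mrg.n_edges - mst.n_edges} chords added)")
print("top MST hubs:", ", ".join(f"{n} (deg {mst.degree(n)})" for n in hubs[:5]))

dists = nx.shortest_path_length(mst.graph, "Fracture yes")
near = sorted((d, n) for n, d in dists.items() if 0 < d <= 2)
print("\nnodes within MST distance 2 of 'Fracture yes':")
for d, n in near:
    print(f"  {d}  {n}")
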