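"""Cluster simulated cells with the dual-importance preference walk (DIPHW).

Builds the cell-node / gene-hyperedge hypergraph from preprocessed counts,
computes the DIPHW node-to-node transition matrix, samples walks, trains
skip-gram cell embeddings and applies K-means.  Prints the five external
evaluation measures against the simulator's ground-truth cell types.
"""

import hyperwalk as hw

cfg = hw.paper_like_profile(genes_per_module=40, n_modules=5, seed=3)
ds = hw.simulate(cfg)
print(f"simulated {ds.counts.n_cells} cells in {cfg.n_types} types")

rc = hw.RunConfig(method="diphw", K=cfg.n_types, alpha=8.0, seed=3, window=2,
                  walks_per_node=20, walk_length=80, dim=64, epochs=10)
labels, report = hw.run_pipeline(ds.counts, rc, truth=ds.cell_labels)

print(f"ARI {report.ari:.3f}  NMI {report.nmi:.3f}  AMI {report.ami:.3f}  "
      f"ACC {report.acc:.3f}  F1 {report.f1:.3f}")
print("-> 1.0 means the K-means clusters reproduce the planted cell types "
      "exactly (up to relabelling); 0 means chance agreement.")
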