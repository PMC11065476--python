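"""Assemble a tiny three-layer network by hand and walk it.

A single TF binds two co-accessible peaks; each peak sits near one gene.
The walk seeded at the TF scores every node by proximity, and the
RNA-layer ranking is the TF's predicted target list.
"""

from plexus import (
    BipartiteLinks,
    Layer,
    RWRConfig,
    assemble,
    build_transition,
    rank_layer,
    rwr,
)

tf = Layer("tf", ["TF1"], [])
atac = Layer("atac", ["p1", "p2", "p3"], [("p1", "p2", 1.0)])  # p3 is isolated
rna = Layer("rna", ["gA", "gB", "gC"], [])

m = assemble(
    [tf, atac, rna],
    [
        BipartiteLinks("tf", "atac", [("TF1", "p1", 1.0), ("TF1", "p2", 1.0)]),
        BipartiteLinks("atac", "rna", [("p1", "gA", 1.0), ("p2", "gB", 1.0)]),
    ],
)

cfg = RWRConfig(restart=0.5)
op = build_transition(m, cfg)
scores = rwr(op, {"tf:TF1": 1.0}, cfg)

print("steady-state probabilities (sum = %.3f):" % scores.values.sum())
for node, p in sorted(scores.as_dict().items(), key=lambda kv: -kv[1]):
    print(f"  {node:10s} {p:.4f}")

ranking = rank_layer(scores, m, "rna")
print("\npredicted targets of TF1 (genes ranked by walk score):")
for gene, s in zip(ranking.nodes, ranking.scores):
    print(f"  {gene}  {s:.4f}")
print("\ngC is unreachable from the TF, so it scores exactly 0.")
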