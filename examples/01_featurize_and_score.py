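"""Build a synthetic peptide-protein complex, featurize it as a residue
graph and score it with a freshly initialized network.

The graph has one vertex per residue (BLOSUM62 column + chain one-hot) and
directed edges between residues whose C-beta (C-alpha for glycine)
reference points lie within 10 A.  The untrained score is arbitrary; see
example 03 for training.
"""

from pepscore import build_graph, forward, init_params, make_fixture_complex
from pepscore.gnn import ModelConfig

complex_ = make_fixture_complex(seed=0)
print(f"receptor: {len(complex_.receptor)} residues, "
      f"peptide: {len(complex_.peptide)} residues")

graph = build_graph(complex_)
n_self = int((graph.edge_features[:, 1] == 1).sum())
n_cov = int((graph.edge_features[:, 0] == 1).sum())
print(f"graph: {graph.n_vertices} vertices, {graph.n_edges} directed edges "
      f"({n_self} self, {n_cov} covalent)")

params = init_params(ModelConfig(seed=1))
pred = forward(graph, params)
print(f"untrained quality score: {pred.score:.3f}  (bounded to [0, 1]; "
      "a trained model regresses 1/(1+(LRMSD/8)^2))")
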