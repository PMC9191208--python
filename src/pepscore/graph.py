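"""Residue-graph featurization of a peptide-protein complex.

Vertices are residues (receptor first, then peptide), each carrying the
BLOSUM62 substitution column of its amino acid plus a two-way chain
one-hot.  Directed edges connect every residue pair whose reference points
(C-beta, or C-alpha for glycine) lie within the distance cutoff (default
10 A, inclusive), plus one self edge per vertex; sequence-adjacent residues
of the same chain are always connected and flagged covalent.  Edge features
are ``[is_covalent, is_self]``.  A constant scalar placeholder stands in
for global input features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure import PepComplex, Residue

logger = logging.getLogger(__name__)

VERTEX_DIM = 22  # 20 BLOSUM62 entries + 2-way chain one-hot
EDGE_DIM = 2     # [is_covalent, is_self]
GLOBAL_PLACEHOLDER = 0.0
DEFAULT_CUTOFF = 10.0  # A

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


def _blosum_columns() -> dict[str, np.ndarray]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    cols = {}
    for aa in AA_ORDER:
        cols[aa] = np.array([mat[aa, other] for other in AA_ORDER], dtype=float)
    return cols


BLOSUM62_COLUMNS = _blosum_columns()


@dataclass
class ComplexGraph:
    """Featurized residue graph, the model input.

    ``vertices`` is (N, 22) float, ``edge_features`` is (E, 2) float with
    ``senders``/``receivers`` the matching (E,) int vertex indices.
    """

    vertices: np.ndarray
    senders: np.ndarray
    receivers: np.ndarray
    edge_features: np.ndarray
    global_in: np.ndarray = field(
        default_factory=lambda: np.array([GLOBAL_PLACEHOLDER])
    )
    vertex_meta: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_features.shape[0]

    def permuted(self, perm: np.ndarray) -> "ComplexGraph":
        """Relabel vertices by permutation ``perm`` (new index of old vertex i)."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        return ComplexGraph(
            vertices=self.vertices[inv],
            senders=perm[self.senders],
            receivers=perm[self.receivers],
            edge_features=self.edge_features.copy(),
            global_in=self.global_in.copy(),
            vertex_meta=[self.vertex_meta[i] for i in inv] if self.vertex_meta else [],
        )


def reference_point(residue: Residue) -> np.ndarray:
    """C-beta position; C-alpha for glycine or when C-beta is absent."""
    if "CA" not in residue.atoms:
        raise ValueError(f"residue {residue.name3} {residue.index} has no CA")
    if residue.name3 == "GLY":
        return residue.ca
    if "CB" in residue.atoms:
        return residue.atoms["CB"].coord
    logger.warning(
        "residue %s %s/%d lacks CB; falling back to CA",
        residue.name3, residue.chain_id, residue.index,
    )
    return residue.ca


def vertex_features(residue: Residue, is_peptide: bool) -> np.ndarray:
    blosum = BLOSUM62_COLUMNS.get(residue.one_letter)
    if blosum is None:
        logger.warning(
            "unknown amino acid %r; using all-zero substitution column",
            residue.name3,
        )
        blosum = np.zeros(len(AA_ORDER))
    onehot = np.array([0.0, 1.0]) if is_peptide else np.array([1.0, 0.0])
    return np.concatenate([blosum, onehot])


def build_graph(complex_: PepComplex, cutoff: float = DEFAULT_CUTOFF) -> ComplexGraph:
    """Build the featurized residue graph of a complex.

    Contact edges use an inclusive reference-point cutoff; covalent edges
    (sequence neighbours with an author-numbering gap of at most 1) are
    added even beyond the cutoff.  Non-self edges appear as directed
    (i, j)/(j, i) pairs with identical features.
    """
    residues: list[tuple[Residue, bool]] = [
        (r, False) for r in complex_.receptor
    ] + [(r, True) for r in complex_.peptide]
    if not residues:
        raise ValueError("empty complex")

    verts = np.array([vertex_features(r, pep) for r, pep in residues])
    points = np.array([reference_point(r) for r, _ in residues])
    meta = [(r.chain_id, r.index) for r, _ in residues]
    n = len(residues)

    covalent: set[tuple[int, int]] = set()
    offset = 0
    for chain in (complex_.receptor, complex_.peptide):
        for k in range(len(chain) - 1):
            a, b = chain.residues[k], chain.residues[k + 1]
            if abs(b.author_seq - a.author_seq) <= 1:
                covalent.add((offset + k, offset + k + 1))
        offset += len(chain)

    dists = cdist(points, points)
    senders, receivers, feats = [], [], []
    for i in range(n):
        senders.append(i)
        receivers.append(i)
        feats.append([0.0, 1.0])
    for i in range(n):
        for j in range(i + 1, n):
            cov = (i, j) in covalent
            if dists[i, j] <= cutoff or cov:
                for s, r in ((i, j), (j, i)):
                    senders.append(s)
                    receivers.append(r)
                    feats.append([1.0 if cov else 0.0, 0.0])

    return ComplexGraph(
        vertices=verts,
        senders=np.array(senders, dtype=np.int64),
        receivers=np.array(receivers, dtype=np.int64),
        edge_features=np.array(feats, dtype=float),
        vertex_meta=meta,
    )


def graph_to_dict(graph: ComplexGraph) -> dict:
    """JSON-serializable dump of a graph (for the ``featurize`` command)."""
    return {
        "n_vertices": graph.n_vertices,
        "n_edges": graph.n_edges,
        "vertices": graph.vertices.tolist(),
        "senders": graph.senders.tolist(),
        "receivers": graph.receivers.tolist(),
        "edge_features": graph.edge_features.tolist(),
        "global_in": graph.global_in.tolist(),
        "vertex_meta": [list(m) for m in graph.vertex_meta],
    }
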