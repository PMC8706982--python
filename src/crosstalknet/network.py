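"""Cross-block similarity network and connected-component clusters.

Variable-level relevance network built from a fitted SGCCA model, in the
style of relevance networks for multi-block latent variable models: for
each pair of blocks and each component, features are projected onto the
bisector variate of the two blocks' components, and the similarity between
a feature of one block and a feature of the other is the sum over
components of the products of their projections. Edges survive when
|similarity| reaches the cut-off (0.6 by default); clusters are the
connected components of the thresholded graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .blocks import DataError
from .sgcca import SgccaModel

DEFAULT_CUTOFF = 0.6

Node = tuple[str, str]  # (feature name, block label)


@dataclass
class SimilarityNetwork:
    """Thresholded cross-block similarity graph with cluster labels."""

    graph: nx.Graph
    cutoff: float
    clusters: dict[Node, int] = field(default_factory=dict)

    @property
    def nodes(self) -> list[Node]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_clusters(self) -> int:
        return len(set(self.clusters.values())) if self.clusters else 0

    def cluster_members(self, cluster_id: int) -> list[Node]:
        return sorted(n for n, c in self.clusters.items() if c == cluster_id)

    def composition(self) -> pd.DataFrame:
        """Per-cluster counts of genus / fecal / plasma nodes."""
        rows = []
        for cid in sorted(set(self.clusters.values())):
            members = self.cluster_members(cid)
            rows.append(
                {
                    "cluster": cid,
                    "n_nodes": len(members),
                    **{
                        lab: sum(1 for _, b in members if b == lab)
                        for lab in ("genus", "fecal", "plasma")
                    },
                }
            )
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": u[0],
                "source_block": u[1],
                "target": v[0],
                "target_block": v[1],
                "similarity": d["similarity"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["source", "source_block", "target", "target_block", "similarity"]
        )

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for (feat, blk) in self.graph.nodes:
            g.add_node(f"{blk}:{feat}", block=blk, feature=feat,
                       cluster=int(self.clusters.get((feat, blk), -1)))
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(f"{u[1]}:{u[0]}", f"{v[1]}:{v[0]}", similarity=float(d["similarity"]))
        nx.write_graphml(g, str(path))


def compute_similarity_matrix(
    model: SgccaModel, block_pair: tuple[str, str]
) -> pd.DataFrame:
    """Signed similarity between selected features of two blocks.

    For components h = 1..H the shared variate is
    ``v_h = (t_A^h + t_B^h) / sd`` (unit SD); each feature's coordinate is
    its correlation with ``v_h``, and ``s_ij = sum_h coord_A(i,h) * coord_B(j,h)``,
    clipped to [-1, 1]. Only features carrying a nonzero weight on at least
    one component are included.
    """
    a_label, b_label = block_pair
    selected = model.selected_features()
    feats = {lab: selected[lab] for lab in block_pair}
    if not feats[a_label] or not feats[b_label]:
        return pd.DataFrame(
            np.zeros((len(feats[a_label]), len(feats[b_label]))),
            index=feats[a_label],
            columns=feats[b_label],
        )

    coords = {}
    for lab in block_pair:
        X = model.scaled_blocks[lab][feats[lab]].to_numpy()
        cols = []
        for h in range(model.n_components):
            v = (
                model.components[a_label].iloc[:, h].to_numpy()
                + model.components[b_label].iloc[:, h].to_numpy()
            )
            sd = v.std(ddof=1)
            if sd == 0:
                raise DataError(
                    f"zero-variance shared variate for pair {block_pair}, component {h + 1}"
                )
            v = (v - v.mean()) / sd
            Xc = X - X.mean(axis=0)
            xsd = X.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cor = (Xc.T @ v) / ((X.shape[0] - 1) * xsd)
            cor[~np.isfinite(cor)] = 0.0
            cols.append(cor)
        coords[lab] = np.column_stack(cols)
    sim = np.clip(coords[a_label] @ coords[b_label].T, -1.0, 1.0)
    return pd.DataFrame(sim, index=feats[a_label], columns=feats[b_label])


def build_network(
    similarities: dict[tuple[str, str], pd.DataFrame],
    cutoff: float = DEFAULT_CUTOFF,
) -> SimilarityNetwork:
    """Keep cross-block edges with |similarity| >= cutoff; drop isolated features."""
    g = nx.Graph()
    for (a_label, b_label), sim in similarities.items():
        S = sim.to_numpy()
        ii, jj = np.nonzero((np.abs(S) >= cutoff) & (S != 0))
        for i, j in zip(ii, jj):
            u: Node = (str(sim.index[i]), a_label)
            v: Node = (str(sim.columns[j]), b_label)
            if u == v:
                continue
            g.add_edge(u, v, similarity=float(S[i, j]))
    net = SimilarityNetwork(graph=g, cutoff=cutoff)
    net.clusters = extract_clusters(net)
    return net


def extract_clusters(network: SimilarityNetwork) -> dict[Node, int]:
    """Connected components, labeled 1..K by decreasing size.

    Ties in size are broken by the lexicographically smallest member name,
    so labeling is deterministic.
    """
    comps = [sorted(c) for c in nx.connected_components(network.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return {node: cid for cid, comp in enumerate(comps, start=1) for node in comp}


def all_pair_similarities(model: SgccaModel) -> dict[tuple[str, str], pd.DataFrame]:
    """Similarity matrices for every unordered pair of blocks in the model."""
    return {
        pair: compute_similarity_matrix(model, pair)
        for pair in combinations(model.labels, 2)
    }


def network_from_model(
    model: SgccaModel, cutoff: float = DEFAULT_CUTOFF
) -> SimilarityNetwork:
    """Convenience: similarities for all block pairs, thresholded network."""
    return build_network(all_pair_similarities(model), cutoff=cutoff)
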