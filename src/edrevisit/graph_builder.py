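"""Per-patient heterogeneous graph construction.

Each labeled instance becomes one graph with three node types and three edge
types:

* **visit** nodes, one per input visit, chained consecutively
  (visit t — visit t+1) so that visit order — not calendar time — is what
  the graph encodes;
* **service** nodes, one per *distinct* service code in the instance, linked
  to every visit at which the service occurred;
* **diagnosis** nodes, one per distinct diagnosis code, linked to every
  service node that co-occurred with that diagnosis at some visit.

Sharing service/diagnosis nodes across visits is what lets a service bridge
the diagnoses of different visits.  Edges are undirected; the stored
adjacency is symmetric, binary and has a zero diagonal (self-loops are a
model-layer concern).  Node features are type-specific — visit nodes carry
[age, triage, disposition], service and diagnosis nodes their own one-hot —
zero-padded to one shared width with a 3-slot node-type indicator prepended
so a single node-feature matrix exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .preprocessing import FeatureSchema, LabeledInstance

__all__ = [
    "NODE_TYPES",
    "EDGE_TYPES",
    "PatientGraph",
    "GraphBatch",
    "build_patient_graph",
    "to_matrices",
    "batch_graphs",
    "unbatch_graphs",
    "dump_graph",
]

NODE_TYPES = ("visit", "service", "diagnosis")
EDGE_TYPES = ("visit-visit", "visit-service", "service-diagnosis")


@dataclass(frozen=True)
class PatientGraph:
    """A heterogeneous patient graph ready for matrix conversion.

    ``edges`` holds undirected typed pairs ``(i, j, edge_type)`` with
    ``i < j`` under the canonical node ordering: visits in temporal order,
    then services, then diagnoses (each by schema index).
    """

    patient_id: str
    node_ids: tuple[str, ...]
    node_types: tuple[str, ...]
    features: np.ndarray  # (n_nodes, feature_width)
    edges: frozenset[tuple[int, int, str]]
    label: int

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def edge_count(self, edge_type: str | None = None) -> int:
        if edge_type is None:
            return len(self.edges)
        return sum(1 for e in self.edges if e[2] == edge_type)


def _code_order(codes: set, index: dict) -> list:
    """Schema-index order; codes unseen by the schema go last, sorted."""
    return sorted(codes, key=lambda c: (index.get(c, len(index)), str(c)))


def build_patient_graph(instance: LabeledInstance, schema: FeatureSchema) -> PatientGraph:
    """Construct the typed patient graph for one labeled instance."""
    visits = instance.input_visits
    if not visits:
        raise ValueError("instance has no input visits")

    services = _code_order({c for v in visits for c in v.service_codes}, schema.service_index)
    diagnoses = _code_order({v.diagnosis_code for v in visits}, schema.diagnosis_index)
    svc_pos = {c: i for i, c in enumerate(services)}
    diag_pos = {c: i for i, c in enumerate(diagnoses)}

    n_v, n_s = len(visits), len(services)
    n_nodes = n_v + n_s + len(diagnoses)

    tri_w, disp_w = len(schema.triage_index), len(schema.disposition_index)
    body_width = max(1 + tri_w + disp_w, len(schema.service_index), len(schema.diagnosis_index))
    width = 3 + body_width
    feats = np.zeros((n_nodes, width))
    node_ids: list[str] = []
    node_types: list[str] = []

    for t, v in enumerate(visits):
        feats[t, 0] = 1.0  # node-type indicator: visit
        feats[t, 3] = (v.age_years - schema.age_center) / schema.age_scale
        i = schema.triage_index.get(v.triage_level)
        if i is not None:
            feats[t, 4 + i] = 1.0
        i = schema.disposition_index.get(v.disposition_code)
        if i is not None:
            feats[t, 4 + tri_w + i] = 1.0
        node_ids.append(f"visit:{t}")
        node_types.append("visit")
    for k, code in enumerate(services):
        row = n_v + k
        feats[row, 1] = 1.0
        i = schema.service_index.get(code)
        if i is not None:
            feats[row, 3 + i] = 1.0
        node_ids.append(f"service:{code}")
        node_types.append("service")
    for k, code in enumerate(diagnoses):
        row = n_v + n_s + k
        feats[row, 2] = 1.0
        i = schema.diagnosis_index.get(code)
        if i is not None:
            feats[row, 3 + i] = 1.0
        node_ids.append(f"diagnosis:{code}")
        node_types.append("diagnosis")

    edges: set[tuple[int, int, str]] = set()
    for t in range(n_v - 1):
        edges.add((t, t + 1, "visit-visit"))
    for t, v in enumerate(visits):
        d_node = n_v + n_s + diag_pos[v.diagnosis_code]
        for code in v.service_codes:
            s_node = n_v + svc_pos[code]
            edges.add((t, s_node, "visit-service"))
            edges.add((min(s_node, d_node), max(s_node, d_node), "service-diagnosis"))

    return PatientGraph(
        patient_id=instance.patient_id,
        node_ids=tuple(node_ids),
        node_types=tuple(node_types),
        features=feats,
        edges=frozenset(edges),
        label=instance.label,
    )


def to_matrices(graph: PatientGraph) -> tuple[np.ndarray, np.ndarray]:
    """Return the (symmetric binary) adjacency and node-feature matrices."""
    n = graph.n_nodes
    adj = np.zeros((n, n))
    for i, j, _ in graph.edges:
        adj[i, j] = 1.0
        adj[j, i] = 1.0
    return adj, graph.features.copy()


@dataclass(frozen=True)
class GraphBatch:
    """Block-diagonal packing of several patient graphs.

    ``node_slices`` records each graph's node index range in the packed
    matrices, so unbatching restores every graph exactly.
    """

    graphs: tuple[PatientGraph, ...]
    adjacency: sp.csr_matrix  # block-diagonal, (N, N)
    features: np.ndarray  # (N, feature_width)
    node_slices: tuple[tuple[int, int], ...]
    labels: np.ndarray  # (n_graphs,)

    @property
    def n_graphs(self) -> int:
        return len(self.graphs)

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]

    def graph_index(self) -> np.ndarray:
        """Graph id per node row, for segment pooling."""
        idx = np.empty(self.n_nodes, dtype=np.int64)
        for g, (a, b) in enumerate(self.node_slices):
            idx[a:b] = g
        return idx


def batch_graphs(graphs: Sequence[PatientGraph]) -> GraphBatch:
    """Pack graphs into one block-diagonal adjacency and stacked features."""
    if not graphs:
        raise ValueError("cannot batch zero graphs")
    widths = {g.features.shape[1] for g in graphs}
    if len(widths) != 1:
        raise ValueError("graphs in a batch must share feature width")
    blocks = [sp.csr_matrix(to_matrices(g)[0]) for g in graphs]
    adjacency = sp.block_diag(blocks, format="csr")
    features = np.vstack([g.features for g in graphs])
    slices, off = [], 0
    for g in graphs:
        slices.append((off, off + g.n_nodes))
        off += g.n_nodes
    labels = np.array([g.label for g in graphs], dtype=float)
    return GraphBatch(tuple(graphs), adjacency, features, tuple(slices), labels)


def unbatch_graphs(batch: GraphBatch) -> list[PatientGraph]:
    return list(batch.graphs)


def dump_graph(graph: PatientGraph, path) -> None:
    """Write a human-readable edge-list dump for inspection."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# patient {graph.patient_id} label {graph.label}\n")
        fh.write("# nodes: id\ttype\n")
        for nid, ntype in zip(graph.node_ids, graph.node_types):
            fh.write(f"{nid}\t{ntype}\n")
        fh.write("# edges: src\tdst\ttype\n")
        for i, j, etype in sorted(graph.edges):
            fh.write(f"{graph.node_ids[i]}\t{graph.node_ids[j]}\t{etype}\n")
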