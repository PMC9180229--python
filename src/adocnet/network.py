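"""Binary directed network container and node-attribute table.

The unit of analysis is a reply relation: a directed edge ``i -> j`` means
user *i* posted a reply or comment to user *j*'s content.  The network is
binary — any number of replies between an ordered pair collapses to a single
tie — and self-replies are dropped (they carry no dyadic information).
Isolated users are retained so the node set always matches the attribute
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: canonical attribute columns and their admissible codes
ATTRIBUTES = ("gender", "experience", "emotion_polarity", "topic_preference")
ATTRIBUTE_LEVELS = {
    "gender": (0, 1),                     # 0 female, 1 male
    "experience": (0, 1),                 # 0 inexperienced, 1 experienced
    "emotion_polarity": (0, 1, 2),        # 0 neutral, 1 negative, 2 positive
    "topic_preference": (1, 2, 3, 4, 5, 6, 7),
}
#: topic code -> short label used in reports
TOPIC_LABELS = {1: "PP", 2: "SGAD", 3: "PAR", 4: "EC", 5: "DE", 6: "DEH", 7: "SS"}


class DyadCensus(NamedTuple):
    mutual: int
    asymmetric: int
    null: int


@dataclass(eq=False)
class DirectedNetwork:
    """A binary digraph on ``n_nodes`` labelled nodes.

    ``edges`` holds ordered pairs of *internal* indices into ``node_ids``.
    Instances are treated as immutable after construction.
    """

    n_nodes: int
    node_ids: tuple
    edges: frozenset
    _adj: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.node_ids = tuple(self.node_ids)
        self.edges = frozenset((int(i), int(j)) for i, j in self.edges)
        if self.n_nodes <= 0:
            raise ValidationError("network must have at least one node")
        if len(self.node_ids) != self.n_nodes:
            raise ValidationError("node_ids length does not match n_nodes")
        if len(set(self.node_ids)) != self.n_nodes:
            raise ValidationError("node_ids must be unique")
        for i, j in self.edges:
            if i == j:
                raise ValidationError(f"self-loop ({i}, {j}) is not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValidationError(f"edge ({i}, {j}) outside [0, {self.n_nodes})")

    # -- basic structure ---------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def density(self) -> float:
        if self.n_nodes < 2:
            return 0.0
        return self.n_edges / (self.n_nodes * (self.n_nodes - 1))

    def mean_degree(self) -> float:
        return self.n_edges / self.n_nodes

    def adjacency(self) -> np.ndarray:
        """Dense adjacency matrix (uint8); cached, do not mutate."""
        if self._adj is None:
            A = np.zeros((self.n_nodes, self.n_nodes), dtype=np.uint8)
            if self.edges:
                e = self.edge_array()
                A[e[:, 0], e[:, 1]] = 1
            self._adj = A
        return self._adj

    def edge_array(self) -> np.ndarray:
        """Edges as an (E, 2) int64 array in a stable sorted order."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(self.edges), dtype=np.int64)

    def in_degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=0).astype(np.int64)

    def out_degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1).astype(np.int64)

    # -- interop -----------------------------------------------------------
    def edge_id_pairs(self) -> list:
        """Edges as (source_id, target_id) pairs of external identifiers."""
        ids = self.node_ids
        return [(ids[i], ids[j]) for i, j in sorted(self.edges)]

    def to_networkx(self, attrs: "NodeAttributeTable | None" = None):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edge_id_pairs())
        if attrs is not None:
            frame = attrs.frame.reindex(list(self.node_ids))
            for col in ATTRIBUTES:
                nx.set_node_attributes(g, frame[col].to_dict(), col)
        return g

    @classmethod
    def from_adjacency(cls, A: np.ndarray, node_ids: Sequence | None = None):
        A = np.asarray(A)
        n = A.shape[0]
        if node_ids is None:
            node_ids = tuple(range(n))
        src, dst = np.nonzero(A)
        return cls(n, tuple(node_ids), frozenset(zip(src.tolist(), dst.tolist())))

    def __eq__(self, other):
        return (
            isinstance(other, DirectedNetwork)
            and self.n_nodes == other.n_nodes
            and self.node_ids == other.node_ids
            and self.edges == other.edges
        )


def build_network(edge_records: Iterable, node_ids: Sequence) -> DirectedNetwork:
    """Assemble a binary reply network from raw (source_id, target_id) records.

    Repeated records collapse to one tie, self-replies are dropped with a
    logged count, and ids with no records are retained as isolates.  Every
    endpoint must appear in ``node_ids``.
    """
    node_ids = tuple(node_ids)
    if not node_ids:
        raise ValidationError("node_ids is empty")
    if len(set(node_ids)) != len(node_ids):
        raise ValidationError("node_ids contains duplicates")
    index = {v: k for k, v in enumerate(node_ids)}
    edges = set()
    n_self = 0
    for rec in edge_records:
        s, t = rec[0], rec[1]
        try:
            i, j = index[s], index[t]
        except KeyError as exc:
            raise ValidationError(f"edge endpoint {exc.args[0]!r} not in node_ids") from None
        if i == j:
            n_self += 1
            continue
        edges.add((i, j))
    if n_self:
        logger.info("build_network: dropped %d self-loop record(s)", n_self)
    return DirectedNetwork(len(node_ids), node_ids, frozenset(edges))


def dyad_census(network: DirectedNetwork) -> DyadCensus:
    """Counts of mutual / asymmetric / null unordered node pairs."""
    A = network.adjacency().astype(bool)
    iu = np.triu_indices(network.n_nodes, k=1)
    both = (A & A.T)[iu].sum()
    either = (A | A.T)[iu].sum()
    total = network.n_nodes * (network.n_nodes - 1) // 2
    mutual = int(both)
    asymmetric = int(either - both)
    return DyadCensus(mutual, asymmetric, total - mutual - asymmetric)


class NodeAttributeTable:
    """Per-node coded covariates: gender, experience, emotion polarity, topic.

    Wraps a pandas DataFrame indexed by node id with exactly the columns in
    :data:`ATTRIBUTES`, all values restricted to the documented codes.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in ATTRIBUTES if c not in frame.columns]
        if missing:
            raise ValidationError(f"attribute table missing column(s): {missing}")
        frame = frame[list(ATTRIBUTES)].copy()
        if frame.index.has_duplicates:
            raise ValidationError("attribute table has duplicate node ids")
        for col in ATTRIBUTES:
            values = frame[col]
            if values.isna().any():
                raise ValidationError(f"attribute {col!r} has missing values")
            frame[col] = values.astype(np.int64)
            bad = set(frame[col].unique()) - set(ATTRIBUTE_LEVELS[col])
            if bad:
                raise ValidationError(f"attribute {col!r} has invalid code(s) {sorted(bad)}")
        self.frame = frame

    def __len__(self):
        return len(self.frame)

    def __eq__(self, other):
        return isinstance(other, NodeAttributeTable) and self.frame.equals(other.frame)

    def matrix(self, node_ids: Sequence) -> np.ndarray:
        """(n, 4) int64 matrix aligned to ``node_ids`` order."""
        missing = [v for v in node_ids if v not in self.frame.index]
        if missing:
            raise ValidationError(f"attribute table missing node(s): {missing[:5]}")
        return self.frame.reindex(list(node_ids)).to_numpy(dtype=np.int64)

    def to_csv(self, path):
        self.frame.to_csv(path, index_label="user_id")

    @classmethod
    def read_csv(cls, path):
        return cls(pd.read_csv(path, index_col="user_id"))
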