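"""Network-restricted prediction and motion-sensitive network extraction.

Edges can be restricted to within-network (both endpoints in one network)
or between-network (endpoints in two given networks) cells of a node
partition, and the full nested CPM rerun per cell to localize predictive
structure.  Edge masks selected across multiple sessions/samples are
consolidated into a *motion-sensitive network*: the edges retained in at
least a configured fraction of the mask sets, independently for positive
and negative networks, summarized by per-node degree (hubs).  A fixed
network plus bilinear coefficients can be applied unchanged to a new
cohort's edges for external validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .connectome import edge_index_pairs
from .cpm import (FeatureMasks, PredictionResult, accuracy, critical_r,
                  loo_cv)
from .exceptions import (DimensionError, InvalidResultError, PartitionError,
                         ValidationError)


@dataclass
class NetworkPartition:
    """Assignment of every node to exactly one network label."""

    labels: np.ndarray  # one label per node, in node order

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or self.labels.shape[0] < 2:
            raise PartitionError("partition needs a label per node (>= 2 nodes)")

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def networks(self) -> list:
        return sorted(set(self.labels.tolist()))

    def network_pairs(self) -> list[tuple]:
        nets = self.networks
        return [(a, b) for i, a in enumerate(nets) for b in nets[i + 1:]]


@dataclass
class OverlapNetwork:
    """Consensus motion-sensitive network across sessions/samples."""

    positive_edges: np.ndarray  # edge indices
    negative_edges: np.ndarray
    n_nodes: int
    min_fraction: float
    n_mask_sets: int
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positive_edges = np.asarray(self.positive_edges, dtype=int)
        self.negative_edges = np.asarray(self.negative_edges, dtype=int)
        if np.intersect1d(self.positive_edges, self.negative_edges).size:
            raise ValidationError("positive and negative edge lists overlap")

    @property
    def n_edges_total(self) -> int:
        return self.positive_edges.size + self.negative_edges.size

    def node_pairs(self, which: str = "positive") -> np.ndarray:
        iu, ju = edge_index_pairs(self.n_nodes)
        idx = self.positive_edges if which == "positive" else self.negative_edges
        return np.column_stack([iu[idx], ju[idx]])

    def degrees(self) -> np.ndarray:
        """Per-node edge count over the union of positive and negative lists."""
        iu, ju = edge_index_pairs(self.n_nodes)
        deg = np.zeros(self.n_nodes, dtype=int)
        for idx in (self.positive_edges, self.negative_edges):
            np.add.at(deg, iu[idx], 1)
            np.add.at(deg, ju[idx], 1)
        return deg

    def to_masks(self, n_edges: int) -> FeatureMasks:
        pos = np.zeros(n_edges, dtype=bool)
        neg = np.zeros(n_edges, dtype=bool)
        pos[self.positive_edges] = True
        neg[self.negative_edges] = True
        return FeatureMasks(positive=pos, negative=neg,
                            selection_p=float("nan"), n_subjects=0)


def edge_cell_mask(n_nodes: int, partition: NetworkPartition,
                   mode: str, target) -> np.ndarray:
    """Boolean mask over edges belonging to a within/between-network cell."""
    if partition.n_nodes != n_nodes:
        raise PartitionError(
            f"partition covers {partition.n_nodes} nodes, expected {n_nodes}")
    iu, ju = edge_index_pairs(n_nodes)
    li, lj = partition.labels[iu], partition.labels[ju]
    known = set(partition.networks)
    if mode == "within":
        if target not in known:
            raise PartitionError(f"unknown network label {target!r}")
        return (li == target) & (lj == target)
    if mode == "between":
        a, b = target
        if a not in known or b not in known:
            raise PartitionError(f"unknown network label in pair {target!r}")
        if a == b:
            raise PartitionError("between mode needs two distinct networks")
        return ((li == a) & (lj == b)) | ((li == b) & (lj == a))
    raise ValidationError("mode must be 'within' or 'between'")


def restrict_mask(masks: FeatureMasks, partition: NetworkPartition,
                  mode: str, target) -> FeatureMasks:
    """Keep only mask edges inside one within/between-network cell."""
    n_nodes = partition.n_nodes
    if masks.n_edges != n_nodes * (n_nodes - 1) // 2:
        raise DimensionError("mask edge count does not match partition size")
    cell = edge_cell_mask(n_nodes, partition, mode, target)
    return FeatureMasks(positive=masks.positive & cell,
                        negative=masks.negative & cell,
                        selection_p=masks.selection_p,
                        n_subjects=masks.n_subjects)


@dataclass
class NetworkwisePrediction:
    """Per-cell CPM accuracies with Bonferroni significance flags."""

    within: dict
    between: dict
    critical_r_within: float
    critical_r_between: float


def networkwise_prediction(edges: np.ndarray, scores: np.ndarray,
                           partition: NetworkPartition,
                           cfg: RunConfig,
                           alpha: float = 0.05) -> NetworkwisePrediction:
    """Run the full nested LOO-CPM restricted to each network cell.

    Returns one result per network (within-network edges only) and per
    unordered network pair (between-network edges only), with significance
    flags from :func:`critical_r` Bonferroni-corrected over the number of
    cells of each kind.  Cells with fewer than 2 candidate edges are
    flagged not-computable (``None``).
    """
    edges = np.asarray(edges, dtype=float)
    n_subjects, n_edges = edges.shape
    n_nodes = partition.n_nodes
    if n_edges != n_nodes * (n_nodes - 1) // 2:
        raise DimensionError("edge count does not match partition size")
    nets = partition.networks
    pairs = partition.network_pairs()
    rc_within = critical_r(n_subjects, alpha, len(nets))
    rc_between = critical_r(n_subjects, alpha, max(len(pairs), 1))

    def run_cell(cell: np.ndarray):
        idx = np.where(cell)[0]
        if idx.size < 2:
            return None
        res = loo_cv(edges[:, idx], scores, cfg)
        return res

    within = {net: run_cell(edge_cell_mask(n_nodes, partition, "within", net))
              for net in nets}
    between = {pair: run_cell(edge_cell_mask(n_nodes, partition, "between", pair))
               for pair in pairs}
    return NetworkwisePrediction(within=within, between=between,
                                 critical_r_within=rc_within,
                                 critical_r_between=rc_between)


def overlap_network(mask_sets: Sequence[FeatureMasks],
                    min_fraction: float = 0.5,
                    n_nodes: int | None = None,
                    provenance: Sequence[str] = ()) -> OverlapNetwork:
    """Edges retained in at least ``min_fraction`` of the mask sets.

    Counting is independent for positive and negative masks.  An edge that
    qualifies on both sides is assigned to the side with the higher count;
    exact ties are dropped from both lists (keeps the lists disjoint).
    """
    if len(mask_sets) < 2:
        raise ValidationError("need at least 2 mask sets")
    n_edges = mask_sets[0].n_edges
    for m in mask_sets:
        if m.n_edges != n_edges:
            raise DimensionError("mask sets have inconsistent edge counts")
    if n_nodes is None:
        # recover node count from the triangular number
        n_nodes = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
        if n_nodes * (n_nodes - 1) // 2 != n_edges:
            raise DimensionError("edge count is not triangular; pass n_nodes")
    n_sets = len(mask_sets)
    pos_counts = np.sum([m.positive for m in mask_sets], axis=0)
    neg_counts = np.sum([m.negative for m in mask_sets], axis=0)
    # integer counts against a possibly inexact fractional threshold
    threshold = min_fraction * n_sets - 1e-9
    pos_in = pos_counts >= threshold
    neg_in = neg_counts >= threshold
    both = pos_in & neg_in
    pos_in = pos_in & (~both | (pos_counts > neg_counts))
    neg_in = neg_in & (~both | (neg_counts > pos_counts))
    return OverlapNetwork(positive_edges=np.where(pos_in)[0],
                          negative_edges=np.where(neg_in)[0],
                          n_nodes=n_nodes, min_fraction=min_fraction,
                          n_mask_sets=n_sets, provenance=list(provenance))


def node_degree_table(net: OverlapNetwork, top_k: int | None = None,
                      coords: Mapping[int, tuple] | None = None) -> pd.DataFrame:
    """Hub table: per-node degree over the retained edges, descending.

    Ties are broken by node index.  If a node-metadata mapping
    ``coords`` (node index → (x, y, z)) is given, coordinate columns are
    added; otherwise the table is degree-only.
    """
    deg = net.degrees()
    nodes = np.where(deg > 0)[0]
    table = pd.DataFrame({"node": nodes, "degree": deg[nodes]})
    table = table.sort_values(["degree", "node"],
                              ascending=[False, True]).reset_index(drop=True)
    if coords is not None:
        table[["x", "y", "z"]] = [coords.get(int(n), (np.nan,) * 3)
                                  for n in table["node"]]
    if top_k is not None:
        table = table.head(top_k)
    return table


def apply_fixed_network(net: OverlapNetwork, a: float, b: float, c: float,
                        cohort_edges: np.ndarray,
                        observed_scores: np.ndarray) -> PredictionResult:
    """Apply a fixed motion-sensitive network and bilinear coefficients to
    a new cohort's edges.

    Per subject X is the sum of edge z over the network's positive edges
    and Y over its negative edges; Ψ̂ = a + bX + cY.  Accuracy is computed
    against the supplied observed scores.  Constant predictions (e.g.
    b = c = 0) yield a flagged invalid result.
    """
    cohort_edges = np.asarray(cohort_edges, dtype=float)
    observed_scores = np.asarray(observed_scores, dtype=float)
    n_edges_expected = net.n_nodes * (net.n_nodes - 1) // 2
    if cohort_edges.ndim != 2 or cohort_edges.shape[1] != n_edges_expected:
        raise DimensionError(
            f"cohort edges have {cohort_edges.shape[-1]} columns; network "
            f"expects {n_edges_expected}")
    X = cohort_edges[:, net.positive_edges].sum(axis=1)
    Y = cohort_edges[:, net.negative_edges].sum(axis=1)
    predicted = a + b * X + c * Y
    if np.ptp(predicted) == 0:
        return PredictionResult(observed=observed_scores, predicted=predicted,
                                pearson_r=float("nan"),
                                pearson_p=float("nan"),
                                spearman_rho=float("nan"),
                                n=observed_scores.shape[0], valid=False)
    return accuracy(observed_scores, predicted)
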