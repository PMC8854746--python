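"""Typed heterogeneous networks and the train/test splitting protocol.

The dataset of labelled lncRNA-protein pairs is split 9:1 into train and
test, independently re-drawn a configurable number of times (three by
default), stratified by class so both partitions keep the positive:negative
balance. Each assembled network merges the *training* interaction edges with
optional same-type similarity graphs; test interactions are never present,
so no downstream stage can leak held-out labels.

Network variants mirror the published ablation: KNet (interactions only),
KJNet (+ Jaccard similarities), KBNet (+ alignment similarities). The full
model embeds KJNet and KBNet independently and splices the vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io_formats import EdgeRecord, ValidationError
from .similarity import NODE_LNC, NODE_PROT, SimilarityGraph

Pair = tuple[str, str]

EDGE_INTERACTION = "interaction"
EDGE_LNC_SIM = "lnc_sim"
EDGE_PROT_SIM = "prot_sim"

_MIN_CLASS_SIZE = 10


def _as_pair(item: EdgeRecord | Pair) -> Pair:
    return item.pair if isinstance(item, EdgeRecord) else (item[0], item[1])


@dataclass(frozen=True)
class RepeatSplit:
    """Train/test partition of positives and negatives for one repeat."""

    train_pos: tuple[Pair, ...]
    test_pos: tuple[Pair, ...]
    train_neg: tuple[Pair, ...]
    test_neg: tuple[Pair, ...]


@dataclass
class InteractionDataset:
    """Labelled pair set with per-repeat stratified train/test assignments."""

    positives: tuple[Pair, ...]
    negatives: tuple[Pair, ...]
    splits: list[RepeatSplit]
    ratio: float
    seed: int

    @property
    def repeats(self) -> int:
        return len(self.splits)

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValidationError("positives and negatives overlap")


def _partition(pairs: Sequence[Pair], ratio: float, rng: np.random.Generator) -> tuple[tuple[Pair, ...], tuple[Pair, ...]]:
    pairs = sorted(pairs)
    order = rng.permutation(len(pairs))
    n_train = int(round(len(pairs) * ratio))
    train = tuple(pairs[i] for i in sorted(order[:n_train]))
    test = tuple(pairs[i] for i in sorted(order[n_train:]))
    return train, test


def split_dataset(
    positives: Iterable[EdgeRecord | Pair],
    negatives: Iterable[EdgeRecord | Pair] = (),
    ratio: float = 0.9,
    repeats: int = 3,
    seed: int = 0,
) -> InteractionDataset:
    """Stratified random train/test splits, re-drawn independently per repeat.

    Deterministic given ``seed``. Negatives may be empty (they can be sampled
    and attached per repeat later); a non-empty class with fewer than 10
    pairs raises, as the split degenerates.
    """
    if not 0.0 < ratio < 1.0:
        raise ValidationError(f"split ratio {ratio} outside (0, 1)")
    if repeats < 1:
        raise ValidationError(f"repeats must be >= 1, got {repeats}")
    pos = tuple(dict.fromkeys(_as_pair(x) for x in positives))
    neg = tuple(dict.fromkeys(_as_pair(x) for x in negatives))
    if len(pos) < _MIN_CLASS_SIZE:
        raise ValidationError(f"need >= {_MIN_CLASS_SIZE} positives to split, got {len(pos)}")
    if neg and len(neg) < _MIN_CLASS_SIZE:
        raise ValidationError(f"need >= {_MIN_CLASS_SIZE} negatives to split, got {len(neg)}")
    splits = []
    for r in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        train_pos, test_pos = _partition(pos, ratio, rng)
        train_neg, test_neg = _partition(neg, ratio, rng) if neg else ((), ())
        splits.append(RepeatSplit(train_pos, test_pos, train_neg, test_neg))
    return InteractionDataset(positives=pos, negatives=neg, splits=splits, ratio=ratio, seed=seed)


@dataclass
class HeteroNetwork:
    """Typed graph of lncRNA/protein nodes with interaction and similarity edges."""

    graph: nx.Graph
    variant: str
    _typed_adj: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, t in self.graph.nodes(data="ntype") if t == node_type)

    def node_type(self, node: str) -> str:
        return self.graph.nodes[node]["ntype"]

    def edges_of_type(self, edge_type: str) -> list[tuple[str, str]]:
        return [
            tuple(sorted((u, v)))
            for u, v, t in self.graph.edges(data="etype")
            if t == edge_type
        ]

    def typed_neighbors(self, node: str, node_type: str) -> np.ndarray:
        """Neighbors of ``node`` with the requested type, as a sorted array.

        Edge typing is implied by endpoint types (lncRNA-protein edges are
        interactions, same-type edges are similarities), so the type filter
        alone enforces metapath edge admissibility.
        """
        key = (node, node_type)
        cached = self._typed_adj.get(key)
        if cached is None:
            hits = sorted(
                nb for nb in self.graph.neighbors(node)
                if self.graph.nodes[nb]["ntype"] == node_type
            )
            cached = np.array(hits, dtype=object)
            self._typed_adj[key] = cached
        return cached


def _infer_variant(lnc_sim: SimilarityGraph | None, prot_sim: SimilarityGraph | None) -> str:
    provs = {g.provenance for g in (lnc_sim, prot_sim) if g is not None and len(g)}
    if not provs:
        return "KNet"
    if provs == {"jaccard"}:
        return "KJNet"
    if provs == {"alignment"}:
        return "KBNet"
    return "mixed"


def assemble_network(
    train_interactions: Iterable[EdgeRecord | Pair],
    lnc_sim: SimilarityGraph | None = None,
    prot_sim: SimilarityGraph | None = None,
    extra_lnc: Iterable[str] = (),
    extra_prot: Iterable[str] = (),
) -> HeteroNetwork:
    """Merge training interactions with optional similarity graphs.

    ``extra_lnc`` / ``extra_prot`` register additional (possibly isolated)
    nodes — e.g. the endpoints of held-out test pairs — so they stay part of
    the network and receive fallback embeddings instead of being silently
    dropped. A similarity edge touching a node of the wrong type raises.
    """
    g = nx.Graph()
    for node in extra_lnc:
        g.add_node(node, ntype=NODE_LNC)
    for node in extra_prot:
        g.add_node(node, ntype=NODE_PROT)
    for item in train_interactions:
        l, p = _as_pair(item)
        if g.nodes.get(l, {}).get("ntype", NODE_LNC) != NODE_LNC:
            raise ValidationError(f"node {l!r} used as both lncRNA and protein")
        if g.nodes.get(p, {}).get("ntype", NODE_PROT) != NODE_PROT:
            raise ValidationError(f"node {p!r} used as both lncRNA and protein")
        g.add_node(l, ntype=NODE_LNC)
        g.add_node(p, ntype=NODE_PROT)
        g.add_edge(l, p, etype=EDGE_INTERACTION, weight=1.0)
    for sim, expected_type, etype in (
        (lnc_sim, NODE_LNC, EDGE_LNC_SIM),
        (prot_sim, NODE_PROT, EDGE_PROT_SIM),
    ):
        if sim is None:
            continue
        if sim.node_type != expected_type:
            raise ValidationError(
                f"similarity graph of type {sim.node_type!r} passed where {expected_type!r} expected"
            )
        for node in sim.nodes:
            current = g.nodes.get(node, {}).get("ntype")
            if current is not None and current != expected_type:
                raise ValidationError(
                    f"similarity edge endpoint {node!r} has mismatched type {current!r}"
                )
            g.add_node(node, ntype=expected_type)
        for u, v, w in sim.edge_pairs():
            g.add_edge(u, v, etype=etype, weight=w)
    return HeteroNetwork(graph=g, variant=_infer_variant(lnc_sim, prot_sim))
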