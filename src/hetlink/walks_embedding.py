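"""Metapath-constrained random walks, skip-gram node embeddings, and pair features.

A metapath scheme is an ordered node-type sequence such as L-P-L-P-L. At
walk step i the walker moves to a uniformly chosen neighbor of the required
type: p(v_{i+1} | v_i) = 1/|N_t(v_i)| over neighbors of type t, 0 elsewhere.
Because interaction edges always join an lncRNA to a protein and similarity
edges join same-type nodes, the type constraint alone decides which edge
kind each step may traverse (L->P / P->L steps use interactions, L->L and
P->P steps use similarity edges). Schemes whose first and last types match
are cycled so walks can be much longer than the literal scheme.

Walk corpora are fed to a skip-gram model with negative sampling (SGNS),
trained by a numba-compiled SGD kernel with the standard word2vec update
rule: unigram^0.75 negative-sampling distribution, reduced context windows,
linearly decaying learning rate. Each heterogeneous network yields one
64-dimensional vector per node; the vectors from the two networks are
spliced to 128 per node, and a candidate (lncRNA, protein) pair is
represented by the 256-dimensional concatenation of its endpoint vectors.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from .heteronet import HeteroNetwork, Pair
from .io_formats import ValidationError
from .similarity import NODE_LNC, NODE_PROT

logger = logging.getLogger("hetlink")

_VALID_TYPES = {NODE_LNC, NODE_PROT}


@dataclass(frozen=True)
class MetaPathScheme:
    """An ordered node-type sequence constraining admissible walk steps."""

    name: str
    types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.types) < 2:
            raise ValidationError(f"scheme {self.name!r} shorter than 2 types")
        if self.types[0] != self.types[-1]:
            raise ValidationError(
                f"scheme {self.name!r} must start and end on the same type to be cyclable"
            )
        if not set(self.types) <= _VALID_TYPES:
            raise ValidationError(f"scheme {self.name!r} has unknown node types")

    @classmethod
    def from_string(cls, spec: str) -> "MetaPathScheme":
        return cls(name=spec, types=tuple(spec))

    def type_at(self, position: int) -> str:
        """Node type required at walk position ``position`` (scheme cycled)."""
        return self.types[position % (len(self.types) - 1)]


DEFAULT_SCHEMES = (MetaPathScheme.from_string("LPLPL"), MetaPathScheme.from_string("LLPPLL"))


@dataclass
class WalkCorpus:
    """Walks of (node id, node type) pairs plus generation metadata."""

    walks: list[list[tuple[str, str]]]
    scheme_names: tuple[str, ...]
    walks_per_node: int
    walk_length: int
    seed: int

    def __len__(self) -> int:
        return len(self.walks)

    def token_walks(self) -> list[list[str]]:
        return [[node for node, _ in walk] for walk in self.walks]

    def bigrams(self) -> set[frozenset]:
        out: set[frozenset] = set()
        for walk in self.walks:
            for (u, _), (v, _) in zip(walk, walk[1:]):
                out.add(frozenset((u, v)))
        return out

    def assert_excludes(self, forbidden_pairs: Iterable[Pair]) -> None:
        """Leak check: no walk bigram may correspond to a held-out pair."""
        forbidden = {frozenset(p) for p in forbidden_pairs}
        hit = self.bigrams() & forbidden
        if hit:
            raise ValidationError(f"walk corpus traverses held-out pairs: {sorted(map(sorted, hit))[:3]}")

    def write_text(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for walk in self.walks:
                fh.write(" ".join(node for node, _ in walk) + "\n")

    @staticmethod
    def merge(corpora: Sequence["WalkCorpus"]) -> "WalkCorpus":
        if not corpora:
            raise ValidationError("cannot merge zero corpora")
        return WalkCorpus(
            walks=[w for c in corpora for w in c.walks],
            scheme_names=tuple(n for c in corpora for n in c.scheme_names),
            walks_per_node=corpora[0].walks_per_node,
            walk_length=corpora[0].walk_length,
            seed=corpora[0].seed,
        )


def transition_distribution(
    network: HeteroNetwork, current: str, required_type: str
) -> dict[str, float]:
    """Uniform next-step distribution over neighbors of the required type.

    Returns an empty map when no admissible neighbor exists (a dead end).
    """
    if current not in network.graph:
        raise ValidationError(f"node {current!r} not in network")
    neighbors = network.typed_neighbors(current, required_type)
    if len(neighbors) == 0:
        return {}
    p = 1.0 / len(neighbors)
    return {str(nb): p for nb in neighbors}


def generate_walks(
    network: HeteroNetwork,
    scheme: MetaPathScheme,
    walks_per_node: int = 10,
    walk_length: int = 80,
    seed: int = 0,
) -> WalkCorpus:
    """Metapath-constrained random walks from every node of the start type.

    Walks truncate at dead ends; truncated walks shorter than 2 nodes are
    discarded (skip-gram needs at least one context pair). Deterministic
    given ``seed``.
    """
    if walk_length < len(scheme.types):
        raise ValidationError(
            f"walk_length {walk_length} shorter than scheme {scheme.name!r}"
        )
    starts = network.nodes_of_type(scheme.types[0])
    if not starts:
        raise ValidationError(f"no nodes of start type {scheme.types[0]!r} in network")
    scheme_key = zlib.crc32(scheme.name.encode())  # stable across processes
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(scheme_key,)))
    walks: list[list[tuple[str, str]]] = []
    n_discarded = 0
    for start in starts:
        for _ in range(walks_per_node):
            walk = [(start, scheme.types[0])]
            current = start
            for pos in range(1, walk_length):
                required = scheme.type_at(pos)
                neighbors = network.typed_neighbors(current, required)
                if len(neighbors) == 0:
                    break
                current = neighbors[rng.integers(len(neighbors))]
                walk.append((current, required))
            if len(walk) >= 2:
                walks.append(walk)
            else:
                n_discarded += 1
    if n_discarded:
        logger.info(
            "generate_walks(%s): discarded %d immediately dead-ended walks",
            scheme.name, n_discarded,
        )
    return WalkCorpus(
        walks=walks,
        scheme_names=(scheme.name,),
        walks_per_node=walks_per_node,
        walk_length=walk_length,
        seed=seed,
    )


# --- skip-gram with negative sampling -------------------------------------

_MAX_EXP = 6.0


@njit(cache=True)
def _sgns_update(centers, contexts, negatives, syn0, syn1, lr_start, lr_end):  # pragma: no cover
    n_pairs = centers.shape[0]
    dim = syn0.shape[1]
    k = negatives.shape[1]
    neu1e = np.empty(dim, dtype=np.float32)
    for idx in range(n_pairs):
        lr = lr_start + (lr_end - lr_start) * (idx / n_pairs)
        c = centers[idx]
        o = contexts[idx]
        for d in range(dim):
            neu1e[d] = 0.0
        for t in range(k + 1):
            if t == 0:
                target = o
                label = 1.0
            else:
                target = negatives[idx, t - 1]
                if target == o:
                    continue
                label = 0.0
            f = 0.0
            for d in range(dim):
                f += syn0[c, d] * syn1[target, d]
            if f > _MAX_EXP:
                sig = 1.0
            elif f < -_MAX_EXP:
                sig = 0.0
            else:
                sig = 1.0 / (1.0 + np.exp(-f))
            g = (label - sig) * lr
            for d in range(dim):
                neu1e[d] += g * syn1[target, d]
            for d in range(dim):
                syn1[target, d] += g * syn0[c, d]
        for d in range(dim):
            syn0[c, d] += neu1e[d]


def _static_pairs(encoded: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (center, context) pairs within the full window, with their offsets."""
    centers, contexts, dists = [], [], []
    # pad walks with -1 sentinels so offsets never cross walk boundaries
    flat = np.concatenate([np.concatenate((w, [-1] * window)) for w in encoded]).astype(np.int32)
    for d in range(1, window + 1):
        a, b = flat[:-d], flat[d:]
        ok = (a >= 0) & (b >= 0)
        centers.append(a[ok]); contexts.append(b[ok]); dists.append(np.full(ok.sum(), d, dtype=np.int32))
        centers.append(b[ok]); contexts.append(a[ok]); dists.append(np.full(ok.sum(), d, dtype=np.int32))
    return np.concatenate(centers), np.concatenate(contexts), np.concatenate(dists)


def train_embeddings(
    corpus: WalkCorpus,
    dim: int = 64,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    all_nodes: Iterable[str] = (),
) -> dict[str, np.ndarray]:
    """Train SGNS embeddings on the walk corpus; one ``dim``-vector per node.

    Context windows are reduced stochastically as in word2vec: a pair at
    offset d enters an epoch with probability (window - d + 1) / window.
    Negative samples follow the unigram^0.75 distribution. Nodes listed in
    ``all_nodes`` but absent from every walk receive the zero vector (logged).
    Deterministic given ``seed`` (single-threaded kernel).
    """
    if dim < 2:
        raise ValidationError(f"embedding dim must be >= 2, got {dim}")
    token_walks = corpus.token_walks()
    if not token_walks:
        raise ValidationError("cannot train embeddings on an empty corpus")
    counts: dict[str, int] = {}
    for walk in token_walks:
        for tok in walk:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(counts, key=lambda t: (-counts[t], t))
    index = {tok: i for i, tok in enumerate(vocab)}
    encoded = [np.array([index[t] for t in walk], dtype=np.int32) for walk in token_walks]

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    n_vocab = len(vocab)
    syn0 = ((rng.random((n_vocab, dim), dtype=np.float32) - 0.5) / dim).astype(np.float32)
    syn1 = np.zeros((n_vocab, dim), dtype=np.float32)

    freq = np.array([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    cum = np.cumsum(freq / freq.sum())

    centers_all, contexts_all, dists_all = _static_pairs(encoded, window)
    keep_prob = (window - dists_all + 1) / window
    for epoch in range(epochs):
        keep = rng.random(len(centers_all)) < keep_prob
        centers = centers_all[keep]
        contexts = contexts_all[keep]
        order = rng.permutation(len(centers))
        centers = np.ascontiguousarray(centers[order])
        contexts = np.ascontiguousarray(contexts[order])
        negs = np.searchsorted(cum, rng.random((len(centers), negative))).astype(np.int32)
        lr_hi = alpha - (alpha - min_alpha) * (epoch / epochs)
        lr_lo = alpha - (alpha - min_alpha) * ((epoch + 1) / epochs)
        _sgns_update(centers, contexts, negs, syn0, syn1, lr_hi, lr_lo)

    out = {tok: syn0[i].copy() for tok, i in index.items()}
    missing = [n for n in all_nodes if n not in out]
    for node in missing:
        out[node] = np.zeros(dim, dtype=np.float32)
    if missing:
        logger.info("train_embeddings: %d nodes absent from walks got zero vectors", len(missing))
    return out


def splice_node_features(
    emb_kjnet: Mapping[str, np.ndarray], emb_kbnet: Mapping[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Concatenate per-network vectors (Jaccard-network half first).

    A node missing from one network contributes a zero block for that half.
    """
    dims = set()
    for emb in (emb_kjnet, emb_kbnet):
        dims.update(len(v) for v in emb.values())
    if len(dims) > 1:
        raise ValidationError(f"embedding dimension mismatch: {sorted(dims)}")
    if not dims:
        raise ValidationError("both embedding maps are empty")
    d = dims.pop()
    zero = np.zeros(d, dtype=np.float32)
    out: dict[str, np.ndarray] = {}
    for node in sorted(set(emb_kjnet) | set(emb_kbnet)):
        left = np.asarray(emb_kjnet.get(node, zero), dtype=np.float32)
        right = np.asarray(emb_kbnet.get(node, zero), dtype=np.float32)
        out[node] = np.concatenate((left, right))
    return out


@dataclass
class PairFeatureSet:
    """Per-pair feature vectors ([lncRNA vec || protein vec]) with optional labels."""

    pairs: tuple[Pair, ...]
    features: np.ndarray  # shape (n_pairs, feature_dim)
    labels: np.ndarray | None = None  # binary, shape (n_pairs,)
    partition: str = ""

    def __post_init__(self) -> None:
        if self.features.ndim != 2 or self.features.shape[0] != len(self.pairs):
            raise ValidationError("feature matrix shape does not match pair list")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (len(self.pairs),):
                raise ValidationError("label vector shape does not match pair list")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValidationError("labels must be binary")

    @property
    def dim(self) -> int:
        return self.features.shape[1]


def pair_features(
    node_feats: Mapping[str, np.ndarray],
    pairs: Sequence[Pair],
    labels: Sequence[int] | None = None,
    partition: str = "",
) -> PairFeatureSet:
    """Concatenate endpoint vectors per (lncRNA, protein) pair."""
    rows = []
    for l, p in pairs:
        if l not in node_feats:
            raise ValidationError(f"no node features for lncRNA {l!r} in pair ({l}, {p})")
        if p not in node_feats:
            raise ValidationError(f"no node features for protein {p!r} in pair ({l}, {p})")
        rows.append(np.concatenate((node_feats[l], node_feats[p])))
    features = np.vstack(rows) if rows else np.empty((0, 0), dtype=np.float32)
    return PairFeatureSet(
        pairs=tuple((l, p) for l, p in pairs),
        features=features,
        labels=None if labels is None else np.asarray(labels),
        partition=partition,
    )
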