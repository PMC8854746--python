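"""Jaccard and alignment-based similarity graphs over one node type.

Two lncRNAs (or proteins) are compared through their association sets: the
Jaccard index J(A, B) = |A ∩ B| / |A ∪ B| between the sets of partners they
interact with. Association sets are built from *training-partition*
interactions only, so that similarity edges cannot leak held-out test pairs
into the network. Alignment similarities come from BLAST tabular output; an
edge is kept when the best e-value in either query/subject orientation beats
the cutoff.

Edge thresholds follow the published construction: lncRNA-lncRNA Jaccard
edges require similarity strictly greater than 0.5, protein-protein Jaccard
edges strictly greater than 0; lncRNA alignment edges require e-value
strictly below 1e-3, protein alignment edges strictly below 1e-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import AbstractSet, Iterable, Mapping

from .io_formats import AlignmentHit, EdgeRecord, ParseError, ValidationError

NODE_LNC = "L"
NODE_PROT = "P"

#: -log10 weight assigned to an e-value of exactly zero.
EVALUE_LOG_CAP = 300.0

DEFAULT_JACCARD_THRESHOLD = {NODE_LNC: 0.5, NODE_PROT: 0.0}
DEFAULT_EVALUE_CUTOFF = {NODE_LNC: 1e-3, NODE_PROT: 1e-2}


@dataclass(frozen=True)
class AssociationSets:
    """Partner sets per molecule, built from training interactions only.

    ``lnc_partners[l]`` is the set of proteins known to interact with lncRNA
    ``l``; ``prot_partners[p]`` the converse. Membership is symmetric across
    the two maps by construction.
    """

    lnc_partners: Mapping[str, frozenset[str]]
    prot_partners: Mapping[str, frozenset[str]]

    @classmethod
    def from_interactions(cls, interactions: Iterable[EdgeRecord | tuple[str, str]]) -> "AssociationSets":
        lnc: dict[str, set[str]] = {}
        prot: dict[str, set[str]] = {}
        for item in interactions:
            l, p = item.pair if isinstance(item, EdgeRecord) else item
            lnc.setdefault(l, set()).add(p)
            prot.setdefault(p, set()).add(l)
        return cls(
            lnc_partners={k: frozenset(v) for k, v in lnc.items()},
            prot_partners={k: frozenset(v) for k, v in prot.items()},
        )

    def sets_for(self, node_type: str) -> Mapping[str, frozenset[str]]:
        if node_type == NODE_LNC:
            return self.lnc_partners
        if node_type == NODE_PROT:
            return self.prot_partners
        raise ValidationError(f"unknown node type {node_type!r}")


@dataclass
class SimilarityGraph:
    """Undirected weighted similarity edges over a single node type."""

    node_type: str
    provenance: str  # "jaccard" | "alignment"
    edges: dict[frozenset, float] = field(default_factory=dict)
    nodes: set[str] = field(default_factory=set)

    def add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            raise ValidationError(f"self-loop on {u!r}")
        self.nodes.update((u, v))
        self.edges[frozenset((u, v))] = weight

    def edge_pairs(self) -> list[tuple[str, str, float]]:
        out = [(*sorted(key), w) for key, w in self.edges.items()]
        out.sort()
        return out

    def __len__(self) -> int:
        return len(self.edges)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for u, v, w in self.edge_pairs():
                fh.write(f"{u}\t{v}\t{w:.6g}\t{self.provenance}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, node_type: str) -> "SimilarityGraph":
        path = Path(path)
        graph = None
        with path.open() as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ParseError(f"{path}:{lineno}: expected (u, v, weight, provenance)")
                if graph is None:
                    graph = cls(node_type=node_type, provenance=fields[3])
                graph.add_edge(fields[0], fields[1], float(fields[2]))
        return graph if graph is not None else cls(node_type=node_type, provenance="jaccard")


def jaccard(a: AbstractSet[str], b: AbstractSet[str]) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b|; defined as 0 when both sets are empty."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def build_jaccard_graph(
    assoc: AssociationSets,
    node_type: str,
    threshold: float | None = None,
    strict: bool = True,
) -> SimilarityGraph:
    """Connect nodes whose association-set Jaccard similarity exceeds ``threshold``.

    The published rule is a strict inequality ("more than"); ``strict=False``
    relaxes it to >=. Defaults: 0.5 for lncRNAs, 0 for proteins.
    """
    sets = assoc.sets_for(node_type)
    if threshold is None:
        threshold = DEFAULT_JACCARD_THRESHOLD[node_type]
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"jaccard threshold {threshold} outside [0, 1]")
    graph = SimilarityGraph(node_type=node_type, provenance="jaccard")
    graph.nodes.update(sets)
    for u, v in combinations(sorted(sets), 2):
        sim = jaccard(sets[u], sets[v])
        if (sim > threshold) if strict else (sim >= threshold):
            graph.add_edge(u, v, sim)
    return graph


def build_alignment_graph(
    hits: Iterable[AlignmentHit],
    node_type: str,
    evalue_cutoff: float | None = None,
    orientation: str = "either",
    known_ids: AbstractSet[str] | None = None,
) -> SimilarityGraph:
    """Connect nodes whose best alignment e-value beats ``evalue_cutoff`` (strict <).

    ``orientation`` resolves asymmetric query/subject hits: ``"either"`` keeps
    the edge if the minimum e-value over both orientations passes (default),
    ``"both"`` requires the maximum to pass (max-stringency). The edge weight
    is -log10 of the best e-value, capped at 300 so an e-value of exactly zero
    stays finite. Defaults: cutoff 1e-3 for lncRNAs, 1e-2 for proteins.
    """
    if evalue_cutoff is None:
        evalue_cutoff = DEFAULT_EVALUE_CUTOFF[node_type]
    if evalue_cutoff <= 0:
        raise ValidationError(f"e-value cutoff must be positive, got {evalue_cutoff}")
    if orientation not in ("either", "both"):
        raise ValidationError(f"unknown orientation rule {orientation!r}")
    per_pair: dict[frozenset, list[float]] = {}
    for hit in hits:
        if known_ids is not None:
            for node in (hit.query_id, hit.subject_id):
                if node not in known_ids:
                    raise ValidationError(
                        f"alignment hit node {node!r} is not a known {node_type} id"
                    )
        per_pair.setdefault(frozenset((hit.query_id, hit.subject_id)), []).append(hit.evalue)
    graph = SimilarityGraph(node_type=node_type, provenance="alignment")
    for key, evalues in sorted(per_pair.items(), key=lambda kv: sorted(kv[0])):
        decisive = min(evalues) if orientation == "either" else max(evalues)
        if decisive < evalue_cutoff:
            best = min(evalues)
            weight = EVALUE_LOG_CAP if best == 0.0 else min(-math.log10(best), EVALUE_LOG_CAP)
            u, v = sorted(key)
            graph.add_edge(u, v, weight)
    return graph
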