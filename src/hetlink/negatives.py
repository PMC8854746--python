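"""Negative-sample generation: random pairing, subcellular incompatibility, network distance.

Known interactions give only positive examples; class-0 training pairs must
be constructed. Three strategies are provided:

* ``random`` — uniform sample of non-interacting (lncRNA, protein) pairs;
* ``subcellular`` — pairs whose compartment annotation sets are disjoint
  (molecules that never share a cellular compartment cannot interact);
* ``distance`` — pairs far apart in the prior interaction network, measured
  by unweighted shortest-path distance on the *training* positives only
  (test edges would leak labels into the negative set). In a bipartite
  interaction graph every finite lncRNA-protein distance is odd; distance 1
  means a known interaction, so all variants require distance > 1. The
  published variants are Distance_3 (d == 3), Distance_5 (1 < d <= 5) and
  Distance_7 (1 < d <= 7); unreachable pairs (d = infinite) qualify only for
  the explicit ``distance_inf`` strategy.

Every strategy returns exactly ``count`` pairs, disjoint from the positives,
with no duplicates, deterministically for a given seed. The negative set
size defaults to the positive set size to keep the classifier balanced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .heteronet import Pair
from .io_formats import ValidationError


@dataclass(frozen=True)
class NegativeSpec:
    """Parameters of one negative-sampling run."""

    strategy: str  # "random" | "subcellular" | "distance" | "distance_inf"
    count: int
    seed: int
    distance_min: int | None = None
    distance_max: int | None = None

    def __post_init__(self) -> None:
        if self.count <= 0:
            raise ValidationError(f"negative count must be positive, got {self.count}")
        if self.strategy not in ("random", "subcellular", "distance", "distance_inf"):
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "distance":
            if self.distance_min is None or self.distance_max is None:
                raise ValidationError("distance strategy needs distance_min and distance_max")
            if self.distance_min <= 1:
                raise ValidationError("distance_min must exceed 1 (distance 1 is a positive)")
            if self.distance_max < self.distance_min:
                raise ValidationError("distance_max below distance_min")

    @classmethod
    def distance_3(cls, count: int, seed: int) -> "NegativeSpec":
        return cls("distance", count, seed, distance_min=3, distance_max=3)

    @classmethod
    def distance_5(cls, count: int, seed: int) -> "NegativeSpec":
        return cls("distance", count, seed, distance_min=2, distance_max=5)

    @classmethod
    def distance_7(cls, count: int, seed: int) -> "NegativeSpec":
        return cls("distance", count, seed, distance_min=2, distance_max=7)


def _draw(candidates: Sequence[Pair], count: int, seed: int) -> set[Pair]:
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    chosen = rng.choice(len(candidates), size=count, replace=False)
    return {candidates[i] for i in chosen}


def sample_random(
    lncRNAs: Iterable[str],
    proteins: Iterable[str],
    positives: Iterable[Pair],
    count: int,
    seed: int,
) -> set[Pair]:
    """Uniform sample without replacement from all non-positive pairs."""
    lncs, prots = sorted(set(lncRNAs)), sorted(set(proteins))
    pos = set(positives)
    candidates = [(l, p) for l in lncs for p in prots if (l, p) not in pos]
    if count > len(candidates):
        raise ValidationError(
            f"requested {count} negatives but only {len(candidates)} non-positive pairs exist"
        )
    return _draw(candidates, count, seed)


def compartment_disjoint(
    localization: Mapping[str, set[str]], molecule_a: str, molecule_b: str
) -> bool:
    """True when the two molecules share no annotated compartment."""
    return not (localization[molecule_a] & localization[molecule_b])


def sample_subcellular(
    localization: Mapping[str, set[str]],
    lncRNAs: Iterable[str],
    proteins: Iterable[str],
    positives: Iterable[Pair],
    count: int,
    seed: int,
) -> set[Pair]:
    """Uniform sample of compartment-disjoint, non-positive pairs."""
    lncs, prots = sorted(set(lncRNAs)), sorted(set(proteins))
    missing = [m for m in lncs + prots if m not in localization]
    if missing:
        raise ValidationError(f"no localization annotation for {missing[:5]!r}...")
    pos = set(positives)
    candidates = [
        (l, p)
        for l in lncs
        for p in prots
        if (l, p) not in pos and compartment_disjoint(localization, l, p)
    ]
    if count > len(candidates):
        n_pairs = len(lncs) * len(prots)
        raise ValidationError(
            f"requested {count} subcellular negatives but only {len(candidates)} "
            f"compartment-disjoint non-positive pairs exist "
            f"({n_pairs} total pairs, {len(pos)} positives)"
        )
    return _draw(candidates, count, seed)


def interaction_distances(
    train_positives: Iterable[Pair],
    lncRNAs: Iterable[str],
    proteins: Iterable[str],
) -> dict[Pair, float]:
    """Shortest-path distance for every (lncRNA, protein) pair in the prior network.

    The prior network contains training interaction edges only; pairs in
    different components get ``math.inf``.
    """
    lncs, prots = sorted(set(lncRNAs)), sorted(set(proteins))
    g = nx.Graph()
    g.add_nodes_from(lncs)
    g.add_nodes_from(prots)
    g.add_edges_from(train_positives)
    out: dict[Pair, float] = {}
    for l in lncs:
        reach = nx.single_source_shortest_path_length(g, l)
        for p in prots:
            out[(l, p)] = float(reach[p]) if p in reach else math.inf
    return out


def distance_candidates(
    distances: Mapping[Pair, float], spec: NegativeSpec
) -> list[Pair]:
    if spec.strategy == "distance_inf":
        return sorted(p for p, d in distances.items() if d > 1)
    return sorted(
        p for p, d in distances.items()
        if math.isfinite(d) and spec.distance_min <= d <= spec.distance_max
    )


def sample_by_distance(
    train_positives: Iterable[Pair],
    lncRNAs: Iterable[str],
    proteins: Iterable[str],
    spec: NegativeSpec,
    exclude: Iterable[Pair] = (),
) -> set[Pair]:
    """Uniform sample of pairs whose prior-network distance lies in the spec bounds.

    Distances come from the prior (training) interaction network, so a
    held-out positive pair may sit at an eligible distance; ``exclude``
    removes such known pairs from the candidate set before drawing.
    """
    if spec.strategy not in ("distance", "distance_inf"):
        raise ValidationError(f"spec strategy {spec.strategy!r} is not distance-based")
    distances = interaction_distances(train_positives, lncRNAs, proteins)
    excluded = set(exclude)
    candidates = [p for p in distance_candidates(distances, spec) if p not in excluded]
    if spec.count > len(candidates):
        census: dict[str, int] = {}
        for d in distances.values():
            key = "inf" if math.isinf(d) else str(int(d))
            census[key] = census.get(key, 0) + 1
        raise ValidationError(
            f"requested {spec.count} distance negatives but only {len(candidates)} candidates "
            f"satisfy {spec.distance_min}<=d<={spec.distance_max}; distance census: {census}"
        )
    return _draw(candidates, spec.count, spec.seed)


def sample_negatives(
    spec: NegativeSpec,
    lncRNAs: Iterable[str],
    proteins: Iterable[str],
    positives: Iterable[Pair],
    localization: Mapping[str, set[str]] | None = None,
    train_positives: Iterable[Pair] | None = None,
) -> set[Pair]:
    """Dispatch to the configured strategy; all strategies exclude positives."""
    positives = set(positives)
    if spec.strategy == "random":
        out = sample_random(lncRNAs, proteins, positives, spec.count, spec.seed)
    elif spec.strategy == "subcellular":
        if localization is None:
            raise ValidationError("subcellular strategy needs a localization table")
        out = sample_subcellular(localization, lncRNAs, proteins, positives, spec.count, spec.seed)
    else:
        prior = positives if train_positives is None else train_positives
        out = sample_by_distance(prior, lncRNAs, proteins, spec, exclude=positives)
    return out
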