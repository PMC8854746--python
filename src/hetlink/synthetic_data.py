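"""Planted-structure synthetic fixtures for every pipeline stage.

The generator emulates the statistical structure the method assumes: a
block-modular bipartite interaction network (lncRNAs and proteins sharing a
latent block interact with probability ``p_within``, others with
``p_between``), similarity tables concentrated within blocks, and a
localization table in which each block is one cellular compartment — so
cross-block pairs are compartment-disjoint, mirroring the assumption behind
subcellular negative sampling. Sequences per block descend from one random
ancestor by point mutation, so within-block alignment similarity exceeds
between-block similarity.

All outputs are deterministic given the spec seed and round-trip through
:mod:`hetlink.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import AlignmentHit, EdgeRecord, ValidationError


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Parameters of the planted-block benchmark network."""

    n_lnc: int = 150
    n_prot: int = 30
    k_blocks: int = 3
    p_within: float = 0.6
    p_between: float = 0.02
    sim_noise: float = 0.05  # chance a similarity edge is flipped across/within blocks
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_between < self.p_within <= 1.0):
            raise ValidationError(
                f"need 0 <= p_between < p_within <= 1, got {self.p_between}, {self.p_within}"
            )
        if self.k_blocks < 1 or self.k_blocks > min(self.n_lnc, self.n_prot):
            raise ValidationError(
                f"k_blocks {self.k_blocks} outside [1, min(n_lnc, n_prot)]"
            )
        if not 0.0 <= self.sim_noise <= 1.0:
            raise ValidationError(f"sim_noise {self.sim_noise} outside [0, 1]")


@dataclass
class PlantedNetwork:
    """One generated fixture: labelled interactions plus consistent side data."""

    spec: PlantedNetworkSpec
    interactions: list[EdgeRecord]
    lnc_hits: list[AlignmentHit]
    prot_hits: list[AlignmentHit]
    localization: dict[str, set[str]]
    blocks: dict[str, int]  # ground-truth block per molecule id

    @property
    def lncRNAs(self) -> tuple[str, ...]:
        return tuple(m for m in sorted(self.blocks) if m.startswith("L"))

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(m for m in sorted(self.blocks) if m.startswith("P"))

    @property
    def positive_pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(rec.pair for rec in self.interactions)


def _similarity_hits(
    ids: Sequence[str],
    blocks: Mapping[str, int],
    sim_noise: float,
    rng: np.random.Generator,
) -> list[AlignmentHit]:
    """Synthetic alignment table: strong hits mostly within blocks.

    Present hits get an e-value drawn log-uniformly in [1e-50, 1e-5], which
    passes both published cutoffs; absent pairs simply emit no hit.
    """
    hits: list[AlignmentHit] = []
    for i, u in enumerate(ids):
        for v in ids[i + 1:]:
            same = blocks[u] == blocks[v]
            p_edge = (1.0 - sim_noise) if same else sim_noise
            if rng.random() < p_edge:
                log_e = rng.uniform(-50.0, -5.0)
                hits.append(AlignmentHit(u, v, 10.0 ** log_e, float(rng.uniform(50.0, 500.0))))
    return hits


def generate_planted_network(spec: PlantedNetworkSpec) -> PlantedNetwork:
    """Draw one planted-block fixture; raises if no positive interaction was drawn."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(42,)))
    lncs = [f"L{i:04d}" for i in range(spec.n_lnc)]
    prots = [f"P{i:04d}" for i in range(spec.n_prot)]
    blocks = {m: int(rng.integers(spec.k_blocks)) for m in lncs + prots}

    interactions: list[EdgeRecord] = []
    for l in lncs:
        for p in prots:
            prob = spec.p_within if blocks[l] == blocks[p] else spec.p_between
            if rng.random() < prob:
                interactions.append(EdgeRecord(l, p))
    if not interactions:
        raise ValidationError("spec produced an empty positive set")

    lnc_hits = _similarity_hits(lncs, blocks, spec.sim_noise, rng)
    prot_hits = _similarity_hits(prots, blocks, spec.sim_noise, rng)
    localization = {m: {f"compartment{blocks[m]}"} for m in lncs + prots}
    return PlantedNetwork(
        spec=spec,
        interactions=interactions,
        lnc_hits=lnc_hits,
        prot_hits=prot_hits,
        localization=localization,
        blocks=blocks,
    )


def generate_sequences(
    n: int,
    length: int,
    alphabet: str,
    block_assignment: Mapping[str, int] | Sequence[int],
    mutation_rate: float,
    seed: int,
) -> dict[str, str]:
    """Per-block ancestor sequences with point-mutated copies per member.

    ``block_assignment`` maps ids to blocks (or gives a block per index, in
    which case ids are ``S0000``...). Within-block pairwise identity exceeds
    between-block identity for mutation rates below 0.5.
    """
    if not 0.0 <= mutation_rate <= 0.5:
        raise ValidationError(f"mutation_rate {mutation_rate} outside [0, 0.5]")
    if isinstance(block_assignment, Mapping):
        assignment = dict(block_assignment)
    else:
        assignment = {f"S{i:04d}": int(b) for i, b in enumerate(block_assignment)}
    ids = sorted(assignment)[:n] if n < len(assignment) else sorted(assignment)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
    symbols = np.array(list(alphabet))
    ancestors = {
        b: rng.integers(len(symbols), size=length)
        for b in sorted(set(assignment.values()))
    }
    out: dict[str, str] = {}
    for name in ids:
        seq = ancestors[assignment[name]].copy()
        mutate = rng.random(length) < mutation_rate
        # mutated positions shift to a uniformly chosen *different* symbol
        shift = rng.integers(1, len(symbols), size=length)
        seq[mutate] = (seq[mutate] + shift[mutate]) % len(symbols)
        out[name] = "".join(symbols[seq])
    return out


def toy_alignment_hits(
    sequences: Mapping[str, str],
    baseline_identity: float = 0.25,
) -> list[AlignmentHit]:
    """Hamming-identity scorer emitting BLAST-like hits for equal-length sequences.

    A toy stand-in for a real aligner in tests: pairwise identity in excess
    of the random baseline maps onto a pseudo e-value, so clearly related
    sequences pass the pipeline's e-value cutoffs and unrelated ones do not.
    Synthetic by construction; not a sequence aligner.
    """
    ids = sorted(sequences)
    hits: list[AlignmentHit] = []
    for i, u in enumerate(ids):
        for v in ids[i + 1:]:
            a, b = sequences[u], sequences[v]
            if len(a) != len(b):
                raise ValidationError("toy scorer requires equal-length sequences")
            identity = sum(x == y for x, y in zip(a, b)) / len(a)
            excess = max(0.0, (identity - baseline_identity) / (1.0 - baseline_identity))
            evalue = 10.0 ** (2.0 - 40.0 * excess)
            hits.append(AlignmentHit(u, v, min(evalue, 100.0), 100.0 * excess))
    return hits
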