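"""Complex mining: seed-expand-merge over the PPI network.

Every PPI edge seeds a candidate complex. The neighbor pool of the seed
edge (the union of the two endpoints' neighbors) is collected once; each
round, every remaining pool node is tentatively added to the current
member set and the grown set scored by the classifier, and the best
neighbor is adopted when its score exceeds the threshold alpha. Adopted
nodes leave the pool and the pool is never re-expanded, so a candidate is
confined to the seed edge's neighborhood - which is what keeps expansion
from leaking across complex boundaries node by node. Candidates are then
deduplicated and merged: scanning in descending score order, a
lower-scoring candidate whose overlap with a retained one exceeds beta is
merged into it when the union scores higher than the retained candidate,
and is dropped otherwise. Only sets with more than 2 members are emitted.

The scorer is any callable mapping a member set to [0, 1]; in production
it wraps the trained DNN, and in tests it can be an oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

from .classifier import ComplexDNN, EmbeddingTable, score_complex
from .io import Complex, ComplexSet, InteractionNetwork
from .metrics import na_score

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionConfig",
    "make_scorer",
    "expand_seed",
    "merge_candidates",
    "detect_complexes",
]

Scorer = Callable[[frozenset[str]], float]


@dataclass
class DetectionConfig:
    alpha: float = 0.9           # classifier-score threshold for expansion
    beta: float = 0.5            # overlap threshold for merging
    min_output_size: int = 3
    overlap: str = "na"          # "na" | "jaccard"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if self.overlap not in ("na", "jaccard"):
            raise ValueError(f"unknown overlap strategy {self.overlap!r}")


def make_scorer(classifier: ComplexDNN, embeddings: EmbeddingTable) -> Scorer:
    """Wrap a trained classifier + embedding table as a set scorer.

    The returned callable also exposes ``score_many(sets)`` so the
    expansion loop can score all candidate unions in one forward pass.
    """
    import numpy as np

    from .classifier import complex_embedding

    def scorer(members: frozenset[str]) -> float:
        return score_complex(classifier, embeddings, members)

    def score_many(sets) -> "np.ndarray":
        X = np.vstack([complex_embedding(embeddings, s) for s in sets])
        return classifier.predict_proba(X)

    scorer.score_many = score_many
    return scorer


def _overlap(a: frozenset[str], b: frozenset[str], strategy: str) -> float:
    if strategy == "na":
        return na_score(a, b)
    return len(a & b) / len(a | b)


def expand_seed(
    edge: tuple[str, str],
    network: InteractionNetwork,
    scorer: Scorer,
    alpha: float = 0.9,
    _adjacency_cache: dict[str, set[str]] | None = None,
) -> Complex:
    """Grow a candidate complex from one PPI edge.

    The candidate pool is the seed edge's neighborhood, collected once.
    Each round scores current u {v} for every remaining pool node v and
    adopts the best one whose score exceeds alpha (lexicographic smallest
    id wins ties); the adopted node leaves the pool. Expansion stops when
    no remaining pool node scores above alpha. Returns the final member
    set with its score.
    """
    u, v = edge
    key = (u, v) if u < v else (v, u)
    if key not in network.edges:
        raise ValueError(f"edge {edge!r} not in network")
    members = frozenset(edge)
    adjacency = (
        _adjacency_cache if _adjacency_cache is not None else _adjacency(network)
    )
    score_many = getattr(scorer, "score_many", None)
    pool = _neighbor_pool(members, adjacency)
    while pool:
        cands = sorted(pool)  # sorted => lexicographic tie-break on argmax
        unions = [members | {c} for c in cands]
        if score_many is not None:
            scores = list(score_many(unions))
        else:
            scores = [scorer(u) for u in unions]
        best_i = max(range(len(cands)), key=lambda i: scores[i])
        if scores[best_i] <= alpha:
            break
        members = unions[best_i]
        pool.discard(cands[best_i])
    return Complex(members=members, score=scorer(members))


def _adjacency(network: InteractionNetwork) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {n: set() for n in network.nodes}
    for a, b in network.edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def _neighbor_pool(
    members: frozenset[str], adjacency: dict[str, set[str]]
) -> set[str]:
    pool: set[str] = set()
    for m in members:
        pool |= adjacency[m]
    return pool - members


def _sort_key(c: Complex):
    # score desc, size desc, lexicographic members: deterministic ordering
    return (-(c.score or 0.0), -c.size, tuple(sorted(c.members)))


def merge_candidates(
    candidates: ComplexSet | Iterable[Complex],
    scorer: Scorer,
    beta: float = 0.5,
    min_output_size: int = 3,
    overlap: str = "na",
) -> ComplexSet:
    """Merge/deduplicate scored candidates.

    Candidates are sorted by score descending. Scanning down, each
    lower-scoring candidate overlapping a retained one above beta is merged
    into it when the union outscores the retained candidate, and removed
    otherwise. Only sets with more than ``min_output_size - 1`` members
    survive.
    """
    items = sorted(candidates, key=_sort_key)
    removed = [False] * len(items)
    retained: list[Complex] = []
    for i, ci in enumerate(items):
        if removed[i]:
            continue
        members_i = ci.members
        score_i = ci.score if ci.score is not None else scorer(members_i)
        for j in range(i + 1, len(items)):
            if removed[j]:
                continue
            cj = items[j]
            if _overlap(members_i, cj.members, overlap) > beta:
                union = members_i | cj.members
                union_score = scorer(union)
                if union_score > score_i:
                    members_i = union
                    score_i = union_score
                removed[j] = True
        if len(members_i) >= min_output_size:
            retained.append(Complex(members=members_i, score=score_i))
    return ComplexSet(retained)


def detect_complexes(
    network: InteractionNetwork,
    scorer: Scorer,
    config: DetectionConfig | None = None,
) -> ComplexSet:
    """Mine complexes from a PPI network with a set scorer.

    Expands a candidate from every edge, deduplicates identical member
    sets (keeping the highest score), then merges per ``config``.
    """
    if config is None:
        config = DetectionConfig()
    if network.n_edges == 0:
        return ComplexSet([])
    best: dict[frozenset[str], float] = {}
    adjacency = _adjacency(network)
    for n_done, edge in enumerate(sorted(network.edges), start=1):
        cand = expand_seed(
            edge, network, scorer, alpha=config.alpha,
            _adjacency_cache=adjacency,
        )
        prev = best.get(cand.members)
        if prev is None or cand.score > prev:
            best[cand.members] = cand.score
        if n_done % 500 == 0:
            logger.info("expanded %d / %d seeds", n_done, network.n_edges)
    candidates = [Complex(members=m, score=s) for m, s in best.items()]
    logger.info("%d distinct candidates before merging", len(candidates))
    return merge_candidates(
        candidates,
        scorer,
        beta=config.beta,
        min_output_size=config.min_output_size,
        overlap=config.overlap,
    )
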