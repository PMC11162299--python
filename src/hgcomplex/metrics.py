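"""Complex-matching metrics and biological-property statistics.

Matching a predicted complex p against a known complex b uses the
neighborhood-affinity (NA) score |p n b|^2 / (|p| |b|); p and b match when
NA >= 0.25 (the field's conventional threshold). From matches the standard
precision / recall / F1 follow, and from the intersection-count matrix
T_ij = |b_i n p_j| the complex-wise sensitivity Sn, positive predictive
value PPV and their geometric mean Acc.

Also provided: the mean pairwise score operator used for GO semantic
similarity summaries (with a pluggable pair scorer - ontology-based
similarity itself is out of scope and supplied by the caller as a table),
Manhattan-distance expression concordance, the hypergeometric enrichment
tail, and size-matched random pseudo-complexes for null comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import Complex, ComplexSet

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "na_score",
    "match_metrics",
    "accuracy_metrics",
    "evaluate_complexes",
    "mean_pairwise_score",
    "manhattan_concordance",
    "hypergeom_enrichment_p",
    "random_pseudo_complexes",
    "rank_compare",
]


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    sn: float
    ppv: float
    acc: float
    n_matched_predicted: int
    n_matched_known: int
    na_threshold: float = 0.25

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def na_score(p: Iterable[str], b: Iterable[str]) -> float:
    """Neighborhood affinity |p n b|^2 / (|p| * |b|); 1 iff p == b."""
    p, b = set(p), set(b)
    if not p or not b:
        raise ValueError("NA score of an empty set is undefined")
    inter = len(p & b)
    return inter * inter / (len(p) * len(b))


def match_metrics(
    P: ComplexSet, B: ComplexSet, threshold: float = 0.25
) -> tuple[float, float, float, int, int]:
    """Precision / recall / F1 from NA matching at the given threshold.

    A predicted complex is matched if some known complex reaches
    NA >= threshold, and symmetrically for known complexes. Returns
    (precision, recall, f1, n_matched_predicted, n_matched_known).
    """
    if len(P) == 0 or len(B) == 0:
        raise ValueError("match_metrics requires non-empty P and B")
    p_sets = P.member_sets
    b_sets = B.member_sets
    n_cp = sum(
        1 for p in p_sets if any(na_score(p, b) >= threshold for b in b_sets)
    )
    n_cb = sum(
        1 for b in b_sets if any(na_score(p, b) >= threshold for p in p_sets)
    )
    precision = n_cp / len(p_sets)
    recall = n_cb / len(b_sets)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1, n_cp, n_cb


def accuracy_metrics(
    P: ComplexSet, B: ComplexSet, ppv_denominator: str = "matched"
) -> tuple[float, float, float]:
    """Complex-wise (Sn, PPV, Acc) from the intersection matrix T.

    T_ij = |b_i n p_j|; Sn = sum_i max_j T_ij / sum_i |b_i|;
    PPV = sum_j max_i T_ij / sum_j sum_i T_ij; Acc = sqrt(Sn * PPV).

    ``ppv_denominator="matched"`` (default) counts only predicted complexes
    with at least one nonzero intersection in the PPV denominator - a
    predicted complex hitting nothing contributes zero to both sums either
    way, so this choice only matters conceptually; ``"all"`` is identical
    because zero columns add zero. Kept as a flag to document the 0/0
    convention.
    """
    if len(P) == 0 or len(B) == 0:
        raise ValueError("accuracy_metrics requires non-empty P and B")
    T = np.array(
        [[len(b & p) for p in P.member_sets] for b in B.member_sets],
        dtype=float,
    )
    sn = T.max(axis=1).sum() / sum(len(b) for b in B.member_sets)
    denom = T.sum()
    if denom == 0:
        warnings.warn("no predicted complex intersects any known complex")
        return float(sn), 0.0, 0.0
    if ppv_denominator not in ("matched", "all"):
        raise ValueError(f"unknown ppv_denominator {ppv_denominator!r}")
    ppv = T.max(axis=0).sum() / denom
    return float(sn), float(ppv), float(np.sqrt(sn * ppv))


def evaluate_complexes(
    P: ComplexSet, B: ComplexSet, threshold: float = 0.25
) -> EvalReport:
    """Full complex-level report: NA matching plus Sn/PPV/Acc."""
    precision, recall, f1, n_cp, n_cb = match_metrics(P, B, threshold)
    sn, ppv, acc = accuracy_metrics(P, B)
    return EvalReport(
        precision=precision,
        recall=recall,
        f1=f1,
        sn=sn,
        ppv=ppv,
        acc=acc,
        n_matched_predicted=n_cp,
        n_matched_known=n_cb,
        na_threshold=threshold,
    )


def mean_pairwise_score(
    members: Iterable[str], pair_scorer: Callable[[str, str], float]
) -> float:
    """Average of ``pair_scorer`` over all unordered member pairs.

    This is the per-complex summary used for e.g. GO semantic similarity:
    for three members a, b, c it is (s(a,b) + s(a,c) + s(b,c)) / 3.
    """
    members = sorted(set(members))
    if len(members) < 2:
        raise ValueError("mean_pairwise_score needs at least 2 members")
    scores = [pair_scorer(a, b) for a, b in combinations(members, 2)]
    return float(np.mean(scores))


def manhattan_concordance(
    M: pd.DataFrame, complexes: ComplexSet
) -> pd.DataFrame:
    """Per-complex Manhattan-distance summaries of member abundance profiles.

    D_ij = sum over samples of |M_i - M_j| for each member pair; the frame
    holds the mean, median and min over pairs per complex. Complexes with
    members missing from M, or with fewer than 2 present members, are
    skipped with a warning.
    """
    rows = []
    for idx, c in enumerate(complexes):
        members = sorted(c.members)
        missing = [m for m in members if m not in M.index]
        if missing or len(members) < 2:
            warnings.warn(
                f"complex {idx} skipped (missing={missing}, size={len(members)})"
            )
            continue
        sub = M.loc[members].to_numpy(dtype=float)
        dists = [
            float(np.abs(sub[i] - sub[j]).sum())
            for i, j in combinations(range(len(members)), 2)
        ]
        rows.append(
            {
                "complex": idx,
                "size": len(members),
                "mean": float(np.mean(dists)),
                "median": float(np.median(dists)),
                "min": float(np.min(dists)),
            }
        )
    return pd.DataFrame(rows)


def hypergeom_enrichment_p(
    complex_size: int, hits_in_complex: int, annotated_in_network: int,
    network_size: int,
) -> float:
    """Upper-tail hypergeometric p-value for annotation enrichment.

    P = 1 - sum_{i=0}^{t-1} C(F,i) C(V-F, |C|-i) / C(V, |C|), the probability
    of observing at least t annotated members in a random size-|C| set drawn
    from a network of V proteins of which F are annotated.
    """
    C, t, F, V = complex_size, hits_in_complex, annotated_in_network, network_size
    if not (0 <= t <= min(C, F) and F <= V and 0 < C <= V):
        raise ValueError(
            f"impossible arguments: |C|={C}, t={t}, |F|={F}, |V|={V}"
        )
    if t == 0:
        return 1.0
    return float(stats.hypergeom.sf(t - 1, V, F, C))


def random_pseudo_complexes(
    size_template: ComplexSet,
    universe: list[str],
    seed: int | np.random.Generator = 0,
) -> ComplexSet:
    """Size-matched random complexes: one per template complex, members
    uniform without replacement from the universe."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    max_size = max(size_template.sizes)
    if max_size > len(universe):
        raise ValueError("universe smaller than the largest template complex")
    pool = np.asarray(universe, dtype=object)
    out = [
        Complex(members=frozenset(rng.choice(pool, size=c.size, replace=False)))
        for c in size_template
    ]
    return ComplexSet(out)


def rank_compare(a, b, alternative: str = "two-sided"):
    """Thin Wilcoxon rank-sum comparison of two independent score samples
    (e.g. per-complex GO similarity of predicted vs pseudo complexes).
    Returns (statistic, p_value)."""
    res = stats.mannwhitneyu(list(a), list(b), alternative=alternative)
    return float(res.statistic), float(res.pvalue)
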