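"""Candidate gene ranking in artificial linkage intervals.

Evaluation follows the leave-one-out protocol used throughout the
disease-gene prioritization literature: each known disease gene *u* is
withheld in turn, an artificial linkage interval of 100 candidates is
formed from *u* plus its 99 genomically nearest non-seed genes, and the
method must rank *u* inside that interval.  Three models — one per GO
namespace — score every candidate with their positive-class
probability, and the final score is the arithmetic mean of the three
(a ``rank_mean`` aggregate is available as an alternative); higher
score means better rank, ties break lexicographically by gene ID.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .go_features import FeatureMatrix
from .model import ModelConfig, ModelParams, predict_proba, propagate_features, train
from .ppi import PPINetwork

logger = logging.getLogger(__name__)

INTERVAL_SIZE = 100

#: gene -> (chromosome, start, end), 0-based half-open
Coordinates = Mapping[str, tuple[str, int, int]]


@dataclass
class LinkageInterval:
    """The left-out target gene plus its 99 nearest eligible neighbours."""

    target_gene: str
    candidates: list[str]
    disease_id: str = ""

    def __post_init__(self) -> None:
        if len(self.candidates) != INTERVAL_SIZE:
            raise ValueError(
                f"interval must hold {INTERVAL_SIZE} candidates, got {len(self.candidates)}"
            )
        if self.target_gene not in self.candidates:
            raise ValueError("target gene missing from its own interval")
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError("duplicate candidates in interval")


@dataclass
class RankList:
    """Best-first ordering of one interval with the target's 1-based rank."""

    interval: LinkageInterval
    ranking: list[str]
    scores: dict[str, float]
    target_rank: int

    def __post_init__(self) -> None:
        if sorted(self.ranking) != sorted(self.interval.candidates):
            raise ValueError("ranking is not a permutation of the interval")
        if self.ranking[self.target_rank - 1] != self.interval.target_gene:
            raise ValueError("target_rank inconsistent with ranking")


def build_linkage_interval(
    target: str,
    coordinates: Coordinates,
    seed_set: set[str],
    universe: Sequence[str],
    disease_id: str = "",
) -> LinkageInterval:
    """Target + the 99 nearest non-seed genes by genomic proximity.

    Proximity is midpoint distance on the target's chromosome; only if
    that chromosome lacks 99 eligible genes are genes from other
    chromosomes appended (ordered lexicographically).  Seed genes other
    than the target are never eligible.  Ties break by gene ID.
    """
    if target not in coordinates:
        raise ValueError(f"target {target!r} has no coordinates")
    chrom, start, end = coordinates[target]
    mid_t = (start + end) / 2
    eligible = [
        g for g in universe
        if g != target and g not in seed_set and g in coordinates
    ]
    n_needed = INTERVAL_SIZE - 1
    if len(eligible) < n_needed:
        raise ValueError(
            f"only {len(eligible)} eligible genes for {target!r}; need {n_needed}"
        )
    same, other = [], []
    for g in eligible:
        c, s, e = coordinates[g]
        if c == chrom:
            same.append((abs((s + e) / 2 - mid_t), g))
        else:
            other.append(g)
    same.sort()
    picked = [g for _, g in same[:n_needed]]
    if len(picked) < n_needed:
        picked += sorted(other)[: n_needed - len(picked)]
    return LinkageInterval(target, sorted([target, *picked], key=str), disease_id)


def score_candidates(
    models: Sequence[ModelParams],
    features: Sequence[FeatureMatrix],
    network: PPINetwork,
    interval: LinkageInterval,
    config: ModelConfig,
    propagated: Sequence[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Positive-class probability of every candidate, per namespace.

    ``propagated`` may carry precomputed OR-propagated feature arrays
    (one per namespace) to avoid repeating the sparse propagation.
    Candidates absent from the network are scored from an all-zero
    feature row (logged).
    """
    if len(models) != len(features):
        raise ValueError("need one model per feature matrix")
    idx = network.index()
    missing = [g for g in interval.candidates if g not in idx]
    if missing:
        logger.info("%d interval candidates absent from the network", len(missing))
    out = []
    for ns, (params, fm) in enumerate(zip(models, features)):
        Xp = (
            propagated[ns]
            if propagated is not None
            else propagate_features(fm, network, config)
        )
        rows = np.zeros((len(interval.candidates), Xp.shape[1]))
        for r, g in enumerate(interval.candidates):
            if g in idx:
                rows[r] = Xp[idx[g]]
        probs = predict_proba(rows, params, config)
        out.append(probs[:, 1])
    return out


def rank_candidates(
    namespace_scores: Sequence[np.ndarray],
    interval: LinkageInterval,
    aggregate: str = "score_mean",
) -> RankList:
    """Average the namespace scores and sort best-first.

    ``score_mean`` (default) averages the positive-class probabilities;
    ``rank_mean`` averages within-namespace ranks instead.  Ties break
    lexicographically by gene ID.
    """
    arr = np.vstack([np.asarray(s, dtype=float) for s in namespace_scores])
    if arr.shape[1] != len(interval.candidates):
        raise ValueError("score vectors not aligned with the interval")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite candidate score")
    if aggregate == "score_mean":
        final = arr.mean(axis=0)
    elif aggregate == "rank_mean":
        from scipy.stats import rankdata

        # rank 1 = best within each namespace; lower mean rank = better
        final = -np.vstack([rankdata(-row, method="average") for row in arr]).mean(axis=0)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    order = sorted(
        range(len(interval.candidates)),
        key=lambda j: (-final[j], interval.candidates[j]),
    )
    ranking = [interval.candidates[j] for j in order]
    scores = {interval.candidates[j]: float(final[j]) for j in range(len(final))}
    return RankList(interval, ranking, scores, ranking.index(interval.target_gene) + 1)


def _training_labels(
    seed_set: set[str],
    target: str,
    network: PPINetwork,
    rng: np.random.Generator,
    negatives_per_positive: int = 3,
) -> dict[str, int]:
    """Positives = the seed set; negatives = a seeded background sample.

    The held-out target is never labeled, so it stays part of the
    unlabeled pool and receives no supervision.
    """
    pool = sorted(set(network.gene_order) - seed_set - {target})
    n_neg = min(negatives_per_positive * len(seed_set), len(pool))
    neg = rng.choice(len(pool), size=n_neg, replace=False)
    labels = {g: 1 for g in sorted(seed_set) if g in network.index()}
    labels.update({pool[j]: 0 for j in sorted(neg)})
    return labels


def loocv_evaluate(
    disease: Sequence[str],
    features: Sequence[FeatureMatrix],
    network: PPINetwork,
    coordinates: Coordinates,
    config: ModelConfig,
    disease_id: str = "",
    aggregate: str = "score_mean",
    fast_loocv: bool = False,
) -> list[RankList]:
    """Leave-one-out ranking of every disease gene in its interval.

    For each gene *u*: remove it from the positive labels, train the
    three namespace models, build *u*'s linkage interval and rank it.
    ``fast_loocv`` instead trains one model triple on the full seed set
    and reuses it for every interval — an approximation that leaks the
    target's label into training, documented as such.
    """
    disease = sorted(set(disease))
    if len(disease) < 2:
        raise ValueError("disease needs >= 2 genes for leave-one-out")
    universe = [g for g in network.gene_order]
    rng = np.random.default_rng(config.seed)
    ns_seeds = [int(s) for s in rng.integers(2**31, size=len(features))]
    neg_rng_seed = int(rng.integers(2**31))

    def train_models(seed_set: set[str], target: str) -> list[ModelParams]:
        labels = _training_labels(
            seed_set, target, network, np.random.default_rng(neg_rng_seed)
        )
        out = []
        for fm, s in zip(features, ns_seeds):
            params, _ = train(fm, network, labels, replace(config, seed=s))
            out.append(params)
        return out

    results: list[RankList] = []
    shared_models = (
        train_models(set(disease), target="") if fast_loocv else None
    )
    propagated = [propagate_features(fm, network, config) for fm in features]
    for u in disease:
        seed_set = set(disease) - {u}
        interval = build_linkage_interval(
            u, coordinates, seed_set, universe, disease_id
        )
        models = shared_models if fast_loocv else train_models(seed_set, u)
        scores = score_candidates(
            models, features, network, interval, config, propagated=propagated
        )
        results.append(rank_candidates(scores, interval, aggregate))
        logger.info("LOOCV %s: target %s ranked %d/%d",
                    disease_id or "disease", u, results[-1].target_rank, INTERVAL_SIZE)
    return results


def degree_baseline_rank(
    network: PPINetwork, interval: LinkageInterval
) -> RankList:
    """Rank candidates by PPI degree (guilt-by-hubness baseline)."""
    idx = network.index()
    deg = network.degrees
    scores = np.array(
        [float(deg[idx[g]]) if g in idx else 0.0 for g in interval.candidates]
    )
    return rank_candidates([scores], interval)
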