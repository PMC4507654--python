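"""Feature selection: exhaustive 1-2 feature search and SFFS under k-fold CV.

All size-1 and size-2 subsets of the ten envelope features (10 + 45 = 55
candidates) are scored by the cross-validated criterion — by default the
n-1 SD of (reference - estimated) SBP differences, the headline agreement
metric.  Sequential forward floating selection (SFFS) then starts from the
best pair: it greedily adds the most improving feature and, after each
addition, conditionally removes features while removal improves on the best
criterion recorded for the smaller subset size.

Cross-validation folds group recordings by subject by default so repeated
measurements of one subject never straddle a train/test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .features import FEATURE_NAMES
from .pipeline import ProcessedRecording, predict_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVPlan:
    """K-fold assignment of recordings (grouped by subject or recording)."""

    k: int = 4
    grouping: str = "by_subject"
    seed: int = 0
    assignments: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least two folds")
        if self.grouping not in ("by_subject", "by_recording"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


@dataclass(frozen=True)
class Candidate:
    """One scored feature subset."""

    features: tuple[str, ...]
    mean_diff: float
    criterion: float
    n: int
    failed: bool = False
    error: str = ""


@dataclass
class SelectionResult:
    """Ranking (ascending criterion) plus the SFFS trajectory, if any."""

    candidate_sets: list[Candidate]
    best_set: tuple[str, ...]
    trajectory: list[dict] = field(default_factory=list)
    criterion_name: str = "sd"


def kfold_split(records: Sequence[ProcessedRecording], plan: CVPlan) -> CVPlan:
    """Assign each recording to a fold, balanced within one group.

    Groups (subjects, or single recordings) are shuffled with ``plan.seed``
    and dealt round-robin, so fold sizes differ by at most one group and the
    same seed always reproduces the same assignment.
    """
    key = (lambda r: r.subject) if plan.grouping == "by_subject" else (lambda r: r.rec_id)
    groups: dict[str, list[str]] = {}
    for r in records:
        groups.setdefault(key(r), []).append(r.rec_id)
    names = sorted(groups)
    if len(names) < plan.k:
        raise ValueError(f"only {len(names)} groups for {plan.k} folds")
    rng = np.random.default_rng(plan.seed)
    order = rng.permutation(len(names))
    assignments = {}
    for pos, gi in enumerate(order):
        for rid in groups[names[gi]]:
            assignments[rid] = pos % plan.k
    return replace(plan, assignments=assignments)


def cv_sbp_differences(
    records: Sequence[ProcessedRecording],
    estimator_kind: str,
    feature_names: Sequence[str],
    plan: CVPlan,
) -> np.ndarray:
    """Pooled out-of-fold (reference - estimate) SBP differences.

    All model fitting (fixed-ratio means, regression coefficients, feature
    standardization) happens inside the training folds only.
    """
    if not plan.assignments:
        plan = kfold_split(records, plan)
    diffs: list[float] = []
    for fold in range(plan.k):
        train = [r for r in records if plan.assignments[r.rec_id] != fold]
        test = [r for r in records if plan.assignments[r.rec_id] == fold]
        if not test:
            continue
        for rec, est, _err in predict_cohort(train, test, estimator_kind, feature_names):
            if est is not None and rec.ref_sbp is not None:
                diffs.append(rec.ref_sbp - est.sbp)
    return np.asarray(diffs)


def _score(
    records: Sequence[ProcessedRecording],
    estimator_kind: str,
    features: tuple[str, ...],
    plan: CVPlan,
    criterion: str,
) -> Candidate:
    try:
        d = cv_sbp_differences(records, estimator_kind, features, plan)
        if d.size < 2:
            raise ValueError("fewer than two scored recordings")
        crit = float(np.abs(d).mean()) if criterion == "mae" else float(d.std(ddof=1))
        return Candidate(features=features, mean_diff=float(d.mean()), criterion=crit, n=d.size)
    except Exception as exc:  # noqa: BLE001 - candidate isolation
        logger.warning("candidate %s failed: %s", features, exc)
        return Candidate(
            features=features, mean_diff=float("nan"), criterion=float("inf"),
            n=0, failed=True, error=str(exc),
        )


def _rank_key(c: Candidate):
    return (c.criterion, len(c.features), c.features)


def exhaustive_search(
    records: Sequence[ProcessedRecording],
    estimator_kind: str = "mlr",
    plan: CVPlan = CVPlan(),
    feature_pool: tuple[str, ...] = FEATURE_NAMES,
    criterion: str = "sd",
) -> SelectionResult:
    """Score every subset of one or two features from the pool.

    With the full ten-feature pool this enumerates 10 + C(10,2) = 55
    candidates.  Failed candidates are excluded from the ranking.  Ties are
    broken by fewer features, then lexicographic name order.
    """
    if not plan.assignments:
        plan = kfold_split(records, plan)
    subsets = [(f,) for f in feature_pool] + [
        tuple(sorted(pair)) for pair in combinations(feature_pool, 2)
    ]
    scored = [_score(records, estimator_kind, s, plan, criterion) for s in subsets]
    ranked = sorted([c for c in scored if not c.failed], key=_rank_key)
    ranked += [c for c in scored if c.failed]
    if not ranked or ranked[0].failed:
        raise ValueError("every candidate failed")
    return SelectionResult(
        candidate_sets=ranked, best_set=ranked[0].features, criterion_name=criterion
    )


def sffs(
    records: Sequence[ProcessedRecording],
    estimator_kind: str = "mlr",
    plan: CVPlan = CVPlan(),
    start_set: Optional[tuple[str, ...]] = None,
    feature_pool: tuple[str, ...] = FEATURE_NAMES,
    criterion: str = "sd",
    tol: float = 0.02,
) -> SelectionResult:
    """Sequential forward floating selection from ``start_set``.

    Repeats {add the best improving feature; then conditionally remove
    features while removal beats the best criterion recorded at the smaller
    size} until no addition improves the criterion by more than
    ``tol * criterion``.  The default 2% relative tolerance reflects that the
    criterion is itself a cross-validated estimate: improvements below CV
    sampling noise are not evidence a feature helps.  Returns the best set
    found plus the full add/remove trajectory.
    """
    if not plan.assignments:
        plan = kfold_split(records, plan)
    pool = tuple(feature_pool)
    if start_set is None:
        start_set = exhaustive_search(records, estimator_kind, plan, pool, criterion).best_set
    current = tuple(sorted(start_set))

    cache: dict[tuple[str, ...], Candidate] = {}

    def score(s: tuple[str, ...]) -> Candidate:
        s = tuple(sorted(s))
        if s not in cache:
            cache[s] = _score(records, estimator_kind, s, plan, criterion)
        return cache[s]

    best_by_size: dict[int, Candidate] = {}

    def record_best(c: Candidate) -> None:
        k = len(c.features)
        if not c.failed and (k not in best_by_size or c.criterion < best_by_size[k].criterion):
            best_by_size[k] = c

    trajectory: list[dict] = []
    cur = score(current)
    if cur.failed:
        raise ValueError(f"start set {current} failed: {cur.error}")
    record_best(cur)
    trajectory.append({"step": "start", "features": list(current), "criterion": cur.criterion})

    while True:
        remaining = [f for f in pool if f not in current]
        if not remaining:
            break
        adds = [score(current + (f,)) for f in remaining]
        adds = [c for c in adds if not c.failed]
        if not adds:
            break
        best_add = min(adds, key=_rank_key)
        if best_add.criterion >= cur.criterion * (1.0 - tol):
            break  # no addition improves beyond tolerance
        current, cur = best_add.features, best_add
        record_best(cur)
        trajectory.append({"step": "add", "features": list(current), "criterion": cur.criterion})

        # floating backward phase
        while len(current) > 2:
            drops = [score(tuple(f for f in current if f != g)) for g in current]
            drops = [c for c in drops if not c.failed]
            if not drops:
                break
            best_drop = min(drops, key=_rank_key)
            incumbent = best_by_size.get(len(current) - 1)
            if incumbent is not None and best_drop.criterion < incumbent.criterion * (1.0 - tol):
                current, cur = best_drop.features, best_drop
                record_best(cur)
                trajectory.append(
                    {"step": "remove", "features": list(current), "criterion": cur.criterion}
                )
            else:
                break

    best = min(best_by_size.values(), key=_rank_key)
    ranked = sorted((c for c in cache.values() if not c.failed), key=_rank_key)
    return SelectionResult(
        candidate_sets=ranked, best_set=best.features, trajectory=trajectory,
        criterion_name=criterion,
    )
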