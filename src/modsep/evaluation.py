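"""Cross-validation of missing-gene prediction: ROC, thresholds, baselines.

The evaluation scheme reserves known common genes of a disease pair as
positive test examples and an equal-sized draw of non-common genes as
negatives, scores every test gene with s(x) = S_AB − S_AB[+x] on the reduced
working sets, and measures how well the ranking recovers the held-out common
genes (AUROC). A Youden-style threshold — the ROC point farthest above the
diagonal — converts scores into predictions for precision and recall.

Two hold-out conventions are supported. The default, ``reserve``, removes
each held-out common gene from *both* working sets; it is then scored in
de-novo mode, S_AB[+x] adding it to both sets at once. The alternative,
``demote``, instead retains each positive on one randomly chosen side
(recorded on the split), which places it in the single-gene candidate set of
the exhaustive search. Reserving is the default because a demoted common
gene keeps anchoring both disease neighbourhoods through its interactions on
the retained side — the very signal the test is supposed to hide.

The randomised baseline replaces a pair's common genes with uniformly drawn
interactome genes (counts preserved), destroying the biological signal while
keeping the graph topology and module locations intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DataError
from .graph_io import map_to_graph
from .separation import NEAREST, DistanceCache, separation

log = logging.getLogger(__name__)

__all__ = [
    "CVSplit", "EvaluationRecord",
    "make_cv_split", "score_test_set", "roc_auc", "choose_threshold",
    "precision_recall", "randomize_common_genes", "evaluate_pair",
    "evaluate_pairs", "stratified_report", "roc_histogram",
    "DEFAULT_RR_BINS", "DEFAULT_COMMON_BINS",
]

DEFAULT_RR_BINS = ((0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, float("inf")))
DEFAULT_COMMON_BINS = ((0, 5), (5, 10), (10, 15), (15, float("inf")))


@dataclass(frozen=True)
class CVSplit:
    """One seeded hold-out draw for a disease pair.

    ``positives`` are common genes reserved as test examples; ``negatives``
    are non-common genes. ``working_a`` / ``working_b`` are the reduced gene
    sets actually used for scoring. Under the ``demote`` convention,
    ``demotion`` records which side each positive was retained on; under
    ``reserve`` it is empty (positives belong to neither working set).
    """

    pair: tuple
    positives: frozenset
    negatives: frozenset
    demotion: dict
    seed: int
    working_a: frozenset
    working_b: frozenset
    holdout: str = "reserve"


@dataclass(frozen=True)
class EvaluationRecord:
    """Per-pair cross-validation metrics."""

    pair: tuple
    roc_score: float
    threshold: float
    precision: float
    recall: float
    n_common: int
    method: str
    rr: float | None = None


def make_cv_split(A, B, n_pos: int = 10, n_neg: int = 10, seed: int = 0,
                  pair: tuple = ("A", "B"), holdout: str = "reserve") -> CVSplit:
    """Reserve up to ``n_pos`` common and ``n_neg`` non-common genes.

    Sampling is without replacement from the seeded generator; fewer are
    taken when a pool is smaller. Negatives are drawn balanced across the two
    exclusive sides as far as the pools allow. With ``holdout="reserve"``
    each positive is removed from both working sets; with ``"demote"`` it is
    retained on one uniformly chosen side (so it lands in the candidate set
    of the exhaustive single-gene search).
    """
    A, B = set(A), set(B)
    common = sorted(A & B)
    a_only = sorted(A - B)
    b_only = sorted(B - A)
    if not common:
        raise DataError("no common genes to hold out")
    if not (a_only or b_only):
        raise DataError("no non-common genes to use as negatives")
    rng = np.random.default_rng(seed)

    k_pos = min(n_pos, len(common))
    positives = sorted(rng.choice(common, size=k_pos, replace=False).tolist())

    k_neg = min(n_neg, len(a_only) + len(b_only))
    take_a = min(len(a_only), k_neg - k_neg // 2)
    take_b = min(len(b_only), k_neg - take_a)
    take_a = min(len(a_only), k_neg - take_b)  # top up if B-side pool was short
    neg_a = rng.choice(a_only, size=take_a, replace=False).tolist() if take_a else []
    neg_b = rng.choice(b_only, size=take_b, replace=False).tolist() if take_b else []
    negatives = sorted(neg_a + neg_b)

    if holdout == "demote":
        demotion = {p: ("A" if rng.random() < 0.5 else "B") for p in positives}
    elif holdout == "reserve":
        demotion = {}
    else:
        raise DataError(f"unknown holdout mode {holdout!r}")
    working_a = (A - set(positives)) | {p for p, s in demotion.items() if s == "A"}
    working_b = (B - set(positives)) | {p for p, s in demotion.items() if s == "B"}
    return CVSplit(pair=pair, positives=frozenset(positives),
                   negatives=frozenset(negatives), demotion=demotion,
                   seed=seed, working_a=frozenset(working_a),
                   working_b=frozenset(working_b), holdout=holdout)


def score_test_set(g, split: CVSplit, method: str = NEAREST,
                   cache: DistanceCache | None = None) -> list:
    """Score every held-out gene on the reduced working sets.

    Returns ``[(gene, score, label), ...]`` with label 1 for held-out common
    genes, sorted by descending score (ties by gene id). Every test gene x
    is scored by marking it shared on the working sets,
    S_AB[+x] = S(A ∪ {x}, B ∪ {x}); for reserved positives this is the
    de-novo form (x belongs to neither working set), for in-set negatives it
    coincides with the exhaustive search's S_AB[+x]. The base S_AB is
    computed on the same working sets.
    """
    cache = cache or DistanceCache(g)
    A, B = set(split.working_a), set(split.working_b)
    base = separation(g, A, B, method, cache)
    rows = []
    for gene, label in [(p, 1) for p in split.positives] + [(n, 0) for n in split.negatives]:
        sp = separation(g, A | {gene}, B | {gene}, method, cache)
        rows.append((gene, base.s_ab - sp.s_ab, label))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows


def _split_classes(scores):
    s = np.asarray([row[-2] for row in scores] if len(scores[0]) == 3
                   else [row[0] for row in scores], dtype=float)
    y = np.asarray([row[-1] for row in scores], dtype=int)
    if y.min() == y.max():
        raise DataError("need at least one positive and one negative label")
    return s, y


def roc_auc(scores) -> float:
    """Rank-based area under the ROC curve (Mann–Whitney statistic).

    Accepts ``(score, label)`` or ``(gene, score, label)`` tuples; tied
    positive–negative score pairs are credited 0.5.
    """
    s, y = _split_classes(scores)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)  # average ranks => 0.5 credit per tie
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def choose_threshold(scores) -> float:
    """Score cutoff at the ROC point maximising TPR − FPR.

    This is the "highest peak above the diagonal" (Youden) point; a test gene
    is predicted common when its score >= the returned cutoff. Ties in
    TPR − FPR resolve toward the higher threshold (fewer predicted positives).
    """
    s, y = _split_classes(scores)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    best_cut, best_j = None, -np.inf
    for cut in sorted(set(s.tolist()), reverse=True):
        pred = s >= cut
        j = (pred & (y == 1)).sum() / n_pos - (pred & (y == 0)).sum() / n_neg
        if j > best_j:
            best_j, best_cut = j, cut
    return float(best_cut)


def precision_recall(scores, threshold: float) -> tuple:
    """Precision and recall predicting positive where score >= threshold.

    Precision is 0 by convention when nothing is predicted positive.
    """
    s, y = _split_classes(scores)
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn)
    return precision, recall


def randomize_common_genes(g, A, B, seed: int = 0) -> tuple:
    """Null model: swap the pair's common genes for random interactome genes.

    The common genes are removed from both sets and replaced, in both sets,
    by an equal number of genes drawn uniformly without replacement from the
    interactome nodes outside G_A ∪ G_B — common-gene count and set sizes are
    preserved exactly while the shared biology is destroyed.
    """
    A, B = set(A), set(B)
    common = sorted(A & B)
    if not common:
        raise DataError("no common genes to randomize")
    pool = sorted(set(g.nodes) - (A | B))
    if len(pool) < len(common):
        raise DataError(
            f"interactome too small: need {len(common)} replacement genes, "
            f"have {len(pool)}")
    rng = np.random.default_rng(seed)
    repl = set(rng.choice(pool, size=len(common), replace=False).tolist())
    return (A - set(common)) | repl, (B - set(common)) | repl


def evaluate_pair(g, A, B, n_pos: int = 10, n_neg: int = 10, seed: int = 0,
                  method: str = NEAREST, rr: float | None = None,
                  pair: tuple = ("A", "B"), repeats: int = 1,
                  holdout: str = "reserve") -> EvaluationRecord:
    """Full cross-validation of one disease pair.

    Composes split → scoring → AUROC / threshold / precision / recall. With
    ``repeats > 1`` the metrics are averaged over independent draws seeded
    ``seed, seed+1, ...``.
    """
    A, B = set(A), set(B)
    n_common = len(A & B)
    cache = DistanceCache(g)
    rocs, thrs, precs, recs = [], [], [], []
    for i in range(repeats):
        split = make_cv_split(A, B, n_pos, n_neg, seed=seed + i, pair=pair,
                              holdout=holdout)
        scored = score_test_set(g, split, method, cache)
        rocs.append(roc_auc(scored))
        thr = choose_threshold(scored)
        thrs.append(thr)
        p, r = precision_recall(scored, thr)
        precs.append(p)
        recs.append(r)
    return EvaluationRecord(
        pair=pair, roc_score=float(np.mean(rocs)), threshold=float(np.mean(thrs)),
        precision=float(np.mean(precs)), recall=float(np.mean(recs)),
        n_common=n_common, method=method, rr=rr)


def evaluate_pairs(g, associations: dict, pairs, n_pos: int = 10, n_neg: int = 10,
                   seed: int = 0, method: str = NEAREST, repeats: int = 1,
                   baseline: str | None = None, holdout: str = "reserve") -> tuple:
    """Evaluate a table of disease pairs; skip unusable ones with a reason.

    ``pairs`` is an iterable of ``(disease_a, disease_b)`` or
    ``(disease_a, disease_b, rr)``. Pairs with no common gene, with all genes
    common, or with fewer than two mapped genes on a side are skipped — the
    skip reason is logged and returned. ``baseline="randomized"`` applies
    :func:`randomize_common_genes` (seeded) before evaluation.

    Returns ``(records, skipped)`` with ``skipped`` a list of
    ``(pair, reason)``.
    """
    records, skipped = [], []
    for i, row in enumerate(pairs):
        da, db, rr = (row[0], row[1], None) if len(row) == 2 else (row[0], row[1], row[2])
        pair = (da, db)
        try:
            for d in pair:
                if d not in associations:
                    raise DataError(f"unknown disease {d!r}")
            A = set(map_to_graph(g, associations[da], da).in_graph)
            B = set(map_to_graph(g, associations[db], db).in_graph)
            if not A & B:
                raise DataError("no common genes")
            if not A ^ B:
                raise DataError("no candidates: all genes common")
            if baseline == "randomized":
                A, B = randomize_common_genes(g, A, B, seed=seed + i)
            elif baseline is not None:
                raise DataError(f"unknown baseline {baseline!r}")
            records.append(evaluate_pair(
                g, A, B, n_pos=n_pos, n_neg=n_neg, seed=seed + i,
                method=method, rr=rr, pair=pair, repeats=repeats,
                holdout=holdout))
        except DataError as e:
            log.info("skipping pair %s: %s", pair, e)
            skipped.append((pair, str(e)))
    return records, skipped


def _bin_label(lo, hi) -> str:
    return f"[{lo:g}, {hi:g})" if np.isfinite(hi) else f">={lo:g}"


def _summarise(rows_records) -> dict:
    if not rows_records:
        return {"n_pairs": 0, "roc_mean": np.nan, "roc_sd": np.nan,
                "precision_mean": np.nan, "precision_sd": np.nan,
                "recall_mean": np.nan, "recall_sd": np.nan}
    roc = np.array([r.roc_score for r in rows_records])
    pre = np.array([r.precision for r in rows_records])
    rec = np.array([r.recall for r in rows_records])
    # population sd: a single-record bin reports sd 0, not NaN
    return {"n_pairs": len(rows_records),
            "roc_mean": roc.mean(), "roc_sd": roc.std(),
            "precision_mean": pre.mean(), "precision_sd": pre.std(),
            "recall_mean": rec.mean(), "recall_sd": rec.std()}


def stratified_report(records, rr_bins=DEFAULT_RR_BINS,
                      common_bins=DEFAULT_COMMON_BINS) -> pd.DataFrame:
    """Summary table stratified by comorbidity (RR) and common-gene count.

    One row per bin per stratum plus an overall row; empty bins appear with
    ``n_pairs`` 0 and NaN metrics. RR-stratified rows only consider records
    that carry an RR value; bins are left-closed, right-open.
    """
    records = list(records)
    rows = [{"stratum": "overall", "bin": "all", **_summarise(records)}]
    with_rr = [r for r in records if r.rr is not None]
    for lo, hi in rr_bins:
        sel = [r for r in with_rr if lo <= r.rr < hi]
        rows.append({"stratum": "rr", "bin": _bin_label(lo, hi), **_summarise(sel)})
    for lo, hi in common_bins:
        sel = [r for r in records if lo <= r.n_common < hi]
        rows.append({"stratum": "n_common", "bin": _bin_label(lo, hi),
                     **_summarise(sel)})
    return pd.DataFrame(rows)


def roc_histogram(records, grid=None) -> pd.DataFrame:
    """Cumulative AUROC histogram: fraction of pairs with ROC score >= x."""
    records = list(records)
    if grid is None:
        grid = np.round(np.linspace(0.0, 1.0, 21), 2)
    if not records:
        raise DataError("no records to histogram")
    roc = np.array([r.roc_score for r in records])
    frac = [(roc >= x).mean() for x in grid]
    return pd.DataFrame({"roc_score": grid, "fraction_ge": frac})
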