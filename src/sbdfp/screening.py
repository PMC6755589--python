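"""Similarity-search strategies and enrichment benchmarking.

Three search strategies score a library against a set of query actives:

* ``1-NN`` — each library compound is scored by its maximum Tanimoto
  similarity to any query compound (k-nearest-neighbour with k = 1);
* ``DFP`` — the queries are condensed into a classic 50%-threshold database
  fingerprint and each library compound gets one Tanimoto value against it;
* ``SB-DFP`` — likewise, but the condensation is the statistical-based
  database fingerprint built against a reference bit-frequency profile.

Enrichment is summarised by the recovery rate (fraction of actives found in
a selection the size of the number of hidden actives — an early-enrichment
measure) and the ROC AUC (rank-based Mann-Whitney form, ties credited 0.5 —
single-fingerprint searches produce heavily tied scores, and 0.5 credit is
the unbiased convention).

The repeated-random-query benchmark mirrors the standard protocol: in each
replicate a fixed-size query set of actives is drawn at random, the
remaining actives (ADCs) are hidden in the decoy library, the library is
scored under all three strategies, and RR/AUC are averaged over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ttest_ind
from sklearn.metrics import roc_curve

from .builders import build_dfp, build_sbdfp, count_bits
from .core import (
    BitCountProfile,
    BitMatrix,
    DatabaseFingerprint,
    check_same_scheme,
)
from .similarity import tanimoto_matrix

__all__ = [
    "ScreeningRun",
    "knn_scores",
    "single_fp_scores",
    "recovery_rate",
    "roc_auc",
    "benchmark",
    "benchmark_sweep",
    "best_strategies",
    "STRATEGIES",
]

STRATEGIES = ("1-NN", "DFP", "SB-DFP")


@dataclass
class ScreeningRun:
    """One scored library with labels and its enrichment summaries."""

    scores: np.ndarray
    labels: np.ndarray
    strategy: str
    ids: list[str] = field(default_factory=list)
    rr: float = float("nan")
    auc: float = float("nan")

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")


def knn_scores(query: BitMatrix, library: BitMatrix) -> np.ndarray:
    """1-NN scores: max Tanimoto of each library compound over the query set."""
    check_same_scheme(query, library)
    if query.n_molecules < 1:
        raise ValueError("query set is empty")
    return tanimoto_matrix(query.rows, library.rows).max(axis=0)


def single_fp_scores(dbfp: DatabaseFingerprint, library: BitMatrix) -> np.ndarray:
    """Score each library compound by Tanimoto against one condensed
    fingerprint (0/0 pairs score 0)."""
    check_same_scheme(dbfp, library)
    return tanimoto_matrix(dbfp.bits[None, :], library.rows).ravel()


def recovery_rate(
    scores,
    labels,
    ids: list[str] | None = None,
    selection_size: int | None = None,
) -> float:
    """Fraction of actives in the top-``selection_size`` of the ranked library.

    Default selection size is the number of actives.  Ranking is by
    descending score with ties broken by ascending compound identifier, so
    the result is invariant under any permutation of the library order.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_act = int(labels.sum())
    if n_act == 0:
        raise ValueError("recovery rate undefined without actives")
    if selection_size is None:
        selection_size = n_act
    if not 1 <= selection_size <= scores.shape[0]:
        raise ValueError("selection size must lie in [1, library size]")
    if ids is None:
        ids = [str(i) for i in range(scores.shape[0])]
    order = np.lexsort((np.asarray(ids, dtype=object), -scores))
    found = int(labels[order[:selection_size]].sum())
    return found / n_act


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve and rank-based AUC.

    AUC is the Mann-Whitney statistic (probability that a random active
    outscores a random decoy, ties credited 0.5); the curve is returned as
    (fpr, tpr) points over score thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_act = int(labels.sum())
    n_dec = int(labels.shape[0] - n_act)
    if n_act == 0 or n_dec == 0:
        raise ValueError("ROC needs at least one active and one decoy")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5 credit
    auc = (ranks[labels == 1].sum() - n_act * (n_act + 1) / 2.0) / (n_act * n_dec)
    fpr, tpr, _ = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), float(auc)


def _score_library(
    strategy: str,
    query: BitMatrix,
    library: BitMatrix,
    reference_profile: BitCountProfile,
    alpha: float,
    threshold: float,
) -> np.ndarray:
    if strategy == "1-NN":
        return knn_scores(query, library)
    if strategy == "DFP":
        return single_fp_scores(build_dfp(count_bits(query), threshold), library)
    if strategy == "SB-DFP":
        fp = build_sbdfp(count_bits(query), reference_profile, alpha=alpha)
        return single_fp_scores(fp, library)
    raise ValueError(f"unknown strategy {strategy!r}")


def benchmark(
    actives: BitMatrix,
    decoys: BitMatrix,
    reference_profile: BitCountProfile,
    n_reps: int = 100,
    query_size: int = 10,
    alpha: float = 0.01,
    threshold: float = 0.5,
    seed: int = 0,
    selection_size: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated-random-query similarity-search benchmark.

    In each of ``n_reps`` replicates, ``query_size`` actives are drawn
    without replacement as the query; all remaining actives (the ADCs) are
    added to the decoys to form the search set; the set is scored under the
    1-NN, DFP and SB-DFP strategies; and RR (selection size = number of
    ADCs unless overridden) and AUC are recorded.

    Replicate ``r`` draws from substream ``r`` of a single seeded generator,
    so it is reproducible independently of ``n_reps``.

    Returns ``(per_replicate, summary)``: a long table with one row per
    (replicate, strategy) and a per-strategy mean/sd summary.
    """
    check_same_scheme(actives, decoys)
    if actives.n_molecules <= query_size:
        raise ValueError("need more actives than the query size")
    if set(actives.ids) & set(decoys.ids):
        raise ValueError("active and decoy identifiers must be disjoint")

    streams = np.random.SeedSequence(seed).spawn(n_reps)
    records = []
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        q_idx = rng.choice(actives.n_molecules, size=query_size, replace=False)
        adc_idx = np.setdiff1d(np.arange(actives.n_molecules), q_idx)
        query = actives.subset(q_idx)
        adcs = actives.subset(adc_idx)
        library = BitMatrix(
            ids=decoys.ids + adcs.ids,
            rows=np.vstack([decoys.rows, adcs.rows]),
            scheme_tag=actives.scheme_tag,
        )
        labels = np.concatenate(
            [np.zeros(decoys.n_molecules, dtype=int), np.ones(adcs.n_molecules, dtype=int)]
        )
        sel = selection_size if selection_size is not None else adcs.n_molecules
        for strategy in STRATEGIES:
            scores = _score_library(
                strategy, query, library, reference_profile, alpha, threshold
            )
            rr = recovery_rate(scores, labels, ids=library.ids, selection_size=sel)
            _, auc = roc_auc(scores, labels)
            records.append(
                {"replicate": rep, "strategy": strategy, "rr": rr, "auc": auc}
            )

    per_replicate = pd.DataFrame(records)
    summary = (
        per_replicate.groupby("strategy", sort=False)[["rr", "auc"]]
        .agg(["mean", "std"])
        .rename(columns={"mean": "mean", "std": "sd"})
    )
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    return per_replicate, summary


def benchmark_sweep(
    actives: BitMatrix,
    decoys: BitMatrix,
    reference_profile: BitCountProfile,
    alphas: tuple[float, ...] = (0.10, 0.05, 0.01, 0.005, 0.001),
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`benchmark` at several SB-DFP significance levels.

    The default grid corresponds to confidence levels
    {90%, 95%, 99%, 99.5%, 99.9%}.  Returns the stacked summaries with an
    ``alpha`` column; the 1-NN and DFP rows repeat across levels (they do
    not depend on alpha) and serve as controls.
    """
    frames = []
    for a in alphas:
        _, summary = benchmark(actives, decoys, reference_profile, alpha=a, **kwargs)
        s = summary.reset_index()
        s.insert(0, "alpha", a)
        frames.append(s)
    return pd.concat(frames, ignore_index=True)


def best_strategies(
    per_replicate: pd.DataFrame, metric: str = "auc", alpha: float = 0.05
) -> list[str]:
    """Strategies statistically tied with the best one on a metric.

    The top strategy by replicate mean is always included; any other whose
    replicate values are not distinguishable from the top one by a
    two-sided Welch t-test at ``alpha`` is included as a tie.
    """
    means = per_replicate.groupby("strategy")[metric].mean()
    top = means.idxmax()
    top_vals = per_replicate.loc[per_replicate["strategy"] == top, metric]
    best = [top]
    for strat in means.index:
        if strat == top:
            continue
        vals = per_replicate.loc[per_replicate["strategy"] == strat, metric]
        if ttest_ind(top_vals, vals, equal_var=False).pvalue >= alpha:
            best.append(strat)
    return sorted(best, key=lambda s: -means[s])
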