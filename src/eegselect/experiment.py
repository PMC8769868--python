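"""Multi-run experiments, a matched-budget random-search baseline, and the
statistics used to compare stochastic optimizers.

Because the optimizer is stochastic, a method is characterised by a batch of
independent runs (25 by default) differing only in seed.  Batches are
compared with the Wilcoxon signed-rank test (paired by seed, two-sided,
normal approximation so a Z value is reported) and with a sum-of-ranks table
across measures: per measure each method gets competition rank 1..m (ties
share the better rank) and smaller rank sums are better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from . import cuckoo
from .features import FeatureTable
from .objective import ChannelMask, FitnessEvaluator, ObjectiveConfig
from .cuckoo import CSConfig, SelectionResult

__all__ = [
    "RunBatch",
    "ComparisonReport",
    "cuckoo_optimizer",
    "random_search_optimizer",
    "random_search_baseline",
    "run_batch",
    "summarize_batch",
    "wilcoxon_compare",
    "rank_summation",
    "compare_batches",
]

MEASURES = ("fit", "acc", "n_selected", "precision", "recall", "fscore")
MEASURE_LABELS = {
    "fit": "EEG_Fit",
    "acc": "EEG_ACC",
    "n_selected": "EEG_Len",
    "precision": "EEG_Precision",
    "recall": "EEG_Recall",
    "fscore": "EEG_Fscore",
}
HIGHER_IS_BETTER = {m: m != "n_selected" for m in MEASURES}

Optimizer = Callable[[FeatureTable, ObjectiveConfig, int], SelectionResult]


@dataclass
class RunBatch:
    """Independent runs of one method on one dataset, one seed per run."""

    method: str
    results: list[SelectionResult]
    dataset_id: str
    seeds: list[int]

    def measure(self, name: str) -> np.ndarray:
        return np.asarray([getattr(r.best_report, name) for r in self.results], float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({MEASURE_LABELS[m]: self.measure(m) for m in MEASURES})
        df.insert(0, "seed", self.seeds)
        df.insert(0, "method", self.method)
        return df


@dataclass
class ComparisonReport:
    summary: pd.DataFrame
    pairwise: pd.DataFrame
    ranks: pd.DataFrame


def cuckoo_optimizer(cs_config: CSConfig) -> Optimizer:
    """Plug-in adapter: binary cuckoo search with a per-run seed override."""

    def _opt(features: FeatureTable, obj_config: ObjectiveConfig, seed: int) -> SelectionResult:
        import dataclasses

        cfg = dataclasses.replace(cs_config, seed=seed)
        return cuckoo.run(features, obj_config, cfg)

    return _opt


def random_search_baseline(
    features: FeatureTable,
    obj_config: ObjectiveConfig,
    budget: int,
    seed: int,
    without_replacement: bool = False,
) -> SelectionResult:
    """Evaluate ``budget`` uniformly random nonempty masks, keep the best.

    ``without_replacement`` enumerates distinct masks (feasible only for
    small d); with budget = 2^d - 1 it coincides with exhaustive search.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    d = features.n_channels
    evaluator = FitnessEvaluator(features, obj_config)

    seen: set[tuple[int, ...]] = set()
    best: SelectionResult | None = None
    best_fit = -np.inf
    trace, trace_acc, trace_len = [], [], []
    best_mask = best_report = None
    for _ in range(budget):
        for _attempt in range(10000):
            bits = rng.integers(0, 2, size=d)
            if bits.sum() == 0:
                continue
            key = tuple(int(b) for b in bits)
            if without_replacement:
                if key in seen:
                    if len(seen) >= 2**d - 1:
                        break
                    continue
                seen.add(key)
            break
        mask = ChannelMask(key)
        report = evaluator.evaluate(mask)
        if report.fit > best_fit:
            best_fit, best_mask, best_report = report.fit, mask, report
        trace.append(best_fit)
        trace_acc.append(best_report.acc)
        trace_len.append(best_report.n_selected)
    return SelectionResult(
        best_mask=best_mask,
        best_report=best_report,
        trace=np.asarray(trace),
        trace_acc=np.asarray(trace_acc),
        trace_len=np.asarray(trace_len),
        n_evaluations=evaluator.n_evaluations,
        config={"method": "random_search", "budget": budget},
        seed=seed,
    )


def random_search_optimizer(budget: int, without_replacement: bool = False) -> Optimizer:
    def _opt(features: FeatureTable, obj_config: ObjectiveConfig, seed: int) -> SelectionResult:
        return random_search_baseline(
            features, obj_config, budget, seed, without_replacement
        )

    return _opt


def run_batch(
    features: FeatureTable,
    optimizer: Optimizer,
    n_runs: int = 25,
    base_seed: int = 0,
    obj_config: ObjectiveConfig | None = None,
    method: str = "MOBCS-KNN",
    dataset_id: str = "dataset",
) -> RunBatch:
    """Run ``n_runs`` independent optimizations with seeds base_seed + i."""
    if obj_config is None:
        obj_config = ObjectiveConfig()
    seeds = [base_seed + i for i in range(n_runs)]
    results = []
    for s in seeds:
        try:
            results.append(optimizer(features, obj_config, s))
        except Exception as exc:
            raise RuntimeError(f"run with seed {s} failed: {exc}") from exc
    return RunBatch(method=method, results=results, dataset_id=dataset_id, seeds=seeds)


def summarize_batch(batch: RunBatch) -> pd.DataFrame:
    """Mean, median and interquartile range of every measure."""
    rows = []
    for m in MEASURES:
        v = batch.measure(m)
        q1, q3 = np.percentile(v, [25, 75])
        rows.append(
            {
                "measure": MEASURE_LABELS[m],
                "mean": v.mean(),
                "median": float(np.median(v)),
                "iqr": q3 - q1,
                "best": v.max() if HIGHER_IS_BETTER[m] else v.min(),
            }
        )
    return pd.DataFrame(rows)


def wilcoxon_compare(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Wilcoxon signed-rank test, paired by seed.

    Uses the normal approximation without tie correction, Z = (W+ - mu)/sigma
    with mu = m(m+1)/4 and sigma^2 = m(m+1)(2m+1)/24 over the m nonzero
    differences, so the reported Z matches the classic tabulated convention
    (|Z| = 4.3724 for 25 concordant pairs).  Zero differences are dropped.
    Returns (Z, p, verdict) with verdict at the 0.05 level.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError(f"need at least 5 pairs for the signed-rank test, got {len(a)}")
    diff = a - b
    diff = diff[diff != 0]
    if diff.size == 0:
        return 0.0, 1.0, "nonsignificant"
    ranks = stats.rankdata(np.abs(diff))
    w_plus = ranks[diff > 0].sum()
    m = diff.size
    mu = m * (m + 1) / 4.0
    sigma = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0)
    z = (w_plus - mu) / sigma
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p), "significant" if p < 0.05 else "nonsignificant"


def rank_summation(
    values: pd.DataFrame, higher_is_better: dict[str, bool] | None = None
) -> pd.DataFrame:
    """Dense-rank methods per measure and sum the ranks.

    ``values``: rows = methods, columns = measures.  The best method on a
    measure gets rank 1; exact ties share the better (smaller) rank and the
    next distinct value gets the next integer (dense ranking, the convention
    of published sum-of-ranks comparisons).  A ``rank_sum`` column is
    appended; smaller is better.
    """
    if values.isna().any().any():
        bad = values.isna().stack()
        method, measure = bad[bad].index[0]
        raise ValueError(f"missing value for method {method!r}, measure {measure!r}")
    if higher_is_better is None:
        higher_is_better = {c: c != MEASURE_LABELS["n_selected"] for c in values.columns}
    ranks = pd.DataFrame(index=values.index, dtype=int)
    for col in values.columns:
        v = values[col].to_numpy(dtype=float)
        if higher_is_better.get(col, True):
            v = -v
        ranks[col] = stats.rankdata(v, method="dense").astype(int)
    ranks["rank_sum"] = ranks.sum(axis=1)
    return ranks


def compare_batches(batches: list[RunBatch], reference: str | None = None) -> ComparisonReport:
    """Summaries, pairwise Wilcoxon tests against a reference, and rank sums."""
    if len(batches) < 2:
        raise ValueError("need at least two batches to compare")
    n = len(batches[0].results)
    if any(len(b.results) != n for b in batches) or n < 2:
        raise ValueError("all batches must have the same run count >= 2")
    if reference is None:
        reference = batches[0].method
    by_name = {b.method: b for b in batches}
    ref = by_name[reference]

    summary = pd.concat(
        [summarize_batch(b).assign(method=b.method) for b in batches], ignore_index=True
    )
    rows = []
    for b in batches:
        if b.method == reference:
            continue
        z, p, verdict = wilcoxon_compare(ref.measure("fit"), b.measure("fit"))
        rows.append({"method": b.method, "vs": reference, "Z": z, "p": p, "verdict": verdict})
    pairwise = pd.DataFrame(rows)

    values = pd.DataFrame(
        {MEASURE_LABELS[m]: {b.method: b.measure(m).mean() for b in batches} for m in MEASURES}
    )
    ranks = rank_summation(values)
    return ComparisonReport(summary=summary, pairwise=pairwise, ranks=ranks)
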