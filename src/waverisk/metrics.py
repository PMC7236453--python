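"""AUC and the repeated-random-split benchmarking protocol."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .ingest import LabeledCohort, SplitPlan

logger = logging.getLogger(__name__)


def auc(labels, scores) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute 1/2."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class BenchmarkReport:
    model: str
    endpoint: str
    seed: int
    auc_values: list = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_values))

    @property
    def se_auc(self) -> float:
        """Sample SD of per-split AUCs over sqrt(#splits); 0 for one split."""
        if len(self.auc_values) < 2:
            return 0.0
        return float(np.std(self.auc_values, ddof=1) / np.sqrt(len(self.auc_values)))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "endpoint": self.endpoint,
            "seed": self.seed,
            "n_splits": len(self.auc_values),
            "auc_mean": self.mean_auc,
            "auc_se": self.se_auc,
            "auc_values": [float(v) for v in self.auc_values],
        }


def run_benchmark(
    model_factory,
    expr_values: np.ndarray,
    cohort: LabeledCohort,
    plan: SplitPlan,
    model_name: str = "model",
    max_failure_fraction: float = 0.1,
) -> BenchmarkReport:
    """Fit/score a model factory over every split of a plan and collect AUCs.

    ``model_factory(split_index)`` must return an object with ``fit(X, y)``
    and a continuous scorer ``predict_proba(X)[:, 1]`` (sklearn convention);
    ``expr_values`` is samples x genes aligned with ``cohort.sample_ids``.
    Failed splits are recorded and excluded; more than
    ``max_failure_fraction`` failures aborts.
    """
    expr_values = np.asarray(expr_values, dtype=float)
    pos = {s: i for i, s in enumerate(cohort.sample_ids)}
    aucs, failures = [], 0
    for k, (train_ids, val_ids) in enumerate(plan):
        tr = np.array([pos[s] for s in train_ids])
        va = np.array([pos[s] for s in val_ids])
        try:
            model = model_factory(k)
            model.fit(expr_values[tr], cohort.labels[tr])
            scores = model.predict_proba(expr_values[va])[:, 1]
            aucs.append(auc(cohort.labels[va], scores))
        except Exception as exc:
            failures += 1
            logger.warning("benchmark split %d failed: %s", k, exc)
    if failures > max_failure_fraction * len(plan):
        raise RuntimeError(f"{failures}/{len(plan)} benchmark splits failed")
    return BenchmarkReport(model=model_name, endpoint=cohort.endpoint,
                           seed=plan.seed, auc_values=aucs)
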