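"""Permutation-surrogate chance-level test for classification performance.

The null hypothesis is that the forest's balanced accuracy on unseen data
is what label-blind training would achieve.  Training labels are randomly
reassigned (class sizes preserved), a forest with identical
hyperparameters is retrained per randomization, and its balanced accuracy
on the untouched evaluation set forms the null distribution.  Performance
is significant when the observed accuracy exceeds the 95th percentile of
that distribution; the p-value uses the add-one permutation convention so
it is never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classifier import (FeatureTable, balanced_accuracy, feature_matrix,
                         labels_binary, labeled_subset, train_random_forest)

__all__ = ["SurrogateResult", "permutation_null_test"]


@dataclass
class SurrogateResult:
    observed_balanced_accuracy_pct: float
    null_values: np.ndarray
    q95: float
    p_value: float
    significant: bool

    @property
    def n_randomizations(self) -> int:
        return self.null_values.size


def permutation_null_test(train_table: FeatureTable, eval_events,
                          n_randomizations: int = 1000, rng_seed: int = 0,
                          n_trees: int = 1000) -> SurrogateResult:
    """Benchmark a forest against label-permuted retraining.

    ``eval_events`` may be labeled detection events or an ``(X, y)``
    tuple.  The observed accuracy comes from a forest trained on the
    unpermuted table; each of ``n_randomizations`` null draws permutes the
    training labels, retrains with a fresh seed, and scores the same
    evaluation set.  The 95th quantile uses the linearly interpolated
    empirical quantile.
    """
    if len(np.unique(train_table.y)) < 2:
        raise ValueError("training table must contain both classes")
    if n_randomizations < 20:
        warnings.warn("fewer than 20 randomizations: the 95th quantile "
                      "of the null is unstable")
    if isinstance(eval_events, tuple):
        X_eval, y_eval = eval_events
        X_eval = np.asarray(X_eval, dtype=float)
        y_eval = np.asarray(y_eval, dtype=int)
    else:
        evs = labeled_subset(eval_events)
        X_eval, y_eval = feature_matrix(evs), labels_binary(evs)

    rng = np.random.default_rng(rng_seed)
    observed_model = train_random_forest(train_table, n_trees=n_trees,
                                         rng_seed=rng_seed)
    observed = balanced_accuracy(observed_model, X_eval, y_eval)

    null = np.empty(n_randomizations)
    for k in range(n_randomizations):
        y_perm = rng.permutation(train_table.y)
        table_k = FeatureTable(X=train_table.X, y=y_perm,
                               event_times=train_table.event_times,
                               recording_id=train_table.recording_id)
        model_k = train_random_forest(
            table_k, n_trees=n_trees,
            rng_seed=int(rng.integers(0, 2**31 - 1)))
        null[k] = balanced_accuracy(model_k, X_eval, y_eval)

    q95 = float(np.quantile(null, 0.95))
    p = (1.0 + float((null >= observed).sum())) / (1.0 + n_randomizations)
    return SurrogateResult(
        observed_balanced_accuracy_pct=observed,
        null_values=null,
        q95=q95,
        p_value=p,
        significant=observed > q95,
    )
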